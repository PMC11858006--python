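# Methods

This note documents the models, numerical choices and known limitations of
`vitellus`. Nothing here states an empirical result beyond what the test
suite and `scripts/acceptance.py` compute.

## The dip statistic and test

The dip of an empirical distribution function `F_n` is
`D = min_G sup_x |F_n(x) − G(x)|` over unimodal distribution functions `G`
(convex up to a mode, concave after it; an atom is permitted only at the
mode). `D` lies in `[0, 1/4]`; its floor for any sample of distinct values
is `1/(2n)` and an all-equal sample is defined to have `D = 0` (a point
mass is perfectly unimodal) rather than raising an error.

The implementation follows the classical iteration: fit the greatest convex
minorant (GCM) of the ECDF's left limits and the least concave majorant
(LCM) of its right limits on a candidate modal interval, locate the largest
gap between the two hulls, record the largest one-sided ECDF deviation
outside the new modal interval, shrink the interval, and stop when the hull
gap no longer exceeds the recorded deviation; the dip is half the final
deviation. Two details matter numerically:

* the hull gap is evaluated **only at hull contact points** — both curves
  are linear in between, so this is exact, and it keeps the recursion
  stable under floating-point ties in the gap profile;
* deviations across **vertical hull segments** (tied observations) are not
  charged: a unimodal CDF may jump at its mode, so an atom contributes only
  the one-count floor that any hull segment contributes.

Correctness is established against an independent oracle in the test suite:
a linear program that minimises the sup-norm band half-width over piecewise
linear unimodal CDFs (slope sequence single-peaked, optional jump at the
mode knot) for every candidate mode. The two agree to ~1e−12 on thousands
of random samples, with and without ties.

The test's p-value is Monte Carlo: `p = (1 + #{D_null ≥ D_obs}) / (1 + R)`
with null samples of the same size drawn uniform on (0, 1) — the classical
calibration for the dip test — and is therefore never below `1/(1+R)` and
deterministic given the seed. The inner loop is numba-compiled; the default
`R = 999` on a ~20,000-point sample runs in about a second.

## Exact 1-D k-means, k selection, threshold

The optimal k-means partition of scalars is contiguous in sorted order, so
the global optimum is found by dynamic programming over the distinct values
(weighted by multiplicity), with divide-and-conquer over the monotone split
points (`O(k · m log m)` for `m` distinct values). This removes any seed
dependence from the headline threshold; ties in the DP are broken toward
the smaller split index. Centres are reported ascending with sample SDs
(`ddof = 1`, zero for singletons).

The elbow criterion is formalised as the `k` maximising the second
difference `W(k−1) − 2W(k) + W(k+1)` of total within-cluster SS (ties →
smaller `k`; `k = 1` cannot be scored). Mean silhouette width is computed
exactly from per-cluster prefix sums (no distance matrix); singleton
clusters score 0, and `k = 1` is excluded. A sample without dispersion
raises "no dispersion".

The dominance threshold is `floor(min of upper cluster)` from the `k = 2`
model, used strictly: a follicle is dominant iff `diameter > threshold`, so
a diameter exactly at the threshold is non-dominant.

One structural consequence worth knowing: for a contiguous optimal 2-means
partition the boundary falls at the midpoint of the two cluster means
(≈ 18.9 mm for clusters near 8.5 and 29.4 mm). With the generator's
dominant diameters truncated at 18.6 mm, the smallest *upper-cluster*
member is therefore usually just above 19 mm and the derived threshold is
19 rather than 18 — within the ±1 mm band the recovery tests assert.

## Synthetic cohorts

The generator emulates what ovaries recovered at a nesting beach look
like; its defaults are the study conditions, not tuning knobs.

* **Clutch structure.** Clutch frequency is uniform on {3, …, 9}; clutches
  already laid are uniform on {1, …, CF−1} (every female has both scars and
  dominant follicles, as budgets require); eggs per clutch default to 110
  exactly, so truth recovery is sharp. Scars and dominant follicles split
  between ovaries binomially (an `even` split is available for symmetry
  tests).
* **Diameters.** Non-dominant: normal(8, 2.9) truncated to (4.3, 18] mm
  with a Poisson(105) count per ovary; dominant: the two-component mixture
  0.3·N(26, 2.1) + 0.7·N(31, 2.9) truncated to (18.6, 37] mm — the lower
  bound is the smallest dominant diameter observed in the field data.
  Measured diameters are rounded to the 0.1 mm calliper resolution.
* **Composition.** Per follicle type (AF/SF/LF), each variable is normal
  with the field means/SDs; half of each variable's variance
  (`composition_female_variance_share = 0.5`) is a female-level effect
  shared across types. This share is what makes blocking on female id
  informative — the block design in the source analysis presupposes
  exactly such female-level variation — while leaving the marginal SDs at
  their configured values. Five SF and five LF follicles per covered
  female (and up to three atretic follicles for a subset) carry
  composition values and measured dry masses (the dry-weight line plus
  N(0, 0.5 g) noise, floored at 0.05 g).
* **Ground truth.** Both ovaries are always generated; truth (clutches
  laid/left, season half, deficit flag) is computed from the unrounded
  diameters of both ovaries at the true 18 mm threshold before the
  single-ovary measurement scenario drops one ovary for ~25% of females.

What the generator does **not** emulate: covariance between composition
variables (only marginals are known), atresia dynamics or ovulation
timing, spatial structure within the ovary, measurement error in scar
counts, and any stratification of dominant follicles by upcoming clutch.
Passing recovery tests therefore show that the pipeline inverts this
generative structure, not that it would recover every feature of real
ovaries.

## Accounting and budget rules

Egg counts use measured ovaries only; with a single measured ovary both
totals are doubled and the summary is flagged `extrapolated`. Clutch
counts are rounded half-up (the field reports integer clutch frequencies
without stating a rounding rule). Season half: `first` iff clutches laid <
clutches left. Prospective growth of a dominant follicle of diameter `d`
toward its ovary maximum `M` is `100·(M − d)/d` (an increase of the
follicle itself); `(M − d)/M` is available as an option.

Dry-mass predictions below zero (diameters under the line's root,
`10.1/0.572 ≈ 17.66 mm`) are floored at 0 g with the count logged. Since
nearly all non-dominant follicles lie below the root, the synthetic
cohort's resorbable yolk is essentially zero and every simulated female
shows an energy deficit; the recovery tests compare the pipeline against
the generator's truth computed under the same rule, so this is a
consistent — and documented — consequence of applying the published line
outside its fitted range, not a bug. Refitting the line on measured
(diameter, dry mass) pairs is available (`dry_weight_source = "refit"`).
The deposition target is the heaviest dominant follicle **per ovary** (a
female-wide maximum is an option). The summary table multiplies mean yolk
by cohort-mean nutrient fractions, reports `CP = 6.25·N`, and converts
energy as `kJ = g · 0.95 · 29.5` for both the mean and the maximum yolk
mass; display rounding uses two significant figures, computation is full
precision.

## Blocked composition statistics

The Durbin statistic uses within-block midranks:
`T = (t−1) Σ_j (R_j − r(k+1)/2)² / (A − C)` with `A` the sum of squared
ranks and `C = b·k·(k+1)²/4`, referred to chi-square with `t−1` degrees of
freedom; on complete blocks without ties it is exactly the Friedman
statistic (asserted to 1e−9). A fully tied table is defined as `T = 0, p
= 1`. Pairwise follow-ups use rank-sum differences with the Conover
standard error and a t reference on `bk − b − t + 1` degrees of freedom,
Bonferroni-adjusted, and run only after a significant omnibus at the
configured alpha (default 0.05). The chi-square reference is
anti-conservative for very small designs (b ≈ 3); the suite checks that
its alpha = 0.10 decisions agree with within-block permutation on ≥ 95% of
random small tables.

The parametric route is the two-way block ANOVA without interaction —
for complete blocks with one observation per cell this is the
fixed-effect equivalent of a mixed model with a random female intercept,
and its two-treatment case is exactly the paired t-test. REML estimation
is deliberately out of scope. By default water and organic matter take the
rank route and the other nutrients the parametric route; the mapping is a
parameter. Blocks missing a treatment for a given variable are dropped
for that variable's test with the count logged.

## Pipeline and formats

Interchange is plain CSV (UTF-8, comma, "." decimal) with units embedded
in column names; all floats serialise with `%.6g`, and generated values
are rounded (0.1 mm diameters, 2-decimal percentages, 3-decimal gram
masses) so emit → read round-trips are exact and same-seed runs are
byte-identical. The run manifest records the seed, a config echo, library
versions and per-stage row counts, and deliberately contains no
timestamps. Stage failures abort with the stage name.

## Limitations

* The dip p-value is Monte Carlo; at `R = 999` its resolution is 0.001.
* The chi-square reference for Durbin is approximate for < 5 blocks; use
  the permutation route (test oracle) if such designs matter.
* The dry-weight line applied below ~17.7 mm is an extrapolation of the
  published fit; the floor-at-zero rule makes small-follicle yolk masses
  effectively unavailable rather than negative.
* The generator draws composition variables independently (given the
  female effect); real lipid/N/P fractions are likely correlated.
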