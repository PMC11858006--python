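# vitellus

Follicle size-hierarchy classification and reproductive energy budgets for
nesting sea turtles.

Green turtles (*Chelonia mydas*) lay several clutches of roughly 110 eggs
per nesting season. Their ovaries at the nesting beach hold thousands of
vitellogenic follicles whose diameters split into two classes: small
**non-dominant** follicles destined for resorption and large **dominant**
follicles destined for ovulation — with a further size hierarchy inside the
dominant class reflecting the order of upcoming clutches. `vitellus`
implements, as a tested and reusable pipeline, the statistical machinery a
reproductive ecologist needs to quantify this structure from per-follicle
morphometrics and to convert it into a per-female energy budget:

* **Bimodality** — Hartigan's dip statistic `D = min_G sup_x |F_n(x) − G(x)|`
  (the minimal sup-norm distance between the empirical CDF and any unimodal
  CDF), computed by the exact greatest-convex-minorant / least-concave-
  majorant iteration, with a Monte-Carlo p-value calibrated against uniform
  null samples.
* **Clustering** — globally optimal 1-D k-means by dynamic programming over
  the sorted diameters (no seeds, no restarts), cluster-count selection by
  the elbow and silhouette criteria, and a dominance threshold defined as
  the floor of the smallest diameter in the upper cluster (strict lower
  bound: dominant ⇔ diameter > threshold).
* **Clutch accounting** — eggs laid from recent ovulatory scar counts, eggs
  left from dominant follicle counts, both divided by the mean clutch size
  (110) to give clutches laid/left; their sum is the clutch frequency, and a
  female with clutches laid ≥ clutches left is in the second half of her
  season. Single-ovary females are doubled under the symmetry assumption,
  which the package also tests (paired left-right comparisons).
* **Energy budgets** — follicle dry (yolk) mass from the linear model
  `dry weight (g) = −10.1 + 0.572 · diameter (mm)` (measured dry masses
  override predictions); per ovary, deposited yolk is the sum of dominant
  dry masses, yolk still to deposit is each dominant follicle's gap to the
  heaviest dominant follicle of the same ovary, and resorbable yolk is the
  non-dominant total. Nutrients scale yolk by per-female lipid/N/P/mineral
  fractions; crude protein is `CP = 6.25 · N` and energy is
  `kJ = dry mass · 0.95 · 29.5`.
* **Composition statistics** — female-blocked comparisons of yolk
  composition across follicle types (atretic AF, small SF and large LF
  dominant): the Durbin rank test (exactly Friedman on complete blocks)
  with Conover pairwise follow-ups under Bonferroni, and a parametric
  block-ANOVA route whose two-treatment case is the paired t-test.
* **Synthetic cohorts** — a seeded generator that emulates the field data's
  structure (diameter mixture, scar counts for 3–9 clutches of ~110 eggs,
  yolk composition with female-level blocking) and records ground truth for
  parameter-recovery tests. No downloads are needed anywhere.

## Worked example

```python
from vitellus import (CohortSpec, generate_cohort, dip_test, kmeans_1d,
                      derive_dominance_threshold, summarize_cohort)
from vitellus.budget import (female_budget, female_composition_means,
                             cohort_budget_summary)
import numpy as np

cohort, truth = generate_cohort(CohortSpec(rng_seed=1))
diameters = cohort.pooled_diameters()

dip = dip_test(diameters, n_monte_carlo=999, rng_seed=1)
model = kmeans_1d(diameters, 2)
thr = derive_dominance_threshold(model)
summary = summarize_cohort(cohort, thr)

comp = female_composition_means(cohort)
cm = {k: float(np.mean([m[k] for m in comp.values()]))
      for k in ("lipid", "n", "p", "mineral")}
budgets = [female_budget(f, thr, composition_means=comp.get(f.female_id, cm))
           for f in cohort.females]
table, deficit = cohort_budget_summary(budgets)
```

prints (via the obvious `print` calls):

```
dip D = 0.102, p = 0.001 (n = 19166)
cluster centres: [ 8.5 29.4] mm; min of upper cluster = 19.2 mm; dominant iff diameter > 19 mm
clutch frequency: mean 6.2, range 3-9
  category  mean_g   sd_g  max_g   cp_g  energy_kj
 deposited  2087.5 1157.2 4940.6 1240.8    58501.4
to_deposit  1301.9  766.2 3314.5  773.9    36486.8
 to_resorb     0.1    0.1    0.7    0.0        2.0
deficit fraction: 1.00
```

Reading this: the pooled diameter distribution decisively rejects
unimodality (p is at its Monte-Carlo floor of 1/1000); the two clusters sit
near 8.5 and 29.4 mm and the derived dominance threshold is 19 mm; females
average six clutches (range 3–9); the average female has already deposited
~2.1 kg of dry yolk (~59,000 kJ) into dominant follicles and still needs to
deposit more than her non-dominant follicles could supply by resorption —
under the dry-weight line, follicles below its ~17.7 mm root predict zero
resorbable mass, so every simulated female runs an energy deficit. The
same pipeline runs from the command line:

```bash
vitellus simulate --seed 1 --out cohort/
vitellus cluster --follicles cohort/follicles.csv
vitellus all --seed 1 --out run/     # full bundle + manifest
```

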