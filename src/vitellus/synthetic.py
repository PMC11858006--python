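"""Seeded synthetic cohorts of nesting green turtle females.

The generator emulates the statistical structure of ovaries recovered at a
nesting beach: a two-component follicle-diameter distribution (a small
"non-dominant" mode near 8 mm and a dominant mode that is itself a
two-component mixture near 26 and 31 mm), ovulatory-scar counts consistent
with 3-9 clutches of ~110 eggs per season, and yolk composition with
realistic per-follicle-type means and spreads.  Every quantity the
downstream pipeline estimates (clutches laid/left, season half, energy
deficit) is also recorded as ground truth at generation time, enabling
parameter-recovery tests.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .records import (
    Cohort,
    CompositionRecord,
    FemaleRecord,
    FollicleRecord,
    OvaryRecord,
)

__all__ = ["CohortSpec", "SyntheticTruth", "generate_cohort", "emit_tables", "DEFAULT_COMPOSITION_PARAMS"]

#: Per-follicle-type composition (mean, SD) in percent.  Water is % of wet
#: mass; the others are % of dry mass.  AF = atretic, SF/LF = small/large
#: dominant follicles.
DEFAULT_COMPOSITION_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "AF": {
        "water_pct": (56.5, 8.24),
        "om_pct": (95.4, 0.41),
        "mineral_pct": (4.62, 0.41),
        "lipid_pct": (32.6, 4.95),
        "n_pct": (9.47, 1.19),
        "p_pct": (0.99, 0.10),
    },
    "SF": {
        "water_pct": (49.7, 3.46),
        "om_pct": (95.0, 1.09),
        "mineral_pct": (5.01, 1.09),
        "lipid_pct": (32.3, 2.39),
        "n_pct": (9.65, 0.79),
        "p_pct": (1.07, 0.09),
    },
    "LF": {
        "water_pct": (47.4, 2.16),
        "om_pct": (95.0, 1.07),
        "mineral_pct": (4.95, 1.07),
        "lipid_pct": (32.9, 3.14),
        "n_pct": (9.68, 0.92),
        "p_pct": (1.07, 0.10),
    },
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Diameters are drawn from truncated normals: the non-dominant component
    on ``nondominant_range_mm`` and the dominant two-component mixture on
    ``dominant_range_mm``.  Composition values share, per female and
    variable, a common female-level effect across follicle types
    (``composition_female_variance_share`` of the marginal variance), which
    is what makes blocking on female id informative.
    """

    n_females: int = 40
    mean_clutch_size: int = 110
    clutch_frequency_range: tuple[int, int] = (3, 9)
    # non-dominant component: mean, sd, Poisson count per ovary
    nondominant_mean_mm: float = 8.0
    nondominant_sd_mm: float = 2.9
    nondominant_count_per_ovary: float = 105.0
    nondominant_range_mm: tuple[float, float] = (4.3, 18.0)
    # dominant mixture: (mean, sd, weight) per component
    dominant_components: tuple[tuple[float, float, float], ...] = (
        (26.0, 2.1, 0.30),
        (31.0, 2.9, 0.70),
    )
    dominant_range_mm: tuple[float, float] = (18.6, 37.0)
    composition_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            t: dict(v) for t, v in DEFAULT_COMPOSITION_PARAMS.items()
        }
    )
    composition_female_variance_share: float = 0.5
    # dry mass model: intercept (g), slope (g/mm), residual SD (g)
    dry_mass_intercept_g: float = -10.1
    dry_mass_slope_g_per_mm: float = 0.572
    dry_mass_residual_sd_g: float = 0.5
    # fraction of females with only one ovary recovered/measured
    measurement_scenario: float = 0.25
    ovary_split: str = "binomial"  # how scars/follicles divide over ovaries
    caliper_resolution_mm: float = 0.1
    atresia_prob_nondominant: float = 0.5
    atresia_prob_dominant: float = 0.02
    composition_coverage: float = 0.9
    af_presence: float = 0.4
    follicles_sampled_per_type: int = 5
    af_sampled_per_female: int = 3
    oviduct_total_mean: float = 110.0
    oviduct_left_deficit: float = 10.0
    rng_seed: int = 0

    def validate(self) -> None:
        def fail(fieldname: str, msg: str) -> None:
            raise ValueError(f"invalid CohortSpec.{fieldname}: {msg}")

        if self.n_females < 1:
            fail("n_females", "must be >= 1")
        if self.mean_clutch_size < 1:
            fail("mean_clutch_size", "must be >= 1")
        lo, hi = self.clutch_frequency_range
        if not (1 <= lo <= hi <= 12):
            fail("clutch_frequency_range", "must be within [1, 12] with lo <= hi")
        if self.nondominant_sd_mm < 0:
            fail("nondominant_sd_mm", "sd must be >= 0")
        if self.nondominant_count_per_ovary < 0:
            fail("nondominant_count_per_ovary", "must be >= 0")
        w = sum(c[2] for c in self.dominant_components)
        if abs(w - 1.0) > 1e-9:
            fail("dominant_components", f"mixture weights must sum to 1 (got {w})")
        for mean, sd, weight in self.dominant_components:
            if sd < 0:
                fail("dominant_components", "sd must be >= 0")
            if weight < 0:
                fail("dominant_components", "weights must be >= 0")
        for rng_name in ("nondominant_range_mm", "dominant_range_mm"):
            a, b = getattr(self, rng_name)
            if not (0 < a < b):
                fail(rng_name, "must satisfy 0 < low < high")
        for ftype, params in self.composition_params.items():
            for var, (mean, sd) in params.items():
                if not (0.0 <= mean <= 100.0):
                    fail("composition_params", f"{ftype}.{var} mean outside [0, 100]")
                if sd < 0:
                    fail("composition_params", f"{ftype}.{var} sd must be >= 0")
        if not (0.0 <= self.composition_female_variance_share <= 1.0):
            fail("composition_female_variance_share", "must be in [0, 1]")
        if self.dry_mass_residual_sd_g < 0:
            fail("dry_mass_residual_sd_g", "must be >= 0")
        if not (0.0 <= self.measurement_scenario <= 1.0):
            fail("measurement_scenario", "must be in [0, 1]")
        if self.ovary_split not in ("binomial", "even"):
            fail("ovary_split", "must be 'binomial' or 'even'")
        for pname in ("atresia_prob_nondominant", "atresia_prob_dominant",
                      "composition_coverage", "af_presence"):
            v = getattr(self, pname)
            if not (0.0 <= v <= 1.0):
                fail(pname, "must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time.

    ``per_female`` has one row per female with the true clutch counts,
    season half, follicle counts and the energy-budget quantities computed
    from the unrounded diameters of *both* ovaries with the configured dry
    mass line (negative predictions floored at zero) at the true 18 mm
    dominance threshold.
    """

    per_female: pd.DataFrame
    threshold_mm: float
    spec: dict

    @property
    def deficit_fraction(self) -> float:
        return float(self.per_female["deficit"].mean())


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated-normal draws by rejection (falls back to clipping for
    pathologically far-out bounds)."""
    if sd == 0:
        val = min(max(mean, lo), hi)
        return np.full(size, val)
    out = np.empty(size)
    filled = 0
    attempts = 0
    while filled < size:
        need = size - filled
        draw = rng.normal(mean, sd, size=max(need * 2, 16))
        keep = draw[(draw > lo) & (draw <= hi)]
        take = min(keep.size, need)
        out[filled : filled + take] = keep[:take]
        filled += take
        attempts += 1
        if attempts > 1000:
            out[filled:] = np.clip(rng.normal(mean, sd, size - filled), lo, hi)
            break
    return out


def _split_two(rng, total: int, mode: str) -> tuple[int, int]:
    if mode == "even":
        left = total // 2
    else:
        left = int(rng.binomial(total, 0.5))
    return left, total - left


def _round_res(x: np.ndarray, res: float) -> np.ndarray:
    if res <= 0:
        return x
    # second rounding snaps to the shortest decimal so values survive a
    # CSV round-trip bit-exactly
    return np.round(np.round(x / res) * res, 6)


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, SyntheticTruth]:
    """Generate a seeded cohort of females plus its ground truth.

    Each female receives a clutch frequency uniform on the configured
    range, splits it into clutches already laid (scars) and clutches left
    (dominant follicles), and carries a Poisson number of non-dominant
    follicles per ovary.  Both ovaries are always generated (truth is
    computed from both); for females selected by ``measurement_scenario``
    only one randomly chosen ovary is retained in the emitted cohort,
    mirroring field recoveries of a single ovary.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    mcs = spec.mean_clutch_size
    lo_cf, hi_cf = spec.clutch_frequency_range

    comp_means = np.array([c[0] for c in spec.dominant_components])
    comp_sds = np.array([c[1] for c in spec.dominant_components])
    comp_wts = np.array([c[2] for c in spec.dominant_components])

    females: list[FemaleRecord] = []
    composition: list[CompositionRecord] = []
    truth_rows = []

    for fi in range(spec.n_females):
        fid = f"F{fi + 1:03d}"
        cf = int(rng.integers(lo_cf, hi_cf + 1))
        clutches_laid = int(rng.integers(1, cf)) if cf >= 2 else 0
        clutches_left = cf - clutches_laid

        scars_total = clutches_laid * mcs
        dominant_total = clutches_left * mcs
        scars = _split_two(rng, scars_total, spec.ovary_split)
        dom_counts = _split_two(rng, dominant_total, spec.ovary_split)
        nd_counts = tuple(
            int(rng.poisson(spec.nondominant_count_per_ovary)) for _ in range(2)
        )

        # oviducts hold the clutch currently being shelled; the left
        # oviduct runs systematically lower
        total_ovi = max(0, int(round(rng.normal(spec.oviduct_total_mean, 8.0))))
        left_ovi = max(0, int(round((total_ovi - spec.oviduct_left_deficit) / 2.0
                                    + rng.normal(0.0, 3.0))))
        ovi = {"left": min(left_ovi, total_ovi), "right": total_ovi - min(left_ovi, total_ovi)}

        ovaries: list[OvaryRecord] = []
        true_dom_w: dict[str, np.ndarray] = {}
        true_nd_w: dict[str, np.ndarray] = {}
        fidx = 0
        for si, side in enumerate(("left", "right")):
            n_dom = dom_counts[si]
            n_nd = nd_counts[si]
            comp_idx = rng.choice(len(comp_wts), size=n_dom, p=comp_wts)
            dom_raw = np.empty(n_dom)
            for ci in range(len(comp_wts)):
                mask = comp_idx == ci
                if mask.any():
                    dom_raw[mask] = _truncated_normal(
                        rng, comp_means[ci], comp_sds[ci],
                        spec.dominant_range_mm[0], spec.dominant_range_mm[1],
                        int(mask.sum()),
                    )
            nd_raw = _truncated_normal(
                rng, spec.nondominant_mean_mm, spec.nondominant_sd_mm,
                spec.nondominant_range_mm[0], spec.nondominant_range_mm[1],
                n_nd,
            )

            # ground-truth yolk masses from the unrounded diameters
            line = spec.dry_mass_intercept_g + spec.dry_mass_slope_g_per_mm * dom_raw
            true_dom_w[side] = np.maximum(line, 0.0)
            line_nd = spec.dry_mass_intercept_g + spec.dry_mass_slope_g_per_mm * nd_raw
            true_nd_w[side] = np.maximum(line_nd, 0.0)

            dom_meas = _round_res(dom_raw, spec.caliper_resolution_mm)
            nd_meas = _round_res(nd_raw, spec.caliper_resolution_mm)

            follicles = []
            atr_dom = rng.random(n_dom) < spec.atresia_prob_dominant
            atr_nd = rng.random(n_nd) < spec.atresia_prob_nondominant
            for d, atr, sub in zip(dom_meas, atr_dom, comp_idx):
                follicles.append(
                    FollicleRecord(
                        follicle_id=f"{fid}-{fidx:04d}",
                        female_id=fid,
                        ovary_side=side,
                        diameter_mm=float(d),
                        atretic=bool(atr),
                        follicle_type="SF" if sub == 0 else "LF",
                    )
                )
                fidx += 1
            for d, atr in zip(nd_meas, atr_nd):
                follicles.append(
                    FollicleRecord(
                        follicle_id=f"{fid}-{fidx:04d}",
                        female_id=fid,
                        ovary_side=side,
                        diameter_mm=float(d),
                        atretic=bool(atr),
                        follicle_type=None,
                    )
                )
                fidx += 1

            # ovary bulk size from total follicle volume plus stroma
            foll_vol_ml = float(np.sum((4.0 / 3.0) * math.pi
                                       * (np.concatenate([dom_raw, nd_raw]) / 20.0) ** 3))
            volume_ml = 50.0 * round((1.15 * foll_vol_ml + 250.0) / 50.0)
            mass_g = 500.0 * round((1.05 * (1.15 * foll_vol_ml + 250.0) + 300.0) / 500.0)
            ovaries.append(
                OvaryRecord(
                    female_id=fid,
                    side=side,
                    scar_count=scars[si],
                    mass_g=mass_g,
                    volume_ml=volume_ml,
                    oviduct_egg_count=ovi[side],
                    measured=True,
                    follicles=follicles,
                )
            )

        one_ovary = rng.random() < spec.measurement_scenario
        if one_ovary:
            keep = int(rng.integers(0, 2))
            ovaries = [ovaries[keep]]

        female = FemaleRecord(female_id=fid, ovaries=ovaries)

        # --- composition subsample (on retained ovaries only) -------------
        sampled = rng.random() < spec.composition_coverage
        if sampled:
            dom_follicles = [
                f
                for ov in ovaries
                for f in ov.follicles
                if f.follicle_type in ("SF", "LF")
            ]
            af_follicles = [
                f
                for ov in ovaries
                for f in ov.follicles
                if f.follicle_type is None and f.atretic
            ]
            female_effect = {
                var: rng.normal() for var in ("water_pct", "om_pct", "mineral_pct",
                                              "lipid_pct", "n_pct", "p_pct")
            }
            rho = spec.composition_female_variance_share

            def draw_comp(ftype: str) -> dict[str, float]:
                out = {}
                for var, (mu, sd) in spec.composition_params[ftype].items():
                    val = (mu + math.sqrt(rho) * sd * female_effect[var]
                           + math.sqrt(1.0 - rho) * sd * rng.normal())
                    out[var] = round(float(np.clip(val, 0.0, 100.0)), 2)
                return out

            chosen: list[tuple[FollicleRecord, str]] = []
            for ftype in ("SF", "LF"):
                pool = [f for f in dom_follicles if f.follicle_type == ftype]
                take = min(spec.follicles_sampled_per_type, len(pool))
                if take > 0:
                    idx = rng.choice(len(pool), size=take, replace=False)
                    chosen.extend((pool[i], ftype) for i in idx)
            if rng.random() < spec.af_presence and af_follicles:
                take = min(spec.af_sampled_per_female, len(af_follicles))
                idx = rng.choice(len(af_follicles), size=take, replace=False)
                chosen.extend((af_follicles[i], "AF") for i in idx)

            for foll, ftype in chosen:
                foll.follicle_type = ftype
                pred = (spec.dry_mass_intercept_g
                        + spec.dry_mass_slope_g_per_mm * foll.diameter_mm)
                foll.dry_mass_g = round(
                    max(0.05, pred + rng.normal(0.0, spec.dry_mass_residual_sd_g)), 3
                )
                vals = draw_comp(ftype)
                composition.append(
                    CompositionRecord(
                        female_id=fid,
                        follicle_id=foll.follicle_id,
                        follicle_type=ftype,
                        **vals,
                    )
                )
            # dominant follicles not subsampled carry no type label
            for f in dom_follicles:
                if all(f is not c for c, _ in chosen):
                    f.follicle_type = None
        else:
            for ov in ovaries:
                for f in ov.follicles:
                    if f.follicle_type in ("SF", "LF"):
                        f.follicle_type = None

        # --- ground truth (both ovaries, unrounded, threshold 18) ---------
        deposited = to_deposit = to_resorb = 0.0
        for side in ("left", "right"):
            w = true_dom_w[side]
            if w.size:
                wmax = float(w.max())
                deposited += float(w.sum())
                to_deposit += float(np.sum(wmax - w))
            to_resorb += float(true_nd_w[side].sum())

        truth_rows.append(
            {
                "female_id": fid,
                "clutch_frequency": cf,
                "clutches_laid": clutches_laid,
                "clutches_left": clutches_left,
                "season_half": "first" if clutches_laid < clutches_left else "second",
                "n_dominant": int(dominant_total),
                "n_nondominant": int(sum(nd_counts)),
                "n_scars": int(scars_total),
                "one_ovary_measured": bool(one_ovary),
                "yolk_deposited_g": deposited,
                "yolk_to_deposit_g": to_deposit,
                "yolk_to_resorb_g": to_resorb,
                "deficit": to_deposit > to_resorb,
            }
        )
        females.append(female)

    truth = SyntheticTruth(
        per_female=pd.DataFrame(truth_rows),
        threshold_mm=18.0,
        spec={k: v for k, v in asdict(spec).items() if k != "composition_params"},
    )
    return Cohort(females=females, composition=composition), truth


# ---------------------------------------------------------------------------
# table emission


def emit_tables(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the cohort as CSV tables (follicles, ovaries, females,
    composition); returns the paths.  Uses fixed float formatting so that
    identical cohorts serialise to identical bytes."""
    from . import io as vio

    if len(cohort) == 0:
        raise ValueError("cannot emit an empty cohort")
    return vio.write_cohort(cohort, outdir)
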