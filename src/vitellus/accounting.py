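"""Clutch accounting from ovulatory scars and dominant follicles.

Eggs a female has already laid this season are counted by her recently
formed ovulatory scars; eggs still to be laid are counted by her dominant
follicles (diameter strictly above the dominance threshold).  Dividing by
the population's mean clutch size (110 eggs) converts both to clutches;
their sum is the female's clutch frequency.  When only one ovary was
recovered, both ovaries are assumed to contribute equally and the single
ovary's totals are doubled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import Cohort, FemaleRecord
from .blockstats import BlockDesignTable, blocked_two_group

logger = logging.getLogger(__name__)

__all__ = [
    "ReproductiveSummary",
    "count_eggs",
    "summarize_female",
    "summarize_cohort",
    "follicle_growth_pct",
    "ovary_symmetry_report",
]


@dataclass
class ReproductiveSummary:
    female_id: str
    eggs_laid: int
    eggs_left: int
    clutches_laid: int
    clutches_left: int
    clutch_frequency: int
    season_half: str  # "first" | "second"
    extrapolated: bool


def count_eggs(female: FemaleRecord, threshold: float) -> tuple[int, int, bool]:
    """(eggs_laid, eggs_left, extrapolated) for one female.

    eggs_left counts follicles with diameter strictly greater than the
    threshold across measured ovaries; eggs_laid sums ovulatory scars.
    With a single measured ovary both totals are doubled.
    """
    measured = female.measured_ovaries()
    if not measured:
        raise ValueError(f"female {female.female_id}: no measured ovary")
    eggs_left = sum(
        sum(1 for d in ov.diameters() if d > threshold) for ov in measured
    )
    eggs_laid = sum(ov.scar_count for ov in measured)
    extrapolated = len(measured) == 1
    if extrapolated:
        eggs_left *= 2
        eggs_laid *= 2
    return eggs_laid, eggs_left, extrapolated


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summarize_female(
    female_id: str,
    eggs_laid: int,
    eggs_left: int,
    mean_clutch_size: int = 110,
    extrapolated: bool = False,
) -> ReproductiveSummary:
    """Convert egg counts to clutches and classify the season half.

    Clutch counts are rounded half-up.  A female with an equal or greater
    number of clutches laid than left is in the second half of her
    individual nesting season.
    """
    if eggs_laid < 0 or eggs_left < 0:
        raise ValueError("egg counts must be nonnegative")
    clutches_laid = _round_half_up(eggs_laid / mean_clutch_size)
    clutches_left = _round_half_up(eggs_left / mean_clutch_size)
    return ReproductiveSummary(
        female_id=female_id,
        eggs_laid=int(eggs_laid),
        eggs_left=int(eggs_left),
        clutches_laid=clutches_laid,
        clutches_left=clutches_left,
        clutch_frequency=clutches_laid + clutches_left,
        season_half="first" if clutches_laid < clutches_left else "second",
        extrapolated=extrapolated,
    )


def summarize_cohort(
    cohort: Cohort, threshold: float, mean_clutch_size: int = 110
) -> pd.DataFrame:
    """Per-female reproductive summary plus follicle counts by class."""
    rows = []
    for fem in cohort.females:
        laid, left, extra = count_eggs(fem, threshold)
        s = summarize_female(fem.female_id, laid, left, mean_clutch_size, extra)
        n_dom = n_nd = 0
        for ov in fem.measured_ovaries():
            for d in ov.diameters():
                if d > threshold:
                    n_dom += 1
                else:
                    n_nd += 1
        factor = 2 if extra else 1
        rows.append(
            {
                "female_id": s.female_id,
                "eggs_laid": s.eggs_laid,
                "eggs_left": s.eggs_left,
                "clutches_laid": s.clutches_laid,
                "clutches_left": s.clutches_left,
                "clutch_frequency": s.clutch_frequency,
                "season_half": s.season_half,
                "extrapolated": int(s.extrapolated),
                "n_dominant": n_dom * factor,
                "n_nondominant": n_nd * factor,
            }
        )
    return pd.DataFrame(rows)


def follicle_growth_pct(
    female: FemaleRecord, threshold: float, relative_to: str = "self"
) -> float:
    """Mean prospective growth (%) of dominant follicles.

    Each dominant follicle of diameter d is compared with the largest
    dominant follicle M in the same ovary.  With ``relative_to='self'``
    (default) growth is 100 * (M - d) / d, the percent increase the
    follicle would undergo to reach the ovary maximum; ``'max'`` uses
    100 * (M - d) / M instead.
    """
    growths: list[float] = []
    for ov in female.measured_ovaries():
        dom = [d for d in ov.diameters() if d > threshold]
        if not dom:
            continue
        m = max(dom)
        for d in dom:
            denom = d if relative_to == "self" else m
            growths.append(100.0 * (m - d) / denom)
    if not growths:
        raise ValueError(f"female {female.female_id}: no dominant follicles")
    return float(np.mean(growths))


_SYMMETRY_VARIABLES = (
    "dominant_count",
    "nondominant_count",
    "scar_count",
    "volume_ml",
    "oviduct_egg_count",
    "mass_g",
)


def ovary_symmetry_report(cohort: Cohort, threshold: float) -> pd.DataFrame:
    """Paired left-right comparison of ovary variables.

    One row per variable with means by side, the mean paired difference
    (left minus right) and the p-value of the female-blocked two-group
    comparison.  Ovary mass is reported without a test: the scale
    resolution (500 g) exceeds the expected mean difference.  Variables
    absent from the data are skipped with a notice.
    """
    paired = [f for f in cohort.females if len(f.measured_ovaries()) == 2]
    if len(paired) < 2:
        raise ValueError(
            "ovary symmetry requires >= 2 females with both ovaries measured"
        )

    def value(ov, var):
        if var == "dominant_count":
            return float(sum(1 for d in ov.diameters() if d > threshold))
        if var == "nondominant_count":
            return float(sum(1 for d in ov.diameters() if d <= threshold))
        if var == "scar_count":
            return float(ov.scar_count)
        return getattr(ov, var)

    rows = []
    for var in _SYMMETRY_VARIABLES:
        long_rows = []
        for fem in paired:
            vals = {}
            for ov in fem.measured_ovaries():
                v = value(ov, var)
                if v is not None:
                    vals[ov.side] = float(v)
            if set(vals) == {"left", "right"}:
                long_rows.append((fem.female_id, vals["left"], vals["right"]))
        if not long_rows:
            logger.info("symmetry report: variable %s absent, skipped", var)
            continue
        if len(long_rows) < 2:
            raise ValueError(f"insufficient left-right pairs for variable '{var}'")
        left = np.array([r[1] for r in long_rows])
        right = np.array([r[2] for r in long_rows])
        row = {
            "variable": var,
            "n_pairs": len(long_rows),
            "mean_left": float(left.mean()),
            "mean_right": float(right.mean()),
            "mean_diff_left_minus_right": float((left - right).mean()),
        }
        if var == "mass_g":
            row["statistic"] = np.nan
            row["p_value"] = np.nan
            row["note"] = "not tested: scale resolution 500 g"
        else:
            table = BlockDesignTable.from_long(
                blocks=[r[0] for r in long_rows] * 2,
                treatments=["left"] * len(long_rows) + ["right"] * len(long_rows),
                responses=list(left) + list(right),
            )
            res = blocked_two_group(table)
            row["statistic"] = res.statistic
            row["p_value"] = res.p_value
            row["note"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
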