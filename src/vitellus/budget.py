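"""Per-female yolk, nutrient and energy budgets.

Follicle dry (yolk) mass is predicted from diameter with the linear model
``dry weight (g) = -10.1 + 0.572 * diameter (mm)`` (measured dry masses,
where available, override the prediction).  For each ovary the dry mass of
every dominant follicle counts as yolk already deposited; the gap to the
heaviest dominant follicle in the same ovary is yolk still to be
deposited; the dry mass of all non-dominant follicles is the yolk
available for resorption.  One-ovary females are doubled.  Nutrient masses
scale the yolk by each female's mean lipid/N/P/mineral fractions of dry
yolk; crude protein is N x 6.25 and energy is dry mass x 0.95 (organic
fraction) x 29.5 kJ/g.

The prediction line crosses zero near 17.7 mm, so most non-dominant
follicles predict a negative dry mass; predictions are floored at zero and
the floored count is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Cohort, FemaleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DryWeightModel",
    "EnergeticConstants",
    "CategoryBudget",
    "EnergyBudget",
    "predict_dry_weight",
    "fit_dry_weight_model",
    "female_budget",
    "cohort_budget_summary",
    "seasonal_follicle_comparison",
    "female_composition_means",
    "round_sig",
]

#: Yolk categories of the budget, in report order.
CATEGORIES = ("deposited", "to_deposit", "to_resorb")


@dataclass
class DryWeightModel:
    """Linear dry-weight-from-diameter model (grams, millimetres)."""

    intercept_g: float = -10.1
    slope_g_per_mm: float = 0.572
    r_squared: Optional[float] = None
    residual_sd_g: Optional[float] = None

    def predict(self, diameter_mm) -> np.ndarray:
        return self.intercept_g + self.slope_g_per_mm * np.asarray(diameter_mm, dtype=float)


@dataclass
class EnergeticConstants:
    """Proximate-composition conversion factors.

    cp_per_g_n: grams of crude protein per gram of nitrogen (6.25);
    organic_fraction: grams of organic matter per gram of dry yolk (0.95);
    energy_per_g_om: kJ per gram of organic matter (29.5);
    mean_clutch_size: eggs per clutch (110).
    """

    cp_per_g_n: float = 6.25
    organic_fraction: float = 0.95
    energy_per_g_om: float = 29.5
    mean_clutch_size: int = 110

    def __post_init__(self) -> None:
        for name in ("cp_per_g_n", "organic_fraction", "energy_per_g_om", "mean_clutch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"EnergeticConstants.{name} must be positive")

    def om_from_dry(self, yolk_g: float) -> float:
        return yolk_g * self.organic_fraction

    def energy_from_om(self, om_g: float) -> float:
        return om_g * self.energy_per_g_om

    def energy_from_dry(self, yolk_g: float) -> float:
        return self.energy_from_om(self.om_from_dry(yolk_g))

    def cp_from_n(self, n_g: float) -> float:
        return n_g * self.cp_per_g_n


@dataclass
class CategoryBudget:
    yolk_g: float
    lipid_g: float
    n_g: float
    p_g: float
    cp_g: float
    mineral_g: float
    energy_kj: float


@dataclass
class EnergyBudget:
    female_id: str
    deposited: CategoryBudget
    to_deposit: CategoryBudget
    to_resorb: CategoryBudget
    deficit: bool
    extrapolated: bool
    n_floored_predictions: int = 0

    def category(self, name: str) -> CategoryBudget:
        return getattr(self, name)


def predict_dry_weight(diameter_mm: float, model: Optional[DryWeightModel] = None) -> float:
    """Raw dry-weight prediction in grams (may be negative below the root
    of the line; flooring happens at budget time)."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    model = model or DryWeightModel()
    return float(model.predict(diameter_mm))


def fit_dry_weight_model(pairs: Sequence[tuple[float, float]]) -> DryWeightModel:
    """Ordinary least squares fit of dry mass (g) on diameter (mm)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (diameter, dry mass) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: diameters are constant")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(1, x.size - 2)
    return DryWeightModel(
        intercept_g=float(res.intercept),
        slope_g_per_mm=float(res.slope),
        r_squared=float(res.rvalue**2),
        residual_sd_g=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def _follicle_mass(foll, model: DryWeightModel) -> tuple[float, bool]:
    """Dry mass of one follicle: measured if available, else floored
    prediction.  Returns (grams, floored?)."""
    if foll.dry_mass_g is not None:
        return float(foll.dry_mass_g), False
    pred = float(model.predict(foll.diameter_mm))
    if pred < 0.0:
        return 0.0, True
    return pred, False


def female_budget(
    female: FemaleRecord,
    threshold: float,
    model: Optional[DryWeightModel] = None,
    constants: Optional[EnergeticConstants] = None,
    composition_means: Optional[dict[str, float]] = None,
    per_ovary_maximum: bool = True,
) -> EnergyBudget:
    """Yolk/nutrient/energy budget of one female.

    ``composition_means`` maps 'lipid', 'n', 'p', 'mineral' to this
    female's mean fraction (g per g dry yolk); when None, mineral defaults
    to 1 - organic_fraction and the nutrient entries are NaN.  With
    ``per_ovary_maximum`` (default) the deposition target for each
    dominant follicle is the heaviest dominant follicle in the same ovary;
    otherwise the female-wide maximum.
    """
    model = model or DryWeightModel()
    constants = constants or EnergeticConstants()
    measured = female.measured_ovaries()
    if not measured:
        raise ValueError(f"female {female.female_id}: no measured ovary")

    deposited = to_deposit = to_resorb = 0.0
    n_floored = 0
    dom_masses_all: list[float] = []
    per_ovary_dom: list[list[float]] = []
    for ov in measured:
        dom = []
        for f in ov.follicles:
            mass, floored = _follicle_mass(f, model)
            n_floored += floored
            if f.diameter_mm > threshold:
                dom.append(mass)
                dom_masses_all.append(mass)
            else:
                to_resorb += mass
        per_ovary_dom.append(dom)

    if not dom_masses_all:
        raise ValueError(f"female {female.female_id}: no dominant follicles")

    female_max = max(dom_masses_all)
    for dom in per_ovary_dom:
        if not dom:
            continue
        target = max(dom) if per_ovary_maximum else female_max
        deposited += sum(dom)
        to_deposit += sum(target - w for w in dom)

    extrapolated = len(measured) == 1
    if extrapolated:
        deposited *= 2.0
        to_deposit *= 2.0
        to_resorb *= 2.0

    if n_floored:
        logger.debug(
            "female %s: %d negative dry-weight predictions floored at 0 g",
            female.female_id, n_floored,
        )

    fracs = dict(composition_means or {})
    fracs.setdefault("mineral", 1.0 - constants.organic_fraction)
    for key in ("lipid", "n", "p"):
        fracs.setdefault(key, math.nan)

    def cat(yolk_g: float) -> CategoryBudget:
        n_g = yolk_g * fracs["n"]
        return CategoryBudget(
            yolk_g=yolk_g,
            lipid_g=yolk_g * fracs["lipid"],
            n_g=n_g,
            p_g=yolk_g * fracs["p"],
            cp_g=constants.cp_from_n(n_g),
            mineral_g=yolk_g * fracs["mineral"],
            energy_kj=constants.energy_from_dry(yolk_g),
        )

    return EnergyBudget(
        female_id=female.female_id,
        deposited=cat(deposited),
        to_deposit=cat(to_deposit),
        to_resorb=cat(to_resorb),
        deficit=to_deposit > to_resorb,
        extrapolated=extrapolated,
        n_floored_predictions=n_floored,
    )


def female_composition_means(cohort: Cohort) -> dict[str, dict[str, float]]:
    """Per-female mean nutrient fractions of dry yolk (g per g).

    Averages lipid/N/P/mineral percentages over all of a female's
    subsampled follicles (all types pooled) and converts percent of dry
    mass to a fraction.
    """
    if not cohort.composition:
        return {}
    df = pd.DataFrame(
        {
            "female_id": [c.female_id for c in cohort.composition],
            "lipid": [c.lipid_pct / 100.0 for c in cohort.composition],
            "n": [c.n_pct / 100.0 for c in cohort.composition],
            "p": [c.p_pct / 100.0 for c in cohort.composition],
            "mineral": [c.mineral_pct / 100.0 for c in cohort.composition],
        }
    )
    out: dict[str, dict[str, float]] = {}
    for fid, grp in df.groupby("female_id"):
        out[str(fid)] = {k: float(grp[k].mean()) for k in ("lipid", "n", "p", "mineral")}
    return out


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report display convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))


def cohort_budget_summary(
    budgets: Sequence[EnergyBudget],
    constants: Optional[EnergeticConstants] = None,
) -> tuple[pd.DataFrame, float]:
    """Cohort summary table (one row per yolk category) + deficit fraction.

    Yolk columns are mean/SD/min/max over females.  Nutrient columns
    multiply the mean yolk mass by the cohort-mean nutrient fraction; CP is
    N x 6.25.  Energy is reported both for the mean and for the maximum
    yolk mass.  The deficit fraction is the share of females whose yolk
    still to deposit exceeds their resorbable yolk.
    """
    if not budgets:
        raise ValueError("no budgets to summarise")
    constants = constants or EnergeticConstants()
    rows = []
    for cat_name in CATEGORIES:
        yolk = np.array([b.category(cat_name).yolk_g for b in budgets])

        def mean_frac(attr: str) -> float:
            vals = [
                getattr(b.category(cat_name), attr) / b.category(cat_name).yolk_g
                for b in budgets
                if b.category(cat_name).yolk_g > 0
                and np.isfinite(getattr(b.category(cat_name), attr))
            ]
            return float(np.mean(vals)) if vals else math.nan

        mean_yolk = float(yolk.mean())
        n_g = mean_yolk * mean_frac("n_g")
        rows.append(
            {
                "category": cat_name,
                "mean_g": mean_yolk,
                "sd_g": float(yolk.std(ddof=1)) if yolk.size > 1 else 0.0,
                "min_g": float(yolk.min()),
                "max_g": float(yolk.max()),
                "lipid_g": mean_yolk * mean_frac("lipid_g"),
                "n_g": n_g,
                "p_g": mean_yolk * mean_frac("p_g"),
                "cp_g": constants.cp_from_n(n_g),
                "mineral_g": mean_yolk * mean_frac("mineral_g"),
                "energy_kj": constants.energy_from_dry(mean_yolk),
                "energy_kj_max": constants.energy_from_dry(float(yolk.max())),
            }
        )
    deficit_fraction = float(np.mean([b.deficit for b in budgets]))
    return pd.DataFrame(rows), deficit_fraction


def seasonal_follicle_comparison(summary: pd.DataFrame) -> dict[str, dict]:
    """Compare follicle counts between season halves.

    Dominant counts: Welch's unequal-variance t-test.  Non-dominant
    counts: Wilcoxon rank-sum (exact for small samples, normal
    approximation otherwise).  ``summary`` needs columns season_half,
    n_dominant, n_nondominant.
    """
    first = summary[summary["season_half"] == "first"]
    second = summary[summary["season_half"] == "second"]
    if len(first) < 2 or len(second) < 2:
        raise ValueError("both season halves need >= 2 females")
    t_res = stats.ttest_ind(
        first["n_dominant"], second["n_dominant"], equal_var=False
    )
    u_res = stats.mannwhitneyu(
        first["n_nondominant"], second["n_nondominant"],
        alternative="two-sided", method="auto",
    )
    return {
        "dominant_welch_t": {
            "statistic": float(t_res.statistic),
            "p_value": float(t_res.pvalue),
            "n_first": int(len(first)),
            "n_second": int(len(second)),
        },
        "nondominant_rank_sum": {
            "statistic": float(u_res.statistic),
            "p_value": float(u_res.pvalue),
            "n_first": int(len(first)),
            "n_second": int(len(second)),
        },
    }
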