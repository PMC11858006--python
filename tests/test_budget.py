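"""Tests of the dry-weight model and the yolk/nutrient/energy budgets."""

import numpy as np
import pandas as pd
import pytest

from vitellus.budget import (
    DryWeightModel,
    EnergeticConstants,
    cohort_budget_summary,
    female_budget,
    fit_dry_weight_model,
    predict_dry_weight,
    round_sig,
    seasonal_follicle_comparison,
)
from vitellus.records import FemaleRecord, FollicleRecord, OvaryRecord


def female_with_masses(dom_masses, nd_masses, fid="F1", sides=("left",)):
    """Build a female whose follicles carry measured dry masses."""
    ovaries = []
    for side in sides:
        follicles = []
        for i, m in enumerate(dom_masses):
            follicles.append(
                FollicleRecord(f"{fid}-{side}-d{i}", fid, side, 30.0, dry_mass_g=m)
            )
        for i, m in enumerate(nd_masses):
            follicles.append(
                FollicleRecord(f"{fid}-{side}-n{i}", fid, side, 10.0, dry_mass_g=m)
            )
        ovaries.append(
            OvaryRecord(female_id=fid, side=side, scar_count=0, follicles=follicles)
        )
    return FemaleRecord(female_id=fid, ovaries=ovaries)


class TestDryWeightModel:
    @pytest.mark.parametrize(
        "diameter, expected",
        [(30.0, 7.06), (10.1 / 0.572, 0.0), (35.0, 9.92)],
    )
    def test_printed_line(self, diameter, expected):
        assert predict_dry_weight(diameter) == pytest.approx(expected, abs=1e-9)

    def test_exact_fit_recovers_line(self):
        x = np.linspace(19, 36, 40)
        y = -10.1 + 0.572 * x
        model = fit_dry_weight_model(list(zip(x, y)))
        assert model.intercept_g == pytest.approx(-10.1, abs=1e-9)
        assert model.slope_g_per_mm == pytest.approx(0.572, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_recovers_slope_within_3se(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(19, 36, 100)
        y = -10.1 + 0.572 * x + rng.normal(0, 0.5, 100)
        model = fit_dry_weight_model(list(zip(x, y)))
        se = 0.5 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(model.slope_g_per_mm - 0.572) < 3 * se

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            fit_dry_weight_model([(20.0, 1.0), (30.0, 7.0)])

    def test_degenerate_design(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_dry_weight_model([(20.0, 1.0)] * 5)


class TestEnergeticConstants:
    def test_caption_arithmetic_identities(self):
        c = EnergeticConstants()
        for y in (1.0, 2311.0, 0.37, 523.0):
            assert c.energy_from_dry(y) == pytest.approx(y * 0.95 * 29.5, rel=1e-12)
        for n in (1.0, 224.2, 0.01):
            assert c.cp_from_n(n) == pytest.approx(6.25 * n, rel=1e-12)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            EnergeticConstants(organic_fraction=0.0)


class TestFemaleBudget:
    def test_single_ovary_worked_example(self):
        """Dominant dry masses {7.7, 6.0, 5.0} g and non-dominant
        {1.0, 0.5} g in one ovary, doubled for the unmeasured side."""
        fem = female_with_masses([7.7, 6.0, 5.0], [1.0, 0.5])
        b = female_budget(fem, 18.0)
        assert b.deposited.yolk_g == pytest.approx(2 * 18.7)
        assert b.to_deposit.yolk_g == pytest.approx(2 * ((7.7 - 6.0) + (7.7 - 5.0)))
        assert b.to_resorb.yolk_g == pytest.approx(2 * 1.5)
        assert b.deficit is True
        assert b.extrapolated is True

    def test_equal_dominant_masses_mean_nothing_to_deposit(self):
        fem = female_with_masses([4.0, 4.0, 4.0], [], sides=("left", "right"))
        b = female_budget(fem, 18.0)
        assert b.to_deposit.yolk_g == 0.0
        assert b.extrapolated is False

    def test_negative_predictions_floored(self):
        fid = "F1"
        follicles = [
            FollicleRecord(f"{fid}-0", fid, "left", 30.0),  # predicts 7.06
            FollicleRecord(f"{fid}-1", fid, "left", 8.0),  # predicts < 0
        ]
        fem = FemaleRecord(fid, [OvaryRecord(fid, "left", 0, follicles=follicles)])
        b = female_budget(fem, 18.0)
        assert b.to_resorb.yolk_g == 0.0
        assert b.n_floored_predictions == 1

    def test_additivity_per_ovary(self):
        """deposited + to_deposit = n_dominant x heaviest dominant mass."""
        rng = np.random.default_rng(3)
        masses = list(rng.uniform(2, 9, 25))
        fem = female_with_masses(masses, [0.4, 0.2])
        b = female_budget(fem, 18.0)
        assert b.deposited.yolk_g + b.to_deposit.yolk_g == pytest.approx(
            2 * len(masses) * max(masses)
        )

    def test_scale_equivariance(self):
        masses = [7.0, 5.5, 3.2]
        nd = [0.8, 0.3]
        b1 = female_budget(female_with_masses(masses, nd), 18.0)
        b2 = female_budget(
            female_with_masses([2 * m for m in masses], [2 * m for m in nd]), 18.0
        )
        for cat in ("deposited", "to_deposit", "to_resorb"):
            assert b2.category(cat).yolk_g == pytest.approx(2 * b1.category(cat).yolk_g)
            assert b2.category(cat).energy_kj == pytest.approx(
                2 * b1.category(cat).energy_kj
            )
        assert b1.deficit == b2.deficit

    def test_nutrients_scale_with_composition_means(self):
        fem = female_with_masses([7.7, 6.0], [1.0])
        fr = {"lipid": 0.33, "n": 0.096, "p": 0.011, "mineral": 0.05}
        b = female_budget(fem, 18.0, composition_means=fr)
        dep = b.deposited
        assert dep.lipid_g == pytest.approx(dep.yolk_g * 0.33)
        assert dep.cp_g == pytest.approx(dep.n_g * 6.25)
        assert dep.energy_kj == pytest.approx(dep.yolk_g * 0.95 * 29.5)

    def test_no_dominant_raises(self):
        fem = female_with_masses([], [1.0])
        with pytest.raises(ValueError, match="no dominant"):
            female_budget(fem, 18.0)


class TestCohortSummary:
    def _budget(self, to_deposit, to_resorb, fid):
        fem = female_with_masses([5.0, 5.0 - to_deposit / 2], [to_resorb / 2], fid=fid,
                                 sides=("left", "right"))
        return female_budget(fem, 18.0)

    def test_deficit_fraction_half(self):
        budgets = [self._budget(10.0, 2.0, "A"), self._budget(5.0, 8.0, "B")]
        _, frac = cohort_budget_summary(budgets)
        assert frac == 0.5

    def test_all_resorb_zero(self):
        budgets = [self._budget(10.0, 0.0, "A"), self._budget(5.0, 0.0, "B")]
        _, frac = cohort_budget_summary(budgets)
        assert frac == 1.0

    def test_table_columns_follow_caption_rules(self):
        budgets = [self._budget(4.0, 1.0, "A"), self._budget(6.0, 3.0, "B")]
        table, _ = cohort_budget_summary(budgets)
        row = table.set_index("category").loc["deposited"]
        assert row["energy_kj"] == pytest.approx(row["mean_g"] * 0.95 * 29.5)
        assert row["energy_kj_max"] == pytest.approx(row["max_g"] * 0.95 * 29.5)
        assert row["cp_g"] == pytest.approx(row["n_g"] * 6.25, nan_ok=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_budget_summary([])


class TestSeasonalComparison:
    def test_identical_groups(self):
        df = pd.DataFrame(
            {
                "season_half": ["first"] * 3 + ["second"] * 3,
                "n_dominant": [400, 500, 600, 400, 500, 600],
                "n_nondominant": [100, 150, 200, 100, 150, 200],
            }
        )
        res = seasonal_follicle_comparison(df)
        assert res["dominant_welch_t"]["statistic"] == pytest.approx(0.0)
        assert res["dominant_welch_t"]["p_value"] == pytest.approx(1.0)

    def test_separated_halves_detected(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "season_half": ["first"] * 15 + ["second"] * 15,
                "n_dominant": np.concatenate(
                    [rng.normal(700, 50, 15), rng.normal(300, 50, 15)]
                ),
                "n_nondominant": np.concatenate(
                    [rng.normal(250, 30, 15), rng.normal(120, 30, 15)]
                ),
            }
        )
        res = seasonal_follicle_comparison(df)
        assert res["dominant_welch_t"]["p_value"] < 0.001
        assert res["nondominant_rank_sum"]["p_value"] < 0.001

    def test_exact_rank_sum_small_groups(self):
        """{1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 arrangements,
        one-sided exact p = 1/20."""
        from scipy.stats import mannwhitneyu

        res = mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="less", method="exact")
        assert res.pvalue == pytest.approx(0.05)

    def test_missing_half_raises(self):
        df = pd.DataFrame(
            {"season_half": ["first"] * 4, "n_dominant": [1, 2, 3, 4],
             "n_nondominant": [1, 2, 3, 4]}
        )
        with pytest.raises(ValueError):
            seasonal_follicle_comparison(df)


def test_round_sig_matches_report_convention():
    assert round_sig(64766.525, 2) == 65000
    assert round_sig(14656.525, 2) == 15000
    assert round_sig(6697.725, 2) == 6700
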