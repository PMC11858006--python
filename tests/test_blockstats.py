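"""Tests of the Durbin test, pairwise follow-ups, paired comparisons and
the composition report."""

import numpy as np
import pandas as pd
import pytest

from conftest import composition_frame
from vitellus.blockstats import (
    BlockDesignTable,
    blocked_anova,
    blocked_two_group,
    composition_report,
    durbin_all_pairs,
    durbin_test,
)
from vitellus.synthetic import DEFAULT_COMPOSITION_PARAMS, CohortSpec, generate_cohort

from _oracles import durbin_permutation_p, friedman_statistic


def table_from_array(vals):
    b, t = vals.shape
    return BlockDesignTable(
        blocks=[f"B{i}" for i in range(b)],
        treatments=[f"T{j}" for j in range(t)],
        values=np.asarray(vals, dtype=float),
    )


class TestDurbin:
    def test_tied_blocks_give_zero_statistic(self):
        vals = np.tile(np.random.default_rng(0).normal(size=(5, 1)), (1, 3))
        res = durbin_test(table_from_array(vals))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_equals_friedman_on_complete_blocks(self):
        """On complete blocks without ties the Durbin statistic reduces
        exactly to the Friedman chi-square."""
        rng = np.random.default_rng(14)
        from scipy.stats import friedmanchisquare

        for _ in range(20):
            b, t = int(rng.integers(3, 12)), int(rng.integers(3, 6))
            vals = rng.normal(size=(b, t))
            stat = durbin_test(table_from_array(vals)).statistic
            assert stat == pytest.approx(friedman_statistic(vals), abs=1e-9)
            assert stat == pytest.approx(
                friedmanchisquare(*vals.T).statistic, abs=1e-9
            )

    def test_chi_square_p_close_to_permutation_p(self):
        """On a small complete table the chi-square p lands on the same
        side of alpha as a 10000-draw within-block permutation p."""
        vals = np.random.default_rng(7).normal(0, 1, (5, 3))
        vals[:, 0] += 1.5
        tab = table_from_array(vals)
        p_chi = durbin_test(tab).p_value

        def statfn(v):
            return durbin_test(table_from_array(v)).statistic

        _, p_perm = durbin_permutation_p(vals, statfn, 10_000, seed=9)
        assert (p_chi < 0.05) == (p_perm < 0.05)
        assert abs(p_chi - p_perm) < 0.05

    def test_rejection_decisions_agree_with_permutation(self):
        """Chi-square and exhaustive-style permutation p agree in their
        alpha = 0.10 decision on >= 95% of random small tables."""
        rng = np.random.default_rng(42)
        agree = total = 0
        for trial in range(40):
            b, t = int(rng.integers(3, 6)), int(rng.integers(3, 5))
            vals = rng.normal(size=(b, t))
            if trial % 3 == 0:
                vals[:, 0] += rng.uniform(0, 2)
            p_chi = durbin_test(table_from_array(vals)).p_value

            def statfn(v):
                return durbin_test(table_from_array(v)).statistic

            _, p_perm = durbin_permutation_p(vals, statfn, 600, seed=trial)
            agree += (p_chi < 0.10) == (p_perm < 0.10)
            total += 1
        assert agree / total >= 0.95

    def test_incomplete_blocks_dropped(self):
        vals = np.random.default_rng(1).normal(size=(6, 3))
        vals[0, :2] = np.nan  # one observation left: block dropped
        res = durbin_test(table_from_array(vals))
        assert np.isfinite(res.statistic)


class TestDurbinAllPairs:
    def test_shifted_treatment_flagged(self):
        """With one treatment far above the others, both of its pairwise
        comparisons are significant and the remaining pair is not."""
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 1, (20, 3))
        vals[:, 2] += 10.0
        pairs = dict(durbin_all_pairs(table_from_array(vals), alpha=0.05))
        assert pairs[("T0", "T2")] < 0.05
        assert pairs[("T1", "T2")] < 0.05
        assert pairs[("T0", "T1")] >= 0.05

    def test_identical_treatments_give_empty_list(self):
        vals = np.tile(np.random.default_rng(2).normal(size=(8, 1)), (1, 3))
        assert durbin_all_pairs(table_from_array(vals)) == []

    def test_bonferroni_never_decreases_p(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 1, (12, 3))
        vals[:, 0] += 1.2
        tab = table_from_array(vals)
        adjusted = durbin_all_pairs(tab, alpha=0.5)
        # recompute unadjusted by dividing out the pair count
        npairs = 3
        for _, p_adj in adjusted:
            assert p_adj >= p_adj / npairs


class TestBlockedTwoGroup:
    def test_water_difference_pattern_detected(self):
        """38 females whose SF-LF water difference averages 2.3 points
        yield p < 0.001 in the paired comparison."""
        rng = np.random.default_rng(100)
        base = rng.normal(47.4, 2.0, 38)
        diff = rng.normal(2.3, 1.0, 38)
        tab = BlockDesignTable.from_long(
            blocks=list(range(38)) * 2,
            treatments=["LF"] * 38 + ["SF"] * 38,
            responses=list(base) + list(base + diff),
        )
        res = blocked_two_group(tab)
        assert res.p_value < 0.001
        assert res.mean_diff == pytest.approx(diff.mean())

    def test_zero_differences(self):
        vals = np.tile(np.random.default_rng(3).normal(size=(6, 1)), (1, 2))
        res = blocked_two_group(table_from_array(vals))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_agrees_with_durbin_on_strong_shift(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (15, 2))
        vals[:, 1] += 5.0
        tab = table_from_array(vals)
        assert (blocked_two_group(tab).p_value < 0.05) == (
            durbin_test(tab).p_value < 0.05
        )

    def test_requires_two_treatments_and_blocks(self):
        vals = np.random.default_rng(5).normal(size=(2, 2))
        with pytest.raises(ValueError, match="blocks"):
            blocked_two_group(table_from_array(vals))
        vals3 = np.random.default_rng(5).normal(size=(5, 3))
        with pytest.raises(ValueError, match="2 treatments"):
            blocked_two_group(table_from_array(vals3))

    def test_block_anova_two_treatments_equals_paired_t(self):
        vals = np.random.default_rng(6).normal(size=(10, 2))
        res_t = blocked_two_group(table_from_array(vals))
        res_f = blocked_anova(table_from_array(vals))
        assert res_f["statistic"] == pytest.approx(res_t.statistic**2, rel=1e-9)
        assert res_f["p_value"] == pytest.approx(res_t.p_value, rel=1e-9)


def _observed_water_params():
    params = {t: dict(v) for t, v in DEFAULT_COMPOSITION_PARAMS.items()}
    params["AF"]["water_pct"] = (56.5, 8.24)
    params["LF"]["water_pct"] = (47.8, 2.06)
    params["SF"]["water_pct"] = (49.6, 3.26)
    return params


def _mini_spec(seed, params):
    return CohortSpec(
        n_females=16,
        mean_clutch_size=40,
        nondominant_count_per_ovary=40.0,
        composition_coverage=1.0,
        af_presence=1.0,
        measurement_scenario=0.0,
        composition_params=params,
        rng_seed=seed,
    )


class TestCompositionReport:
    def test_water_differences_have_power(self):
        """Cohorts drawn at the observed water means/SDs (AF 56.5, LF 47.8,
        SF 49.6; 16 females) flag each pairwise water comparison at 0.05 in
        >= 80% of 50 seeded replicates."""
        params = _observed_water_params()
        hits = {"p_AF_vs_LF": 0, "p_AF_vs_SF": 0, "p_LF_vs_SF": 0}
        for rep in range(50):
            cohort, _ = generate_cohort(_mini_spec(rep, params))
            tests = composition_report(
                composition_frame(cohort), variables=["water_pct"]
            )["tests"]
            row = tests.iloc[0]
            for key in hits:
                if key in tests.columns and row[key] < 0.05:
                    hits[key] += 1
        for key, count in hits.items():
            assert count / 50 >= 0.80, (key, count)

    def test_null_lipids_keep_type_one_error(self):
        """With a common lipid mean for all follicle types, the omnibus
        rejects at most 10% of the time at alpha = 0.05."""
        params = {t: dict(v) for t, v in DEFAULT_COMPOSITION_PARAMS.items()}
        for t in params:
            params[t]["lipid_pct"] = (32.5, params[t]["lipid_pct"][1])
        false_pos = 0
        for rep in range(50):
            cohort, _ = generate_cohort(_mini_spec(5000 + rep, params))
            tests = composition_report(
                composition_frame(cohort), variables=["lipid_pct"]
            )["tests"]
            if not tests.empty and tests.iloc[0]["p_value"] < 0.05:
                false_pos += 1
        assert false_pos / 50 <= 0.10

    def test_single_type_reports_means_only(self):
        df = pd.DataFrame(
            {
                "female_id": ["A", "B", "C"],
                "type": ["LF"] * 3,
                "water_pct": [47.0, 48.0, 47.5],
            }
        )
        rep = composition_report(df, variables=["water_pct"])
        assert len(rep["means"]) == 1
        assert rep["tests"].empty

    def test_report_means_equal_input_means(self):
        """No silent unit conversion: reported means are input means."""
        cohort, _ = generate_cohort(_mini_spec(1, _observed_water_params()))
        df = composition_frame(cohort)
        rep = composition_report(df, variables=["water_pct"])
        for _, row in rep["means"].iterrows():
            sub = df[(df["type"] == row["type"])]["water_pct"]
            assert row["mean_pct"] == pytest.approx(sub.mean())

    def test_absent_variable_skipped(self):
        df = pd.DataFrame(
            {"female_id": ["A", "A"], "type": ["SF", "LF"], "water_pct": [49.0, 47.0]}
        )
        rep = composition_report(df, variables=["water_pct", "lipid_pct"])
        assert set(rep["means"]["variable"]) == {"water_pct"}
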