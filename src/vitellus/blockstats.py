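"""Female-blocked comparisons of yolk composition across follicle types.

Each female contributes (at most) one mean response per follicle type
(AF, SF, LF), so the natural analysis is a randomised block design with
the female as the block.  Two inference routes are provided:

* a rank route — the Durbin test (which reduces exactly to the Friedman
  test on complete blocks) with Conover-style pairwise follow-ups under a
  Bonferroni correction; ties are handled by midranks throughout;
* a parametric route — the classical two-way block ANOVA without
  interaction, whose two-treatment special case is exactly the paired
  t-test; this is the fixed-effect equivalent of a mixed model with a
  random female intercept when every block is complete.

Which route a variable takes is configurable; by default water and organic
matter (bounded, skewed percentages) take the rank route and the remaining
nutrients the parametric one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BlockDesignTable",
    "RankTestResult",
    "PairedResult",
    "durbin_test",
    "durbin_all_pairs",
    "blocked_two_group",
    "blocked_anova",
    "composition_report",
    "DEFAULT_RANK_VARIABLES",
]

#: Variables that default to the rank (Durbin) route.
DEFAULT_RANK_VARIABLES = ("water_pct", "om_pct")


@dataclass
class BlockDesignTable:
    """Blocks x treatments response table; NaN marks a missing cell."""

    blocks: list[str]
    treatments: list[str]
    values: np.ndarray  # shape (b, t), NaN = unobserved

    @classmethod
    def from_long(cls, blocks, treatments, responses) -> "BlockDesignTable":
        df = pd.DataFrame(
            {"block": blocks, "treatment": treatments, "response": responses}
        )
        wide = df.pivot_table(
            index="block", columns="treatment", values="response", aggfunc="mean"
        )
        return cls(
            blocks=[str(b) for b in wide.index],
            treatments=[str(t) for t in wide.columns],
            values=wide.to_numpy(dtype=float),
        )

    def drop_incomplete(self, min_treatments: int = 2) -> "BlockDesignTable":
        """Drop blocks observing fewer than ``min_treatments`` cells."""
        observed = (~np.isnan(self.values)).sum(axis=1)
        keep = observed >= min_treatments
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d block(s) with < %d treatments", dropped, min_treatments)
        return BlockDesignTable(
            blocks=[b for b, k in zip(self.blocks, keep) if k],
            treatments=list(self.treatments),
            values=self.values[keep],
        )

    def complete_only(self) -> "BlockDesignTable":
        return self.drop_incomplete(len(self.treatments))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)


@dataclass
class RankTestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    pairwise: list[tuple[tuple[str, str], float]] = field(default_factory=list)


@dataclass
class PairedResult:
    treatments: tuple[str, str]
    mean_diff: float
    statistic: float
    df: int
    p_value: float
    n_blocks: int


def _durbin_parts(table: BlockDesignTable):
    """Midranks and the Durbin bookkeeping quantities (t, b, k, r, A, C)."""
    vals = table.values
    b, t = vals.shape
    if b == 0:
        raise ValueError("no usable blocks")
    per_block = (~np.isnan(vals)).sum(axis=1)
    k = int(per_block[0])
    if not np.all(per_block == k):
        raise ValueError("Durbin test requires the same number of observed treatments per block")
    per_treatment = (~np.isnan(vals)).sum(axis=0)
    r = int(per_treatment[0])
    if not np.all(per_treatment == r):
        raise ValueError("Durbin test requires equal replication of treatments")
    ranks = np.full_like(vals, np.nan)
    for i in range(b):
        obs = ~np.isnan(vals[i])
        ranks[i, obs] = stats.rankdata(vals[i, obs])
    rj = np.nansum(ranks, axis=0)
    a_stat = float(np.nansum(ranks**2))
    c_stat = b * k * (k + 1) ** 2 / 4.0
    return t, b, k, r, ranks, rj, a_stat, c_stat


def durbin_test(table: BlockDesignTable) -> RankTestResult:
    """Durbin rank test for treatment effects in a (balanced incomplete or
    complete) block design.

    T = (t-1) * sum_j (R_j - r(k+1)/2)^2 / (A - C) with A the sum of all
    squared within-block midranks and C = b k (k+1)^2 / 4; the reference
    distribution is chi-square with t-1 degrees of freedom.  On complete
    blocks without ties T is exactly the Friedman statistic.  If every
    block is entirely tied (A = C), T is defined as 0 with p = 1.
    """
    cleaned = table.drop_incomplete()
    t, b, k, r, ranks, rj, a_stat, c_stat = _durbin_parts(cleaned)
    denom = a_stat - c_stat
    if denom <= 1e-12:
        return RankTestResult(statistic=0.0, df=t - 1, p_value=1.0, method="durbin")
    stat = (t - 1) * float(np.sum((rj - r * (k + 1) / 2.0) ** 2)) / denom
    p = float(stats.chi2.sf(stat, t - 1))
    return RankTestResult(statistic=float(stat), df=t - 1, p_value=p, method="durbin")


def durbin_all_pairs(
    table: BlockDesignTable, alpha: float = 0.05
) -> list[tuple[tuple[str, str], float]]:
    """Bonferroni-adjusted pairwise Durbin comparisons.

    Runs only after a significant omnibus test at ``alpha`` (otherwise
    returns an empty list).  Pairs are compared through rank-sum
    differences with the Conover standard error and a t reference
    distribution on bk - b - t + 1 degrees of freedom.
    """
    cleaned = table.drop_incomplete()
    omnibus = durbin_test(cleaned)
    if omnibus.p_value >= alpha:
        logger.info(
            "omnibus Durbin p=%.3f >= alpha=%.2f: no pairwise follow-ups",
            omnibus.p_value, alpha,
        )
        return []
    t, b, k, r, ranks, rj, a_stat, c_stat = _durbin_parts(cleaned)
    df2 = b * k - b - t + 1
    t1 = omnibus.statistic
    scale = 1.0 - t1 / (b * (k - 1))
    var = 2.0 * r * (a_stat - c_stat) / df2 * scale
    pairs = list(itertools.combinations(range(t), 2))
    out = []
    for i, j in pairs:
        if var <= 1e-15:
            p = 1.0 if rj[i] == rj[j] else 0.0
        else:
            tij = abs(rj[i] - rj[j]) / np.sqrt(var)
            p = 2.0 * float(stats.t.sf(tij, df2))
        p_adj = min(1.0, p * len(pairs))
        out.append(((cleaned.treatments[i], cleaned.treatments[j]), p_adj))
    return out


def blocked_two_group(table: BlockDesignTable, min_blocks: int = 3) -> PairedResult:
    """Paired comparison of two treatments across complete blocks.

    For a two-treatment complete block design with one observation per
    cell this paired t-test is exactly the fixed-effect test of the
    treatment term.  An all-zero difference vector yields t = 0, p = 1.
    """
    if table.n_treatments != 2:
        raise ValueError("blocked_two_group requires exactly 2 treatments")
    complete = table.complete_only()
    b = complete.n_blocks
    if b < min_blocks:
        raise ValueError(f"needs >= {min_blocks} complete blocks, got {b}")
    d = complete.values[:, 1] - complete.values[:, 0]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = b - 1
    if sd == 0.0:
        stat = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        stat = mean / (sd / np.sqrt(b))
        p = 2.0 * float(stats.t.sf(abs(stat), df))
    return PairedResult(
        treatments=(complete.treatments[0], complete.treatments[1]),
        mean_diff=mean,
        statistic=float(stat),
        df=df,
        p_value=p,
        n_blocks=b,
    )


def blocked_anova(table: BlockDesignTable):
    """Two-way block ANOVA (treatment + block, no interaction) on complete
    blocks; returns (F, df1, df2, p) plus Bonferroni paired-t follow-ups.

    With two treatments, F equals the squared paired t statistic.
    """
    complete = table.complete_only()
    vals = complete.values
    b, t = vals.shape
    if b < 2 or t < 2:
        raise ValueError("block ANOVA needs >= 2 complete blocks and >= 2 treatments")
    grand = vals.mean()
    ss_treat = b * float(np.sum((vals.mean(axis=0) - grand) ** 2))
    ss_block = t * float(np.sum((vals.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((vals - grand) ** 2))
    ss_err = ss_tot - ss_treat - ss_block
    df1 = t - 1
    df2 = (b - 1) * (t - 1)
    ms_err = ss_err / df2
    if ms_err <= 1e-15:
        f = 0.0 if ss_treat <= 1e-15 else np.inf
        p = 1.0 if ss_treat <= 1e-15 else 0.0
    else:
        f = (ss_treat / df1) / ms_err
        p = float(stats.f.sf(f, df1, df2))
    pairs = list(itertools.combinations(range(t), 2))
    pairwise = []
    for i, j in pairs:
        sub = BlockDesignTable(
            blocks=list(complete.blocks),
            treatments=[complete.treatments[i], complete.treatments[j]],
            values=vals[:, [i, j]],
        )
        res = blocked_two_group(sub, min_blocks=2)
        pairwise.append(
            ((complete.treatments[i], complete.treatments[j]),
             min(1.0, res.p_value * len(pairs)))
        )
    return {"statistic": f, "df1": df1, "df2": df2, "p_value": p, "pairwise": pairwise}


# ---------------------------------------------------------------------------
# composition report


def composition_report(
    composition: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    rank_variables: Sequence[str] = DEFAULT_RANK_VARIABLES,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-variable, per-follicle-type composition summary with tests.

    ``composition`` is a long table with columns female_id, type and the
    percentage variables.  For every variable the report gives the number
    of contributing females and follicles, mean and SD per follicle type
    (over follicles), and — when at least two types are present — omnibus
    and Bonferroni-adjusted pairwise p-values from the configured route
    (rank = Durbin; parametric = block ANOVA / paired t).  Blocks that do
    not observe every type for a variable are dropped for that variable's
    test, with the count logged.
    """
    if variables is None:
        variables = ["water_pct", "om_pct", "mineral_pct", "lipid_pct", "n_pct", "p_pct"]
    df = composition.copy()
    df["type"] = df["type"].astype(str).str.upper()

    mean_rows = []
    test_rows = []
    for var in variables:
        if var not in df.columns or df[var].dropna().empty:
            logger.info("composition report: variable %s absent, skipped", var)
            continue
        sub = df[["female_id", "type", var]].dropna()
        types = sorted(sub["type"].unique())
        for ftype in types:
            vals = sub.loc[sub["type"] == ftype, var]
            mean_rows.append(
                {
                    "variable": var,
                    "type": ftype,
                    "n_females": sub.loc[sub["type"] == ftype, "female_id"].nunique(),
                    "n_follicles": len(vals),
                    "mean_pct": float(vals.mean()),
                    "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
        if len(types) < 2:
            continue

        per_female = (
            sub.groupby(["female_id", "type"])[var].mean().reset_index()
        )
        table = BlockDesignTable.from_long(
            per_female["female_id"], per_female["type"], per_female[var]
        )
        complete = table.complete_only()
        if complete.n_blocks < 3:
            logger.info(
                "composition report: %s has %d complete blocks, test skipped",
                var, complete.n_blocks,
            )
            continue
        rule = "rank" if var in rank_variables else "parametric"
        if rule == "rank":
            omnibus = durbin_test(complete)
            pairwise = durbin_all_pairs(complete, alpha=alpha)
            stat, p = omnibus.statistic, omnibus.p_value
        else:
            res = blocked_anova(complete)
            stat, p = res["statistic"], res["p_value"]
            pairwise = res["pairwise"] if p < alpha else []
        row = {
            "variable": var,
            "rule": rule,
            "n_complete_blocks": complete.n_blocks,
            "statistic": stat,
            "p_value": p,
        }
        for (a, b_), padj in pairwise:
            row[f"p_{a}_vs_{b_}"] = padj
        test_rows.append(row)

    return {
        "means": pd.DataFrame(mean_rows),
        "tests": pd.DataFrame(test_rows),
    }
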