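"""End-to-end pipeline: simulate/read -> cluster -> account -> budget -> stats.

Stage order mirrors the analysis flow: the pooled diameter distribution is
tested for bimodality and clustered, the dominance threshold is derived
(or overridden), clutch accounting and the ovary-symmetry checks run next,
then the per-female energy budgets and cohort summary, and finally the
blocked yolk-composition comparisons.  Every output is written as CSV plus
a JSON manifest; identical config and seed reproduce identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from . import io as vio
from .accounting import follicle_growth_pct, ovary_symmetry_report, summarize_cohort
from .blockstats import DEFAULT_RANK_VARIABLES, composition_report
from .budget import (
    DryWeightModel,
    EnergeticConstants,
    cohort_budget_summary,
    female_budget,
    female_composition_means,
    fit_dry_weight_model,
    seasonal_follicle_comparison,
)
from .clustering import derive_dominance_threshold, dip_test, kmeans_1d, select_k
from .records import Cohort
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` (a CohortSpec) or the three input paths must be
    set.  ``threshold`` is "derive" or a numeric dominance threshold in mm.
    """

    simulate: Optional[CohortSpec] = None
    follicles_path: Optional[str] = None
    ovaries_path: Optional[str] = None
    composition_path: Optional[str] = None
    threshold: Union[str, float] = "derive"
    dry_weight_source: str = "printed"  # or "refit"
    constants: EnergeticConstants = field(default_factory=EnergeticConstants)
    alpha: float = 0.05
    n_monte_carlo: int = 999
    candidate_ks: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    rank_variables: tuple[str, ...] = DEFAULT_RANK_VARIABLES
    rng_seed: int = 0
    outdir: str = "vitellus_out"

    def validate(self) -> None:
        if self.simulate is None and not (self.follicles_path and self.ovaries_path):
            raise ValueError("config needs either a simulation spec or input paths")
        if isinstance(self.threshold, str):
            if self.threshold != "derive":
                raise ValueError("threshold must be 'derive' or a number")
        elif not (4.0 < float(self.threshold) < 37.0):
            raise ValueError("numeric threshold must lie in (4, 37) mm")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.dry_weight_source not in ("printed", "refit"):
            raise ValueError("dry_weight_source must be 'printed' or 'refit'")


@dataclass
class PipelineResult:
    outdir: str
    threshold_mm: float
    dip: object
    pooled_model: object
    dominant_model: object
    summary: pd.DataFrame
    budgets: list
    budget_summary: pd.DataFrame
    deficit_fraction: float
    mean_growth_pct: float
    seasonal: Optional[dict]
    symmetry: Optional[pd.DataFrame]
    composition: Optional[dict]
    manifest: dict
    truth: object = None


def _echo_config(config: PipelineConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [conv(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return conv(config)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    counts: dict[str, int] = {}
    truth = None

    # --- stage: input ------------------------------------------------------
    try:
        if config.simulate is not None:
            spec = dataclasses.replace(config.simulate, rng_seed=config.rng_seed)
            cohort, truth = generate_cohort(spec)
            vio.write_cohort(cohort, config.outdir)
        else:
            cohort = vio.read_cohort(
                config.follicles_path, config.ovaries_path, config.composition_path
            )
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineStageError("input", str(exc)) from exc
    counts["females"] = len(cohort)
    counts["follicles"] = len(cohort.all_follicles())

    # --- stage: clustering -------------------------------------------------
    try:
        diameters = np.asarray(cohort.pooled_diameters())
        if diameters.size < 4:
            raise ValueError("no (or too few) follicle diameters")
        dip = dip_test(diameters, n_monte_carlo=config.n_monte_carlo,
                       rng_seed=config.rng_seed)
        selection = select_k(diameters, config.candidate_ks)
        pooled_model = kmeans_1d(diameters, 2)
        if config.threshold == "derive":
            threshold = float(derive_dominance_threshold(pooled_model))
        else:
            threshold = float(config.threshold)
        dominant = diameters[diameters > threshold]
        dominant_model = kmeans_1d(dominant, 2) if np.unique(dominant).size >= 2 else None
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("clustering", str(exc)) from exc

    # --- stage: accounting -------------------------------------------------
    try:
        summary = summarize_cohort(cohort, threshold,
                                   config.constants.mean_clutch_size)
        growths = []
        for fem in cohort.females:
            try:
                growths.append(follicle_growth_pct(fem, threshold))
            except ValueError:
                logger.info("female %s skipped in growth computation", fem.female_id)
        mean_growth = float(np.mean(growths)) if growths else float("nan")
        n_paired = sum(1 for f in cohort.females if len(f.measured_ovaries()) == 2)
        symmetry = ovary_symmetry_report(cohort, threshold) if n_paired >= 2 else None
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("accounting", str(exc)) from exc
    counts["summaries"] = len(summary)

    # --- stage: budget -----------------------------------------------------
    try:
        if config.dry_weight_source == "refit":
            pairs = [
                (f.diameter_mm, f.dry_mass_g)
                for f in cohort.all_follicles()
                if f.dry_mass_g is not None
            ]
            model = fit_dry_weight_model(pairs)
        else:
            model = DryWeightModel()
        comp_means = female_composition_means(cohort)
        cohort_mean = None
        if comp_means:
            keys = ("lipid", "n", "p", "mineral")
            cohort_mean = {
                k: float(np.mean([m[k] for m in comp_means.values()])) for k in keys
            }
        budgets = []
        for fem in cohort.females:
            fracs = comp_means.get(fem.female_id) if comp_means else None
            if fracs is None and cohort_mean is not None:
                logger.info(
                    "female %s lacks composition data; cohort means used",
                    fem.female_id,
                )
                fracs = cohort_mean
            try:
                budgets.append(
                    female_budget(fem, threshold, model, config.constants, fracs)
                )
            except ValueError as exc:
                logger.info("budget skipped: %s", exc)
        if not budgets:
            raise ValueError("no female had a computable budget")
        budget_summary, deficit_fraction = cohort_budget_summary(
            budgets, config.constants
        )
        halves = set(summary["season_half"])
        seasonal = None
        if halves == {"first", "second"}:
            by_half = summary.groupby("season_half").size()
            if by_half.min() >= 2:
                seasonal = seasonal_follicle_comparison(summary)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("budget", str(exc)) from exc
    counts["budgets"] = len(budgets)

    # --- stage: composition stats ------------------------------------------
    composition = None
    try:
        if cohort.composition:
            comp_df = pd.DataFrame(
                {
                    "female_id": [c.female_id for c in cohort.composition],
                    "type": [c.follicle_type for c in cohort.composition],
                    "water_pct": [c.water_pct for c in cohort.composition],
                    "om_pct": [c.om_pct for c in cohort.composition],
                    "mineral_pct": [c.mineral_pct for c in cohort.composition],
                    "lipid_pct": [c.lipid_pct for c in cohort.composition],
                    "n_pct": [c.n_pct for c in cohort.composition],
                    "p_pct": [c.p_pct for c in cohort.composition],
                }
            )
            composition = composition_report(
                comp_df, rank_variables=config.rank_variables, alpha=config.alpha
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("composition", str(exc)) from exc

    # --- stage: report -----------------------------------------------------
    try:
        out = config.outdir
        clustering_rows = [
            {"quantity": "dip_D", "value": dip.statistic_D},
            {"quantity": "dip_p", "value": dip.p_value},
            {"quantity": "dip_n_monte_carlo", "value": dip.n_monte_carlo},
            {"quantity": "threshold_mm", "value": threshold},
            {"quantity": "elbow_k", "value": selection.elbow_k},
            {"quantity": "silhouette_k", "value": selection.silhouette_k},
            {"quantity": "pooled_centre_low_mm", "value": pooled_model.centres[0]},
            {"quantity": "pooled_centre_high_mm", "value": pooled_model.centres[1]},
            {"quantity": "min_of_upper_cluster_mm",
             "value": pooled_model.min_of_upper_cluster},
            {"quantity": "mean_growth_pct", "value": mean_growth},
        ]
        if dominant_model is not None:
            clustering_rows += [
                {"quantity": "dominant_centre_low_mm",
                 "value": dominant_model.centres[0]},
                {"quantity": "dominant_centre_high_mm",
                 "value": dominant_model.centres[1]},
            ]
        for k in selection.candidate_ks:
            if k in selection.total_within_ss_by_k:
                clustering_rows.append(
                    {"quantity": f"within_ss_k{k}",
                     "value": selection.total_within_ss_by_k[k]}
                )
            if k in selection.mean_silhouette_by_k:
                clustering_rows.append(
                    {"quantity": f"mean_silhouette_k{k}",
                     "value": selection.mean_silhouette_by_k[k]}
                )
        vio.write_table(pd.DataFrame(clustering_rows),
                        os.path.join(out, "clustering_report.csv"))
        vio.write_table(summary, os.path.join(out, "reproductive_summary.csv"))
        if symmetry is not None:
            vio.write_table(symmetry, os.path.join(out, "symmetry_report.csv"))

        budget_rows = []
        for b in budgets:
            row = {"female_id": b.female_id, "deficit": int(b.deficit),
                   "extrapolated": int(b.extrapolated)}
            for cat in ("deposited", "to_deposit", "to_resorb"):
                cb = b.category(cat)
                row[f"{cat}_yolk_g"] = cb.yolk_g
                row[f"{cat}_lipid_g"] = cb.lipid_g
                row[f"{cat}_n_g"] = cb.n_g
                row[f"{cat}_p_g"] = cb.p_g
                row[f"{cat}_cp_g"] = cb.cp_g
                row[f"{cat}_mineral_g"] = cb.mineral_g
                row[f"{cat}_energy_kj"] = cb.energy_kj
            budget_rows.append(row)
        vio.write_table(pd.DataFrame(budget_rows),
                        os.path.join(out, "energy_budget.csv"))
        vio.write_table(budget_summary, os.path.join(out, "budget_summary.csv"))
        if composition is not None:
            vio.write_table(composition["means"],
                            os.path.join(out, "composition_report.csv"))
            if not composition["tests"].empty:
                vio.write_table(composition["tests"],
                                os.path.join(out, "composition_tests.csv"))

        manifest = {
            "package_version": __version__,
            "rng_seed": config.rng_seed,
            "config": _echo_config(config),
            "row_counts": counts,
            "threshold_mm": threshold,
            "deficit_fraction": deficit_fraction,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("report", str(exc)) from exc

    return PipelineResult(
        outdir=config.outdir,
        threshold_mm=threshold,
        dip=dip,
        pooled_model=pooled_model,
        dominant_model=dominant_model,
        summary=summary,
        budgets=budgets,
        budget_summary=budget_summary,
        deficit_fraction=deficit_fraction,
        mean_growth_pct=mean_growth,
        seasonal=seasonal,
        symmetry=symmetry,
        composition=composition,
        manifest=manifest,
        truth=truth,
    )
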