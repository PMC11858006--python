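import numpy as np
import pandas as pd
import pytest

from vitellus.pipeline import PipelineConfig, run_pipeline
from vitellus.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort with its ground truth (seed 1)."""
    return generate_cohort(CohortSpec(rng_seed=1))


@pytest.fixture(scope="session")
def small_spec():
    """A fast, reduced-size cohort spec for plumbing tests."""
    return CohortSpec(
        n_females=8,
        mean_clutch_size=40,
        nondominant_count_per_ovary=40.0,
        rng_seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A full pipeline run on the default synthetic cohort (seed 1)."""
    outdir = tmp_path_factory.mktemp("pipeline_default")
    config = PipelineConfig(simulate=CohortSpec(), rng_seed=1, outdir=str(outdir))
    return run_pipeline(config)


def composition_frame(cohort):
    """Long-format composition table for a cohort (test helper)."""
    return pd.DataFrame(
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
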