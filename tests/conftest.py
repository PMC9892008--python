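from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests.helpers oracles

from strainshare.pipeline import RunConfig, run_all
from strainshare.simulate import SimulationConfig, simulate_all

SUITE_SEED = 11


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def suite(tmp_path_factory, default_config):
    """One default synthetic suite plus a full pipeline run, shared by all
    tests that read (not mutate) its outputs."""
    sim_dir = tmp_path_factory.mktemp("sim")
    out_dir = tmp_path_factory.mktemp("out")
    cohort, dsets, truth, snv, triads, fmt_dsets, triad_of = simulate_all(
        default_config, sim_dir
    )
    cfg = RunConfig(
        trees_dir=str(sim_dir / "trees"),
        metadata=str(sim_dir / "metadata.tsv"),
        snv_table=str(sim_dir / "trees" / "snv_rates.tsv"),
        out_dir=str(out_dir),
        seed=SUITE_SEED,
    )
    result = run_all(cfg)
    return {
        "sim_dir": sim_dir,
        "out_dir": out_dir,
        "cohort": cohort,
        "dsets": dsets,
        "truth": truth,
        "snv": snv,
        "triads": triads,
        "fmt_dsets": fmt_dsets,
        "triad_of": triad_of,
        "run_config": cfg,
        "result": result,
    }


@pytest.fixture()
def small_cohort() -> pd.DataFrame:
    """Hand-built cohort: two households in one village, one solo subject in
    another village of the same dataset, one foreign-dataset subject."""
    rows = [
        # household H1: mother, father, infant, with longitudinal samples
        ("mom1_t0", "mom1", "D1", "gut", 0, 30.0, "H1", "V1", None, None, True),
        ("mom1_t1", "mom1", "D1", "gut", 90, 30.0, "H1", "V1", None, None, True),
        ("dad1_t0", "dad1", "D1", "gut", 0, 33.0, "H1", "V1", None, None, True),
        ("kid1_t0", "kid1", "D1", "gut", 5, 0.5, "H1", "V1", "mom1", "dad1", True),
        # household H2: unrelated adult
        ("solo_t0", "solo", "D1", "gut", 10, 40.0, "H2", "V1", None, None, True),
        # different village, same dataset
        ("far_t0", "far", "D1", "gut", 10, 28.0, "H3", "V2", None, None, True),
        # different dataset
        ("ext_t0", "ext", "D2", "gut", 10, 50.0, "H9", "V9", None, None, False),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "subject_id",
            "dataset_id",
            "body_site",
            "collection_day",
            "age_years",
            "household_id",
            "village_id",
            "mother_id",
            "father_id",
            "westernized",
        ],
    )
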