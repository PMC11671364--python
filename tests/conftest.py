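import warnings

import numpy as np
import pandas as pd
import pytest

from urometab.cohort import CohortConfig, EffectSpec, generate_cohort
from urometab.preprocess import PreprocessConfig, preprocess_cohort

FLAT_STAGES = {s: 1.0 for s in ("I", "II", "III", "IV", "unknown")}


def pytest_configure(config):
    # the probability / penalty deprecations come from pinned sklearn APIs we
    # already avoid; silence anything that still leaks from inside sklearn
    warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture(scope="session")
def marker_cohort():
    """Small two-platform cohort with 5 planted pan-cancer markers among nulls."""
    planted = [EffectSpec(f"polar_{i:03d}", "cancer", 1.2, FLAT_STAGES)
               for i in range(1, 6)]
    cfg = CohortConfig(
        n_per_group={"LC": 60, "GC": 45, "CRC": 45, "NCD": 0, "HC": 150},
        platform_sizes={"polar": 40, "gc": 15},
        planted=planted, discovery_fraction=0.7, seed=101,
    )
    matrices, meta, truth = generate_cohort(cfg)
    return cfg, matrices, meta, truth


@pytest.fixture(scope="session")
def preprocessed_marker_cohort(marker_cohort):
    cfg, matrices, meta, truth = marker_cohort
    X, reports = preprocess_cohort(matrices, meta, PreprocessConfig(seed=7))
    return X, meta, truth, reports


@pytest.fixture(scope="session")
def origin_cohort():
    """Three cancer classes with disjoint planted marker sets (~4 SD separation)."""
    planted = (
        [EffectSpec(f"polar_{i:03d}", "LC", 2.7, FLAT_STAGES) for i in (1, 2, 3)]
        + [EffectSpec("gc_001", "LC", 2.7, FLAT_STAGES, direction=-1)]
        + [EffectSpec(f"polar_{i:03d}", "GC", 2.7, FLAT_STAGES) for i in (10, 11)]
        + [EffectSpec("gc_010", "GC", 2.7, FLAT_STAGES, direction=-1)]
    )
    cfg = CohortConfig(
        n_per_group={"LC": 150, "GC": 120, "CRC": 120, "NCD": 0, "HC": 0},
        platform_sizes={"polar": 40, "gc": 30}, planted=planted,
        discovery_fraction=0.65, seed=33,
    )
    matrices, meta, truth = generate_cohort(cfg)
    X, _ = preprocess_cohort(matrices, meta, PreprocessConfig(seed=1))
    return X, meta, truth


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run (small cohort, strong effects), reused widely."""
    import dataclasses
    import warnings as _warnings

    from urometab.pipeline import RunConfig, demo_cohort_config, run_pipeline

    out = tmp_path_factory.mktemp("demo_run")
    cfg = RunConfig(
        cohort=dataclasses.replace(demo_cohort_config(), n_per_group={
            "LC": 60, "GC": 40, "CRC": 40, "NCD": 40, "HC": 40}),
        selection=dataclasses.replace(RunConfig().selection, n_rounds=15),
        n_boot=100, seed=11,
    )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        metrics = run_pipeline(cfg, outdir=out)
    return cfg, metrics, out


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with zero planted effects, for null-calibration checks."""
    cfg = CohortConfig(
        n_per_group={"LC": 50, "GC": 25, "CRC": 25, "NCD": 0, "HC": 100},
        platform_sizes={"polar": 30}, planted=[], discovery_fraction=0.7, seed=55,
    )
    matrices, meta, truth = generate_cohort(cfg)
    X, _ = preprocess_cohort(matrices, meta, PreprocessConfig(seed=9))
    return X, meta
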