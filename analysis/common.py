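"""Shared configuration for the numbered analysis scripts.

One seed and one cohort configuration drive the whole analysis so that the
scripts compose: 01 writes the cohort, later scripts read the artifacts of
the earlier ones from results/.
"""

from pathlib import Path

from urometab.pipeline import RunConfig, demo_cohort_config

SEED = 2024
RESULTS = Path(__file__).resolve().parent.parent / "results"


def analysis_config() -> RunConfig:
    """Demo-scale cohort with planted pan-cancer, LC and GC marker sets."""
    import dataclasses

    return RunConfig(
        cohort=demo_cohort_config(),
        selection=dataclasses.replace(RunConfig().selection, n_rounds=25),
        n_boot=500,
        seed=SEED,
    )
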