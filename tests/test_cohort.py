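"""Generator behavior: determinism, planted effects, corruption bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from urometab.cohort import (CANCER_GROUPS, CohortConfig, EffectSpec,
                             MissingnessSpec, corrupt, generate_cohort,
                             platform_feature_ids, simulate_truth,
                             validate_metadata)

FLAT = {s: 1.0 for s in ("I", "II", "III", "IV", "unknown")}


def small_config(**kw):
    base = dict(
        n_per_group={"LC": 30, "GC": 20, "CRC": 20, "NCD": 25, "HC": 25},
        platform_sizes={"polar": 25, "gc": 10},
        seed=5,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestSimulateTruth:
    def test_group_and_stage_counts_match_config(self):
        cfg = CohortConfig(
            n_per_group={"LC": 431, "GC": 142, "CRC": 140, "NCD": 422, "HC": 172},
            platform_sizes={"polar": 5},
        )
        _, meta = simulate_truth(cfg)
        counts = meta["group"].value_counts()
        assert counts["LC"] == 431 and counts["GC"] == 142 and counts["CRC"] == 140
        assert int(meta["group"].isin(CANCER_GROUPS).sum()) == 713
        # stage counts follow the configured mix by largest-remainder
        lc_stage = meta.loc[meta["group"] == "LC", "stage"].value_counts()
        assert abs(lc_stage["I"] - 431 * 0.30) < 1
        validate_metadata(meta)

    def test_no_planted_effects_means_no_group_difference(self):
        cfg = small_config(n_per_group={"LC": 200, "GC": 0, "CRC": 0, "NCD": 0, "HC": 200})
        latent, meta = simulate_truth(cfg)
        log2 = np.log2(latent["polar"])
        diff = (log2[meta["group"] == "LC"].mean() - log2[meta["group"] == "HC"].mean())
        # Monte-Carlo error of a mean difference at n=200/group, sd=0.6
        assert diff.abs().max() < 0.35

    def test_planted_effect_recovers_at_stated_n(self):
        eff = EffectSpec("polar_001", "cancer", base_log2_effect=2.0,
                         stage_multipliers=FLAT)
        cfg = small_config(
            n_per_group={"LC": 500, "GC": 0, "CRC": 0, "NCD": 0, "HC": 500},
            planted=[eff], seed=17,
        )
        latent, meta = simulate_truth(cfg)
        log2 = np.log2(latent["polar"]["polar_001"])
        observed = log2[meta["group"] == "LC"].mean() - log2[meta["group"] == "HC"].mean()
        assert observed == pytest.approx(2.0, abs=0.15)

    def test_unknown_planted_feature_rejected(self):
        cfg = small_config(planted=[EffectSpec("nope_001", "cancer")])
        with pytest.raises(ValueError, match="unknown feature"):
            simulate_truth(cfg)

    def test_stage_multipliers_modulate_effect(self):
        eff = EffectSpec("polar_001", "cancer", base_log2_effect=2.0,
                         stage_multipliers={"I": 0.0, "II": 1.0, "III": 1.0,
                                            "IV": 1.0, "unknown": 1.0})
        cfg = small_config(
            n_per_group={"LC": 600, "GC": 0, "CRC": 0, "NCD": 0, "HC": 600},
            planted=[eff], seed=19,
        )
        latent, meta = simulate_truth(cfg)
        log2 = np.log2(latent["polar"]["polar_001"])
        hc_mean = log2[meta["group"] == "HC"].mean()
        stage1 = log2[(meta["group"] == "LC") & (meta["stage"] == "I")].mean()
        stage2 = log2[(meta["group"] == "LC") & (meta["stage"] == "II")].mean()
        assert stage1 - hc_mean == pytest.approx(0.0, abs=0.3)
        assert stage2 - hc_mean == pytest.approx(2.0, abs=0.3)


class TestCorrupt:
    def test_noise_free_output_equals_latent(self):
        cfg = small_config(dilution_log_sd=0.0, batch_log_sd=0.0, noise_log_sd=0.0,
                           missingness=MissingnessSpec(0.5, 0.0, 0.0), qc_per_batch=0)
        latent, meta = simulate_truth(cfg)
        matrices, _ = corrupt(latent, meta, cfg)
        subj = matrices["polar"].subject_values()
        pd.testing.assert_frame_equal(subj, latent["polar"], check_exact=False, rtol=1e-12)

    def test_qc_row_count(self):
        cfg = small_config(n_batches=4, qc_per_batch=3)
        latent, meta = simulate_truth(cfg)
        matrices, _ = corrupt(latent, meta, cfg)
        assert int(matrices["polar"].is_qc.sum()) == 12

    def test_censoring_targets_low_intensities(self):
        cfg = small_config(
            missingness=MissingnessSpec(mnar_intensity_quantile=0.3,
                                        mnar_max_prob=0.5, mcar_prob=0.0),
            seed=23,
        )
        latent, meta = simulate_truth(cfg)
        matrices, _ = corrupt(latent, meta, cfg)
        fm = matrices["gc"]
        # reconstruct the pre-censoring intensity ranks from the latent matrix
        lat = np.log(latent["gc"].to_numpy()).ravel()
        missing = fm.subject_values().isna().to_numpy().ravel()
        deciles = pd.qcut(lat, 10, labels=False)
        low = missing[deciles == 0].mean()
        high = missing[deciles == 9].mean()
        assert low > high

    def test_dilution_bookkeeping_recovers_latent(self):
        cfg = small_config(dilution_log_sd=0.5, batch_log_sd=0.0, noise_log_sd=0.0,
                           missingness=MissingnessSpec(0.5, 0.0, 0.0))
        latent, meta = simulate_truth(cfg)
        matrices, truth = corrupt(latent, meta, cfg)
        recovered = matrices["polar"].subject_values().div(truth.dilution, axis=0)
        pd.testing.assert_frame_equal(recovered, latent["polar"],
                                      check_exact=False, rtol=1e-9)


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        cfg = small_config()
        m1, meta1, _ = generate_cohort(cfg)
        m2, meta2, _ = generate_cohort(small_config())
        pd.testing.assert_frame_equal(meta1, meta2)
        for p in m1:
            pd.testing.assert_frame_equal(m1[p].values, m2[p].values)

    def test_stratified_split_proportions(self):
        cfg = small_config(
            n_per_group={"LC": 100, "GC": 50, "CRC": 50, "NCD": 80, "HC": 60},
            discovery_fraction=0.77,
        )
        _, meta, _ = generate_cohort(cfg)
        for group, sub in meta.groupby("group"):
            n_disc = (sub["cohort"] == "discovery").sum()
            assert abs(n_disc - 0.77 * len(sub)) <= 1

    def test_default_platform_sizes(self):
        ids = platform_feature_ids()
        assert [len(ids[p]) for p in ("polar", "lipid", "gc")] == [125, 13, 222]
        cfg = CohortConfig(n_per_group={"LC": 5, "GC": 5, "CRC": 5, "NCD": 5, "HC": 5})
        matrices, _, _ = generate_cohort(cfg)
        assert {p: m.values.shape[1] for p, m in matrices.items()} == {
            "polar": 125, "lipid": 13, "gc": 222}

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortConfig(stage_fractions={"I": 0.5, "II": 0.5, "III": 0.5,
                                          "IV": 0.0, "unknown": 0.0})
        with pytest.raises(ValueError, match="nonnegative"):
            small_config(dilution_log_sd=-1.0)
        with pytest.raises(ValueError, match="unknown groups"):
            CohortConfig(n_per_group={"XX": 5})
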