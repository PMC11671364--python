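"""Preprocessing stages: filter, imputation routing, MSTUS, QC correction, scaling."""

import numpy as np
import pandas as pd
import pytest

from urometab.cohort import (CohortConfig, FeatureMatrix, MissingnessSpec,
                             generate_cohort)
from urometab.preprocess import (PreprocessConfig, filter_features, impute,
                                 log_scale, mstus_normalize, preprocess,
                                 qc_batch_correct, qc_rsd)


def make_fm(values, batch=None, is_qc=None, platform="polar"):
    values = pd.DataFrame(values)
    values.index = [f"S{i}" for i in range(len(values))]
    values.columns = [f"f{j}" for j in range(values.shape[1])]
    batch = pd.Series(batch if batch is not None else ["B1"] * len(values),
                      index=values.index)
    is_qc = pd.Series(is_qc if is_qc is not None else [False] * len(values),
                      index=values.index)
    return FeatureMatrix(platform, values, batch, is_qc)


class TestDetectionFilter:
    @pytest.mark.parametrize("n_observed,kept", [(79, False), (80, True), (100, True)])
    def test_80_percent_boundary(self, n_observed, kept):
        col = np.full(100, np.nan)
        col[:n_observed] = 10.0
        fm = make_fm(np.column_stack([col, np.full(100, 5.0)]))
        out, dropped = filter_features(fm, 0.80)
        assert ("f0" in out.feature_ids) is kept
        assert ("f0" in dropped) is (not kept)

    def test_complete_matrix_unchanged(self):
        fm = make_fm(np.full((10, 3), 2.0))
        out, dropped = filter_features(fm, 0.8)
        assert dropped == []
        pd.testing.assert_frame_equal(out.values, fm.values)

    def test_all_dropped_is_an_error(self):
        vals = np.full((10, 2), np.nan)
        vals[0, :] = 1.0
        with pytest.raises(ValueError, match="below detection"):
            filter_features(make_fm(vals), 0.8)

    def test_detection_ignores_qc_rows(self):
        vals = np.full((10, 1), 5.0)
        vals[8:, 0] = np.nan  # the two QC rows are missing
        fm = make_fm(vals, is_qc=[False] * 8 + [True] * 2)
        out, dropped = filter_features(fm, 0.9)
        assert dropped == []


class TestImpute:
    def test_half_minimum_route(self):
        vals = np.array([[8.0], [10.0], [12.0], [np.nan]])
        fm = make_fm(vals)
        cfg = PreprocessConfig(impute_missing_rate_threshold=0.1)  # force half-min
        out, routes = impute(fm, cfg)
        assert out.values.iloc[3, 0] == pytest.approx(4.0)
        assert set(routes["route"]) == {"half-minimum"}

    def test_complete_matrix_untouched(self):
        fm = make_fm(np.full((6, 2), 3.0))
        out, routes = impute(fm, PreprocessConfig())
        pd.testing.assert_frame_equal(out.values, fm.values)
        assert set(routes["route"]) == {"none"}

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 1, size=(30, 6))
        drop = rng.random(size=vals.shape) < 0.2
        masked = np.where(drop, np.nan, vals)
        fm = make_fm(masked)
        out, _ = impute(fm, PreprocessConfig(seed=4))
        observed = ~np.isnan(masked)
        np.testing.assert_array_equal(out.values.to_numpy()[observed], masked[observed])
        assert not out.values.isna().any().any()

    def test_iterative_beats_half_minimum_on_correlated_features(self):
        rng = np.random.default_rng(11)
        n = 80
        base = rng.normal(10, 1, size=n)
        f0 = np.exp2(base)
        f1 = np.exp2(base + rng.normal(0, 0.14, size=n))  # r ~ 0.99 in log space
        others = np.exp2(rng.normal(10, 1, size=(n, 3)))
        vals = np.column_stack([f0, f1, others])
        truth = vals[0, 1]
        masked = vals.copy()
        masked[0, 1] = np.nan
        fm = make_fm(masked)
        cfg = PreprocessConfig(seed=2, impute_missing_rate_threshold=0.3,
                               impute_intensity_quantile_threshold=0.01)
        out, routes = impute(fm, cfg)
        route = routes.set_index("feature_id").loc["f1", "route"]
        assert route == "iterative"
        iterative_err = abs(np.log2(out.values.iloc[0, 1]) - np.log2(truth))
        halfmin_err = abs(np.log2(np.nanmin(masked[:, 1]) / 2) - np.log2(truth))
        assert iterative_err < halfmin_err

    def test_batchwise_feature_all_missing_uses_global_half_min(self):
        vals = np.array([[4.0], [6.0], [np.nan], [np.nan]])
        fm = make_fm(vals, batch=["B1", "B1", "B2", "B2"])
        with pytest.warns(UserWarning, match="entirely missing"):
            out, routes = impute(fm, PreprocessConfig())
        assert out.values.iloc[2, 0] == pytest.approx(2.0)  # half of global min 4


class TestMSTUS:
    def test_arithmetic(self):
        fm = make_fm(np.array([[2.0, 4.0, 6.0]]))
        out, denom = mstus_normalize(fm)
        np.testing.assert_allclose(out.values.to_numpy(), [[2 / 12, 4 / 12, 6 / 12]])
        assert denom.iloc[0] == 12.0

    def test_dilution_invariance_exact(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 1, size=(5, 8))
        fm1 = make_fm(vals)
        fm2 = make_fm(vals * rng.lognormal(0, 1, size=(5, 1)))
        out1, _ = mstus_normalize(fm1)
        out2, _ = mstus_normalize(fm2)
        np.testing.assert_allclose(out1.values.to_numpy(), out2.values.to_numpy(),
                                   rtol=1e-12)

    def test_removes_simulated_dilution(self):
        cfg = CohortConfig(
            n_per_group={"LC": 30, "GC": 0, "CRC": 0, "NCD": 0, "HC": 30},
            platform_sizes={"polar": 40}, dilution_log_sd=0.5, batch_log_sd=0.0,
            noise_log_sd=0.0, missingness=MissingnessSpec(0.5, 0.0, 0.0), seed=9,
        )
        matrices, meta, truth = generate_cohort(cfg)
        fm = matrices["polar"]
        out, _ = mstus_normalize(fm)
        norm = out.subject_values()
        lat = truth.latent["polar"]
        for sid in norm.index:
            r = np.corrcoef(norm.loc[sid], lat.loc[sid])[0, 1]
            assert r > 0.999

    def test_nonpositive_denominator_rejected(self):
        fm = make_fm(np.array([[np.nan, np.nan]]))
        with pytest.raises(ValueError, match="denominator"):
            mstus_normalize(fm, useful_features=["f0", "f1"])


class TestQCBatchCorrection:
    def _cohort(self, batch_sd, seed=13):
        cfg = CohortConfig(
            n_per_group={"LC": 20, "GC": 0, "CRC": 0, "NCD": 0, "HC": 20},
            platform_sizes={"polar": 30}, n_batches=4, qc_per_batch=4,
            batch_log_sd=batch_sd, noise_log_sd=0.1, dilution_log_sd=0.0,
            missingness=MissingnessSpec(0.5, 0.0, 0.0), seed=seed,
        )
        matrices, _, _ = generate_cohort(cfg)
        return matrices["polar"]

    def test_single_batch_identity(self):
        vals = np.exp2(np.random.default_rng(1).normal(10, 1, size=(8, 4)))
        fm = make_fm(vals, is_qc=[False] * 6 + [True] * 2)
        out, shifts = qc_batch_correct(fm)
        np.testing.assert_allclose(out.values.to_numpy(), vals, rtol=1e-9)
        np.testing.assert_allclose(shifts.to_numpy(), 0.0, atol=1e-12)

    def test_qc_rsd_strictly_decreases(self):
        fm = self._cohort(batch_sd=0.5)
        before = qc_rsd(fm).median()
        out, _ = qc_batch_correct(fm)
        after = qc_rsd(out).median()
        assert after < before

    def test_null_batch_effects_give_small_corrections(self):
        fm = self._cohort(batch_sd=0.0)
        _, shifts = qc_batch_correct(fm)
        # only QC measurement noise (sd 0.1 ln ~ 0.14 log2) remains
        assert np.abs(shifts.to_numpy()).mean() < 0.15

    def test_missing_qc_in_batch_is_an_error(self):
        vals = np.exp2(np.random.default_rng(1).normal(10, 1, size=(6, 3)))
        fm = make_fm(vals, batch=["B1"] * 3 + ["B2"] * 3,
                     is_qc=[False, False, True, False, False, False])
        with pytest.raises(ValueError, match="B2"):
            qc_batch_correct(fm)


class TestLogScale:
    def test_unit_variance_on_discovery(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(5, 1, size=(40, 6))
        fm = make_fm(vals)
        disc = [f"S{i}" for i in range(25)]
        out, center, scale = log_scale(fm, PreprocessConfig(), discovery_ids=disc)
        got = out.values.loc[disc]
        np.testing.assert_allclose(got.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(got.std(ddof=0), 1.0, rtol=1e-9)
        # validation rows are transformed with discovery parameters
        val = out.values.drop(index=disc)
        assert not np.allclose(val.mean(), 0.0, atol=1e-3)

    def test_mode_none_is_plain_log(self):
        fm = make_fm(np.array([[8.0]]))
        out, center, scale = log_scale(fm, PreprocessConfig(scaling_mode="none"))
        assert out.values.iloc[0, 0] == pytest.approx(3.0)
        assert center is None and scale is None

    def test_nonpositive_value_is_located(self):
        fm = make_fm(np.array([[2.0], [1.0]]), platform="gc")
        fm.values.iloc[1, 0] = 0.0
        fm.require_positive = False
        with pytest.raises(ValueError, match="S1"):
            log_scale(fm, PreprocessConfig())


class TestFullPipeline:
    def test_deterministic_and_complete(self, marker_cohort):
        cfg, matrices, meta, _ = marker_cohort
        disc = list(meta.index[meta["cohort"] == "discovery"])
        out1, rep1 = preprocess(matrices["polar"], PreprocessConfig(seed=3), disc)
        out2, _ = preprocess(matrices["polar"], PreprocessConfig(seed=3), disc)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        assert not out1.values.isna().any().any()
        assert rep1.qc_rsd_after.median() <= rep1.qc_rsd_before.median()
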