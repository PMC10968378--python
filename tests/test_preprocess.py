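import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mirwoi.matrix import StageError
from mirwoi.preprocess import (
    PreprocessConfig,
    PreprocessError,
    PreprocessParams,
    apply_imputation,
    apply_pca,
    apply_preprocess,
    apply_quantile_reference,
    apply_scaler,
    drop_zero_variance,
    filter_low_amplification,
    fit_pca,
    fit_preprocess,
    fit_scaler,
    impute_missing,
    quantile_normalize,
)
from tests.conftest import make_matrix


class TestQuantileNormalize:
    def test_two_complete_rows_hand_example(self):
        # rows [2,4,6] and [3,5,7]: rank means are (2.5, 4.5, 6.5)
        fm = make_matrix([[2.0, 4.0, 6.0], [3.0, 5.0, 7.0]])
        out, ref = quantile_normalize(fm)
        np.testing.assert_allclose(ref, [2.5, 4.5, 6.5])
        np.testing.assert_allclose(out.values, [[2.5, 4.5, 6.5], [2.5, 4.5, 6.5]])
        assert out.stage == "quantile_normalized"

    def test_identical_rows_unchanged(self):
        fm = make_matrix([[1.0, 5.0, 9.0]] * 3)
        out, _ = quantile_normalize(fm)
        np.testing.assert_allclose(out.values, fm.values)

    def test_complete_rows_share_sorted_values(self):
        rng = np.random.default_rng(0)
        fm = make_matrix(rng.normal(28, 3, size=(6, 9)))
        out, _ = quantile_normalize(fm)
        sorted_rows = np.sort(out.values, axis=1)
        for r in range(1, 6):
            np.testing.assert_allclose(sorted_rows[r], sorted_rows[0])

    def test_missing_entries_stay_missing(self):
        fm = make_matrix([[2.0, np.nan, 6.0], [3.0, 5.0, 7.0], [1.0, 4.0, 8.0]])
        out, _ = quantile_normalize(fm)
        assert np.isnan(out.values[0, 1])
        assert np.isnan(out.values).sum() == 1

    def test_ties_get_mean_of_tied_reference_positions(self):
        fm = make_matrix([[5.0, 5.0, 9.0], [1.0, 2.0, 3.0]])
        out, ref = quantile_normalize(fm)
        # tied pair occupies rank positions 0 and 1 -> mean(ref[0], ref[1])
        expected = np.mean(ref[:2])
        assert out.values[0, 0] == pytest.approx(expected)
        assert out.values[0, 1] == pytest.approx(expected)

    def test_row_with_single_value_rejected(self):
        fm = make_matrix([[2.0, np.nan, np.nan], [3.0, 5.0, 7.0]])
        with pytest.raises(PreprocessError, match="P1"):
            quantile_normalize(fm)

    def test_wrong_stage_rejected(self):
        fm = make_matrix([[1.0, 2.0]], stage="scaled")
        with pytest.raises(StageError):
            quantile_normalize(fm)

    @given(hnp.arrays(np.float64, (4, 6),
                      elements=st.floats(1.0, 39.0, allow_nan=False)))
    @settings(max_examples=40, deadline=None)
    def test_rank_order_preserved(self, values):
        fm = make_matrix(values)
        out, _ = quantile_normalize(fm)
        for r in range(values.shape[0]):
            orig = np.argsort(values[r], kind="stable")
            mapped = out.values[r]
            assert np.all(np.diff(mapped[orig]) >= -1e-12)


class TestApplyQuantileReference:
    def test_row_equal_to_reference_unchanged(self):
        ref = np.array([1.0, 4.0, 9.0])
        fm = make_matrix([[1.0, 4.0, 9.0]])
        out = apply_quantile_reference(fm, ref)
        np.testing.assert_allclose(out.values, [[1.0, 4.0, 9.0]])

    def test_monotone_row_stays_monotone(self):
        ref = np.array([1.0, 2.0, 5.0, 6.0])
        fm = make_matrix([[10.0, 11.0, 12.0, 13.0]])
        out = apply_quantile_reference(fm, ref)
        assert np.all(np.diff(out.values[0]) >= 0)

    def test_shorter_row_hits_interpolated_quantiles(self):
        # 3 observed values vs a length-5 reference: quantiles 0, 0.5, 1
        ref = np.array([1.0, 2.0, 3.0, 5.0, 9.0])
        fm = make_matrix([[100.0, 50.0, 200.0, np.nan, np.nan]])
        out = apply_quantile_reference(fm, ref)
        obs = out.values[0][~np.isnan(out.values[0])]
        np.testing.assert_allclose(sorted(obs), [1.0, 3.0, 9.0])

    def test_empty_reference_rejected(self):
        fm = make_matrix([[1.0, 2.0]])
        with pytest.raises(PreprocessError):
            apply_quantile_reference(fm, np.array([]))


class TestFilter:
    def test_exact_boundary_retained(self):
        vals = np.ones((10, 2))
        vals[0, 0] = np.nan  # 10% missing: retained
        vals[:2, 1] = np.nan  # 20% missing: removed
        fm = make_matrix(vals, stage="quantile_normalized")
        out, removed = filter_low_amplification(fm, 0.10)
        assert removed == ["miR-2"]
        assert out.feature_ids == ["miR-1"]
        assert out.stage == "filtered"

    def test_complete_feature_retained(self):
        fm = make_matrix(np.ones((5, 3)), stage="quantile_normalized")
        out, removed = filter_low_amplification(fm)
        assert removed == []
        assert out.n_features == 3

    def test_all_removed_is_error(self):
        fm = make_matrix(np.full((4, 2), np.nan), stage="quantile_normalized")
        with pytest.raises(PreprocessError):
            filter_low_amplification(fm)

    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_filter_monotone_in_threshold(self, t_low, t_high):
        t_low, t_high = sorted((t_low, t_high))
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(20, 8))
        vals[rng.random(vals.shape) < 0.25] = np.nan
        fm = make_matrix(vals, stage="quantile_normalized")
        try:
            kept_low = set(filter_low_amplification(fm, t_low)[0].feature_ids)
            kept_high = set(filter_low_amplification(fm, t_high)[0].feature_ids)
        except PreprocessError:
            return
        assert kept_low <= kept_high


class TestImpute:
    def test_missing_cells_become_global_max(self):
        fm = make_matrix([[38.2, 20.0], [np.nan, 25.0]], stage="filtered")
        out, value = impute_missing(fm)
        assert value == 38.2
        assert out.values[1, 0] == 38.2
        assert out.stage == "imputed"

    def test_no_missing_is_identity_with_max(self):
        fm = make_matrix([[1.0, 2.0], [3.0, 4.0]], stage="filtered")
        out, value = impute_missing(fm)
        assert value == 4.0
        np.testing.assert_array_equal(out.values, fm.values)

    def test_observed_cells_untouched(self):
        vals = np.array([[30.0, np.nan], [20.0, 25.0]])
        fm = make_matrix(vals, stage="filtered")
        out, _ = impute_missing(fm)
        assert out.values[0, 0] == 30.0
        assert out.values[1, 0] == 20.0
        assert out.values[1, 1] == 25.0

    def test_per_feature_mode(self):
        fm = make_matrix([[10.0, np.nan], [np.nan, 25.0], [12.0, 20.0]],
                         stage="filtered")
        out, value = impute_missing(fm, per_feature=True)
        np.testing.assert_allclose(value, [12.0, 25.0])
        assert out.values[1, 0] == 12.0
        assert out.values[0, 1] == 25.0

    def test_imputed_value_dominates_observed(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(25, 4, size=(8, 5))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        fm = make_matrix(vals, stage="filtered")
        out, value = impute_missing(fm)
        assert value >= np.nanmax(vals)

    def test_entirely_missing_rejected(self):
        fm = make_matrix(np.full((2, 2), np.nan), stage="filtered")
        with pytest.raises(PreprocessError):
            impute_missing(fm)


class TestScaler:
    def test_hand_example_sample_sd(self):
        fm = make_matrix([[1.0], [2.0], [3.0]], stage="imputed")
        means, sds = fit_scaler(fm)
        assert means[0] == 2.0 and sds[0] == pytest.approx(1.0)  # ddof=1
        out = apply_scaler(fm, means, sds)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_feature_rejected(self):
        fm = make_matrix([[1.0, 5.0], [1.0, 6.0]], stage="imputed")
        with pytest.raises(PreprocessError, match="miR-1"):
            fit_scaler(fm)

    def test_training_columns_centered(self):
        rng = np.random.default_rng(1)
        fm = make_matrix(rng.normal(20, 5, (12, 4)), stage="imputed")
        means, sds = fit_scaler(fm)
        out = apply_scaler(fm, means, sds)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0)


class TestPCA:
    def test_line_geometry_single_component(self):
        t = np.linspace(-2, 2, 10)
        fm = make_matrix(np.column_stack([t, t]), stage="scaled")
        pca = fit_pca(fm, n_components=1)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(2)
        fm = make_matrix(rng.normal(size=(15, 6)), stage="scaled")
        pca = fit_pca(fm, n_components=4)
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_variance_ratios_non_increasing_and_bounded(self):
        rng = np.random.default_rng(4)
        fm = make_matrix(rng.normal(size=(20, 7)), stage="scaled")
        pca = fit_pca(fm, variance_target=0.99)
        ratios = pca.explained_variance_ratio
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1.0 + 1e-12

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        fm = make_matrix(rng.normal(size=(10, 5)), stage="scaled")
        pca = fit_pca(fm, n_components=3)
        for j in range(3):
            assert pca.loadings[np.argmax(np.abs(pca.loadings[:, j])), j] > 0

    def test_components_beyond_rank_rejected(self):
        fm = make_matrix(np.ones((3, 5)) * np.arange(5), stage="scaled")
        with pytest.raises(PreprocessError):
            fit_pca(fm, n_components=4)


class TestFitApplyPreprocess:
    def _train(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(27, 3, size=(20, 12))
        vals[rng.random(vals.shape) < 0.05] = np.nan
        return make_matrix(vals)

    def test_apply_matches_stagewise_pipeline(self):
        train = self._train()
        cfg = PreprocessConfig(variance_target=0.95)
        params = fit_preprocess(train, cfg)
        replay = apply_preprocess(train, params)

        qn, _ = quantile_normalize(train)
        filt, _ = filter_low_amplification(qn, cfg.max_missing_fraction)
        imp, _ = impute_missing(filt)
        imp, _ = drop_zero_variance(imp)
        means, sds = fit_scaler(imp)
        scaled = apply_scaler(imp, means, sds)
        stagewise = apply_pca(scaled, params.pca)
        np.testing.assert_allclose(replay.values, stagewise.values, atol=1e-10)

    def test_heldout_missing_retained_feature_gets_imputation_value(self):
        train = self._train()
        params = fit_preprocess(train)
        held = self._train()
        held.values[0, :] = 25.0
        held.values[0, 3] = np.nan
        imputed = apply_preprocess(held, params, stop_at="imputed")
        fid = train.feature_ids[3]
        if fid in params.retained_features:
            j = params.retained_features.index(fid)
            assert imputed.values[0, j] == params.imputation_value

    def test_deterministic_replay(self):
        train = self._train()
        params = fit_preprocess(train)
        a = apply_preprocess(train, params)
        b = apply_preprocess(train, params)
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_retained_feature_is_error(self):
        train = self._train()
        params = fit_preprocess(train)
        narrower = make_matrix(train.values[:, :5],
                               feature_ids=train.feature_ids[:5])
        with pytest.raises(PreprocessError, match="retained"):
            apply_preprocess(narrower, params)

    def test_params_json_round_trip(self, tmp_path):
        params = fit_preprocess(self._train())
        path = tmp_path / "params.json"
        params.save(path)
        back = PreprocessParams.load(path)
        np.testing.assert_array_equal(back.quantile_reference, params.quantile_reference)
        np.testing.assert_array_equal(back.pca.loadings, params.pca.loadings)
        assert back.retained_features == params.retained_features
        assert back.imputation_value == params.imputation_value

    def test_unknown_schema_version_rejected(self):
        params = fit_preprocess(self._train())
        d = params.to_dict()
        d["schema_version"] = 99
        with pytest.raises(PreprocessError, match="schema_version"):
            PreprocessParams.from_dict(d)
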