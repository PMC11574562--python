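"""Curation filter, feature reduction, log scaling, quantile normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metaboscreen as ms
from metaboscreen.preprocess import FilterConfig
from metaboscreen.synthetic import MetaboliteRecord

from conftest import make_matrix


def _lib(origins):
    return [MetaboliteRecord(f"M{j+1:02d}", f"M{j+1:02d}", 100.0 + j,
                             origin, 100.0, 5.0)
            for j, origin in enumerate(origins)]


class TestCurationFilter:
    def test_removes_nonhuman_features(self):
        mat = make_matrix(np.ones((3, 5)))
        lib = _lib(["human", "human", "drug", "human", "human"])
        out = ms.filter_nonhuman(mat, lib)
        assert out.shape == (3, 4)
        assert "M03" not in out.feature_ids

    def test_all_human_matrix_unchanged_but_logged(self):
        mat = make_matrix(np.ones((2, 3)))
        out = ms.filter_nonhuman(mat, _lib(["human"] * 3))
        pd.testing.assert_frame_equal(out.values, mat.values)
        assert out.transform_log[-1].startswith("curated")

    def test_exact_fraction_from_generator(self, small_library):
        ids = [r.metabolite_id for r in small_library]
        mat = make_matrix(np.ones((2, 60)), feature_ids=ids)
        out = ms.filter_nonhuman(mat, small_library)
        assert out.shape[1] == 48  # 60 features, exactly 20% non-human

    def test_unknown_feature_is_named_in_error(self):
        mat = make_matrix(np.ones((2, 2)), feature_ids=["M01", "MX"])
        with pytest.raises(KeyError, match="MX"):
            ms.filter_nonhuman(mat, _lib(["human", "human"]))


class TestFeatureReduction:
    def test_prevalence_boundary_inclusive(self):
        col_rare = [1.0] + [np.nan] * 9          # 1/10 -> dropped
        col_edge = [1.0, 1.0] + [np.nan] * 8     # 2/10 -> kept (boundary)
        mat = make_matrix(np.c_[col_rare, col_edge, np.ones(10)])
        out = ms.apply_feature_filter(
            mat, FilterConfig(mode="prevalence", min_presence_fraction=0.2))
        assert out.feature_ids == ["M02", "M03"]

    def test_abundance_mode_matches_hand_ranking(self):
        # 10 features with increasing means; k=20% drops exactly the 2 lowest
        values = np.tile(10.0 ** np.arange(1, 11), (4, 1))
        mat = make_matrix(values)
        out = ms.apply_feature_filter(
            mat, FilterConfig(mode="abundance_percentile", k_percent=20))
        assert out.shape[1] == 8
        assert "M01" not in out.feature_ids and "M02" not in out.feature_ids

    def test_all_dropped_raises(self):
        mat = make_matrix(np.full((4, 2), np.nan))
        with pytest.raises(ValueError):
            ms.apply_feature_filter(
                mat, FilterConfig(mode="prevalence", min_presence_fraction=0.5))


class TestLogTransform:
    def test_values_and_missing_sentinel(self):
        mat = make_matrix([[100.0, 1.0, np.nan]])
        out = ms.log_transform(mat)
        np.testing.assert_allclose(out.values.iloc[0, :2], [2.0, 0.0])
        assert np.isnan(out.values.iloc[0, 2])

    def test_double_application_refused(self):
        out = ms.log_transform(make_matrix([[10.0, 100.0]]))
        with pytest.raises(ValueError, match="already"):
            ms.log_transform(out)

    def test_nonpositive_observed_raises(self):
        with pytest.raises(ValueError):
            ms.log_transform(make_matrix([[0.0, 1.0]]))


class TestQuantileReference:
    def test_two_complete_samples_hand_oracle(self):
        train = make_matrix([[1.0, 3.0, 5.0], [2.0, 4.0, 6.0]],
                            transform_log=["log10"])
        ref = ms.fit_quantile_reference(train)
        np.testing.assert_allclose(ref.reference_quantiles, [1.5, 3.5, 5.5])

    def test_identical_samples_give_that_sample_sorted(self):
        train = make_matrix([[5.0, 1.0, 3.0]] * 4, transform_log=["log10"])
        ref = ms.fit_quantile_reference(train)
        np.testing.assert_allclose(ref.reference_quantiles, [1.0, 3.0, 5.0])

    def test_single_feature_reference_is_mean(self):
        train = make_matrix([[2.0], [4.0], [6.0]], transform_log=["log10"])
        ref = ms.fit_quantile_reference(train)
        np.testing.assert_allclose(ref.reference_quantiles, [4.0])

    def test_requires_log_scale_and_two_samples(self):
        with pytest.raises(ValueError):
            ms.fit_quantile_reference(make_matrix([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            ms.fit_quantile_reference(
                make_matrix([[1.0, 2.0]], transform_log=["log10"]))
        with pytest.raises(ValueError, match="no observed"):
            ms.fit_quantile_reference(make_matrix(
                [[1.0, 2.0], [np.nan, np.nan]], transform_log=["log10"]))

    def test_roundtrip_json(self, tmp_path):
        train = make_matrix([[1.0, 3.0], [2.0, 4.0]], transform_log=["log10"])
        ref = ms.fit_quantile_reference(train)
        ref.to_json(tmp_path / "ref.json")
        back = ms.NormalizationReference.from_json(tmp_path / "ref.json")
        np.testing.assert_allclose(back.reference_quantiles,
                                   ref.reference_quantiles)
        assert back.feature_order == ref.feature_order


class TestQuantileNormalization:
    @pytest.fixture()
    def ref(self):
        train = make_matrix([[1.0, 3.0, 5.0], [2.0, 4.0, 6.0]],
                            transform_log=["log10"])
        return ms.fit_quantile_reference(train)

    def test_complete_sample_sorted_equals_reference(self, ref):
        sample = pd.Series([9.0, 2.0, 4.0], index=ref.feature_order)
        out = ms.apply_quantile_normalization(sample, ref)
        np.testing.assert_allclose(np.sort(out), ref.reference_quantiles,
                                   atol=1e-9)

    def test_constant_sample_maps_to_reference_center(self, ref):
        # all-tied values take the average rank, the midpoint of the grid;
        # the reference here is symmetric so that midpoint is its mean
        sample = pd.Series([7.0, 7.0, 7.0], index=ref.feature_order)
        out = ms.apply_quantile_normalization(sample, ref)
        np.testing.assert_allclose(out, np.mean(ref.reference_quantiles))

    def test_rank_order_invariance_across_scales(self, ref):
        a = pd.Series([1.0, 10.0, 5.0], index=ref.feature_order)
        b = pd.Series([100.0, 1e6, 2000.0], index=ref.feature_order)
        out_a = ms.apply_quantile_normalization(a, ref)
        out_b = ms.apply_quantile_normalization(b, ref)
        np.testing.assert_allclose(out_a, out_b)

    def test_missing_cells_stay_missing(self, ref):
        sample = pd.Series([2.0, np.nan, 4.0], index=ref.feature_order)
        out = ms.apply_quantile_normalization(sample, ref)
        assert np.isnan(out.iloc[1])
        assert out.notna().sum() == 2

    def test_rowwise_equals_whole_matrix(self, ref):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.uniform(1, 9, (6, 3)),
                              columns=ref.feature_order)
        values.iloc[2, 1] = np.nan
        whole = ms.apply_quantile_normalization(values, ref)
        rows = pd.DataFrame(
            [ms.apply_quantile_normalization(values.iloc[i], ref)
             for i in range(len(values))])
        np.testing.assert_allclose(whole.to_numpy(), rows.to_numpy())

    def test_feature_order_mismatch_raises(self, ref):
        sample = pd.Series([1.0, 2.0, 3.0], index=["X", "Y", "Z"])
        with pytest.raises(ValueError):
            ms.apply_quantile_normalization(sample, ref)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False), min_size=4, max_size=12,
                    unique=True))
    def test_rank_preservation(self, raw):
        n = len(raw)
        rng = np.random.default_rng(0)
        train = make_matrix(np.sort(rng.normal(size=(3, n)), axis=1),
                            feature_ids=[f"F{j}" for j in range(n)],
                            transform_log=["log10"])
        ref = ms.fit_quantile_reference(train)
        sample = pd.Series(raw, index=ref.feature_order)
        out = ms.apply_quantile_normalization(sample, ref)
        order_in = np.argsort(sample.to_numpy(), kind="stable")
        normed = out.to_numpy()[order_in]
        assert np.all(np.diff(normed) >= -1e-12)


def test_batch_effect_reduced_by_normalization(small_cohort, small_library,
                                               small_matrix):
    """Between-batch variance of per-sample means drops >= 50%."""
    _, _, meta, _ = small_cohort
    logged = ms.log_transform(small_matrix)
    ref = ms.fit_quantile_reference(logged)
    normed = ms.apply_quantile_normalization(logged, ref)

    def between_batch_variance(values):
        means = values.mean(axis=1, skipna=True)
        batches = meta.set_index("sample_id").loc[means.index, "batch_id"]
        grand = means.mean()
        return float(sum(len(g) * (g.mean() - grand) ** 2
                         for _, g in means.groupby(batches)) / len(means))

    assert between_batch_variance(normed.values) <= \
        0.5 * between_batch_variance(logged.values)
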