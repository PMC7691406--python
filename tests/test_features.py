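"""Connectivity features: correlations, ADF windows, selection."""
import numpy as np
import pandas as pd
import pytest

from fcclust import (
    FeatureMatrix,
    ROITimeSeriesSet,
    SyntheticCohortConfig,
    WindowSpec,
    adf_window_length,
    build_feature_matrices,
    dfc_variance,
    generate_roi_timeseries,
    select_top_features,
    sliding_window_corr,
    static_fc,
)
from fcclust.features import ZeroVarianceError, dfc_variance_matrix, group_effect_pvalues

from conftest import make_labels


def ts_from_arrays(*series):
    data = np.asarray(series, dtype=float)[None]  # one subject
    return ROITimeSeriesSet(
        data=data, subject_ids=["s0"], roi_ids=[f"ROI{i}" for i in range(len(series))]
    )


class TestStaticFC:
    def test_identity_and_sign_flip(self, rng):
        x = rng.normal(size=50)
        mats = static_fc(ts_from_arrays(x, x.copy(), -x))
        assert mats[0, 0, 1] == pytest.approx(1.0)
        assert mats[0, 0, 2] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        mats = static_fc(ts_from_arrays([1, 2, 3, 4], [1, 2, 4, 3]))
        assert mats[0, 0, 1] == pytest.approx(0.8)

    def test_symmetric_unit_diagonal(self, rng):
        ts = ROITimeSeriesSet(rng.normal(size=(3, 6, 40)),
                              [f"s{i}" for i in range(3)],
                              [f"r{i}" for i in range(6)])
        mats = static_fc(ts)
        for m in mats:
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0)
            assert np.all(np.abs(m) <= 1 + 1e-12)

    def test_zero_variance_series_names_roi(self, rng):
        ts = ts_from_arrays(rng.normal(size=30), np.full(30, 2.0))
        with pytest.raises(ZeroVarianceError, match="ROI1"):
            static_fc(ts)


class TestADFWindowLength:
    def test_white_noise_accepts_smallest_window(self):
        spec = WindowSpec()
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(135)
            res = adf_window_length(x, spec)
            hits += res.length == spec.search_range[0] and res.stationary
        assert hits >= 95

    def test_random_walk_flagged_non_stationary(self):
        spec = WindowSpec()
        hits = 0
        for seed in range(100):
            x = np.cumsum(np.random.default_rng(seed).standard_normal(135))
            res = adf_window_length(x, spec)
            hits += (not res.stationary) and res.length == spec.search_range[1]
        assert hits >= 90

    def test_constant_series_rejected(self):
        with pytest.raises(ZeroVarianceError):
            adf_window_length(np.ones(135), WindowSpec())

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            adf_window_length(np.random.default_rng(0).normal(size=10), WindowSpec())


class TestSlidingWindowCorr:
    def test_identical_series_all_ones(self, rng):
        x = rng.normal(size=30)
        assert np.allclose(sliding_window_corr(x, x, 10), 1.0)

    def test_single_window_equals_static_pearson(self, rng):
        x, y = rng.normal(size=(2, 25))
        r = sliding_window_corr(x, y, 25)
        assert r.shape == (1,)
        assert r[0] == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_hand_computed_windows(self):
        # windows: (1,2,3)~(1,2,4) -> 3/sqrt(28/3); (2,3,4)~(2,4,3) -> 0.5
        r = sliding_window_corr(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 4, 3]), 3)
        assert r == pytest.approx([3.0 / np.sqrt(28.0 / 3.0), 0.5])

    def test_output_length_decreases_with_window(self, rng):
        x, y = rng.normal(size=(2, 60))
        lengths = [len(sliding_window_corr(x, y, w)) for w in (5, 10, 20, 40)]
        assert lengths == sorted(lengths, reverse=True)
        assert all(a > b for a, b in zip(lengths, lengths[1:]))

    def test_flat_window_flagged_nan(self, rng):
        x = np.concatenate([np.zeros(10), rng.normal(size=10)])
        y = rng.normal(size=20)
        r = sliding_window_corr(x, y, 5)
        assert np.isnan(r[0])
        assert np.isfinite(r[-1])


class TestDFCVariance:
    def test_constant_series_zero(self):
        assert dfc_variance(np.ones(3)) == 0.0

    def test_hand_computed_sample_variance(self):
        assert dfc_variance(np.array([0.5, -0.5])) == pytest.approx(0.5)

    def test_shift_invariance(self, rng):
        r = rng.uniform(-1, 1, 40)
        assert dfc_variance(r + 0.37) == pytest.approx(dfc_variance(r))

    def test_too_few_valid_entries_rejected(self):
        with pytest.raises(ValueError):
            dfc_variance(np.array([0.2, np.nan]))

    def test_matrix_route_matches_scalar_route(self, rng):
        ts = ROITimeSeriesSet(rng.normal(size=(2, 5, 50)),
                              ["s0", "s1"], [f"r{i}" for i in range(5)])
        mat = dfc_variance_matrix(ts, 12)
        for i, a, b in [(0, 0, 1), (1, 2, 4), (0, 3, 2)]:
            ref = dfc_variance(sliding_window_corr(ts.data[i, a], ts.data[i, b], 12))
            assert mat[i, a, b] == pytest.approx(ref, rel=1e-10)


class TestSelectTopFeatures:
    def make_cohort(self, rng, n_per=15, n_feat=30, shift=1.0):
        labels = make_labels([("a", n_per), ("b", n_per), ("c", n_per), ("d", n_per)], rng)
        codes = labels.codes()
        values = rng.normal(size=(4 * n_per, n_feat))
        values[:, 0] += shift * codes  # group-driven feature
        values[:, 1] = 2.0 * labels.covariates["age"].to_numpy() + rng.normal(
            size=4 * n_per)  # pure covariate feature
        fm = FeatureMatrix(values, [f"f{j}" for j in range(n_feat)],
                           labels.subject_ids)
        return fm, labels

    def test_returns_k_columns_in_ascending_p_order(self, rng):
        fm, labels = self.make_cohort(rng)
        sel, table = select_top_features(fm, labels, k=5)
        assert sel.n_features == 5
        ps = table.set_index("feature_id")["p"]
        assert list(ps[sel.feature_ids]) == sorted(ps[sel.feature_ids])

    def test_covariate_feature_ranks_below_group_feature(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fm, labels = self.make_cohort(rng, shift=1.5)
            _, table = select_top_features(fm, labels, k=5)
            ranks = table.set_index("feature_id")["rank"]
            hits += ranks["f0"] < ranks["f1"]
        assert hits >= 95

    def test_null_pvalues_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(17)
        labels = make_labels([("a", 10), ("b", 10), ("c", 10), ("d", 10)], rng)
        fm = FeatureMatrix(rng.normal(size=(40, 2000)),
                           [f"f{j}" for j in range(2000)], labels.subject_ids)
        _, p = group_effect_pvalues(fm, labels)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_matches_statsmodels_anova(self, rng):
        """Dual-route check of the vectorized partial F-test."""
        import statsmodels.formula.api as smf

        fm, labels = self.make_cohort(rng, n_feat=4)
        f_ours, p_ours = group_effect_pvalues(fm, labels)
        df = labels.covariates.copy()
        df["group"] = labels.labels
        for j in range(4):
            df["y"] = fm.values[:, j]
            full = smf.ols("y ~ C(group) + age + gender + motion", df).fit()
            red = smf.ols("y ~ age + gender + motion", df).fit()
            f_ref = ((red.ssr - full.ssr) / 3) / (full.ssr / full.df_resid)
            assert f_ours[j] == pytest.approx(f_ref, rel=1e-8)

    def test_selection_deterministic(self, rng):
        fm, labels = self.make_cohort(rng)
        a, _ = select_top_features(fm, labels, k=7)
        b, _ = select_top_features(fm, labels, k=7)
        assert a.feature_ids == b.feature_ids
        assert np.array_equal(a.values, b.values)

    def test_collinear_covariates_named(self, rng):
        labels = make_labels([("a", 10), ("b", 10)], rng)
        labels.covariates["motion"] = labels.covariates["age"] * 2.0
        fm = FeatureMatrix(rng.normal(size=(20, 3)), ["f0", "f1", "f2"],
                           labels.subject_ids)
        with pytest.raises(ValueError, match="motion"):
            select_top_features(fm, labels, k=2)

    def test_k_larger_than_features_rejected(self, rng):
        fm, labels = self.make_cohort(rng, n_feat=5)
        with pytest.raises(ValueError):
            select_top_features(fm, labels, k=6)


class TestBuildFeatureMatrices:
    def test_three_rois_give_three_candidate_pairs(self):
        cfg = SyntheticCohortConfig(
            group_sizes=[8, 8], group_names=("a", "b"), n_rois=3,
            n_affected_pairs=1, seed=0,
        )
        ts, labels = generate_roi_timeseries(cfg)
        sfc, dfc, w = build_feature_matrices(ts, labels, WindowSpec(length=20), k=3)
        assert sfc.n_features == 3 and dfc.n_features == 3
        assert all(f.endswith("|SFC") for f in sfc.feature_ids)
        assert all(f.endswith("|DFCvar") for f in dfc.feature_ids)

    def test_dfc_features_bounded_unit_interval(self, rng):
        cfg = SyntheticCohortConfig(
            group_sizes=[6, 6], group_names=("a", "b"), n_rois=10,
            n_affected_pairs=3, seed=1,
        )
        ts, labels = generate_roi_timeseries(cfg)
        _, dfc, _ = build_feature_matrices(ts, labels, WindowSpec(length=25), k=10)
        assert np.all(dfc.values >= 0)
        assert np.all(dfc.values <= 1)
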