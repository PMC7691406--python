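"""Synthetic cohort generators: shapes, determinism, effect knobs."""
import numpy as np
import pytest

from fcclust import (
    ConfigError,
    SyntheticCohortConfig,
    auto_dbscan,
    generate_feature_cohort,
    generate_roi_timeseries,
    purity,
    sliding_window_corr,
)


def small_ts_config(**kw):
    base = dict(group_sizes=[6, 6, 6, 6], n_rois=12, n_affected_pairs=4, seed=0)
    base.update(kw)
    return SyntheticCohortConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"group_sizes": [0, 5, 5, 5]},
            {"group_sizes": []},
            {"within_group_sd": 0.0},
            {"sfc_effect": -0.1},
            {"n_timepoints": 1},
            {"n_rois": 10, "n_affected_pairs": 6},
            {"centroid_mode": "ring"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SyntheticCohortConfig(**kw).validate()


class TestFeatureCohort:
    def test_default_shape_is_132_by_100(self):
        fm, labels = generate_feature_cohort(SyntheticCohortConfig())
        assert fm.values.shape == (132, 100)
        assert labels.n_subjects == 132
        sizes = [labels.labels.count(g) for g in ("control", "EMCI", "LMCI", "AD")]
        assert sizes == [35, 34, 34, 29]

    def test_seed_reproducibility(self):
        cfg = SyntheticCohortConfig(seed=7)
        a, la = generate_feature_cohort(cfg)
        b, lb = generate_feature_cohort(cfg)
        assert np.array_equal(a.values, b.values)
        assert la.covariates.equals(lb.covariates)
        c, _ = generate_feature_cohort(SyntheticCohortConfig(seed=8))
        assert not np.array_equal(a.values, c.values)

    def test_null_effect_centroids_indistinguishable_by_permutation(self):
        """With sfc_effect = 0 the observed between-group centroid spread
        sits inside its label-permutation null distribution."""
        cfg = SyntheticCohortConfig(
            group_sizes=[125, 125, 125, 125], sfc_effect=0.0, seed=3
        )
        fm, labels = generate_feature_cohort(cfg)
        codes = labels.codes()

        def centroid_spread(c):
            cents = np.array([fm.values[c == g].mean(0) for g in range(4)])
            d = np.linalg.norm(cents[:, None] - cents[None], axis=-1)
            return d[np.triu_indices(4, 1)].mean()

        obs = centroid_spread(codes)
        rng = np.random.default_rng(0)
        null = [centroid_spread(rng.permutation(codes)) for _ in range(200)]
        assert obs <= np.quantile(null, 0.99)

    def test_vanishing_dispersion_gives_perfect_purity(self):
        cfg = SyntheticCohortConfig(
            group_sizes=[15, 15, 15, 15], n_features=20,
            sfc_effect=0.3, within_group_sd=1e-6, seed=1,
        )
        fm, labels = generate_feature_cohort(cfg)
        res, _ = auto_dbscan(fm.values, min_pts=5, grid_size=50)
        assert purity(res, labels).overall_purity == pytest.approx(100.0)

    def test_centroid_distance_monotone_in_effect(self):
        """Median inter-centroid distance of generated cohorts is
        non-decreasing in sfc_effect (grid of 4 effects, 10 seeds)."""
        meds = []
        for eff in (0.05, 0.1, 0.2, 0.4):
            per_seed = []
            for seed in range(10):
                cfg = SyntheticCohortConfig(
                    group_sizes=[12, 12, 12, 12], n_features=30,
                    sfc_effect=eff, seed=seed,
                )
                fm, labels = generate_feature_cohort(cfg)
                codes = labels.codes()
                cents = np.array([fm.values[codes == g].mean(0) for g in range(4)])
                d = np.linalg.norm(cents[:, None] - cents[None], axis=-1)
                per_seed.append(np.median(d[np.triu_indices(4, 1)]))
            meds.append(np.median(per_seed))
        assert all(b >= a for a, b in zip(meds, meds[1:]))

    def test_spectrum_mode_orders_groups_along_a_line(self):
        cfg = SyntheticCohortConfig(
            group_sizes=[20, 20, 20, 20], centroid_mode="spectrum",
            sfc_effect=0.3, seed=2,
        )
        fm, labels = generate_feature_cohort(cfg)
        codes = labels.codes()
        cents = np.array([fm.values[codes == g].mean(0) for g in range(4)])
        d = np.linalg.norm(cents[:, None] - cents[None], axis=-1)
        # extremes are farther apart than adjacent groups
        assert d[0, 3] > d[0, 1]
        assert d[0, 3] > d[2, 3]
        assert d[0, 3] == pytest.approx(d[0, 1] + d[1, 3], rel=0.1)


class TestCovariates:
    def test_covariate_columns_and_ranges(self):
        _, labels = generate_feature_cohort(SyntheticCohortConfig(seed=5))
        cov = labels.covariates
        assert set(cov.columns) == {"age", "gender", "motion"}
        assert cov["gender"].isin([0, 1]).all()
        assert (cov["motion"] >= 0).all()
        assert 55 < cov["age"].mean() < 90

    def test_confound_switch_injects_age_effect(self):
        base = SyntheticCohortConfig(group_sizes=[40, 40], group_names=("a", "b"),
                                     sfc_effect=0.0, seed=9)
        fm0, la0 = generate_feature_cohort(base)
        fm1, la1 = generate_feature_cohort(base.replace(covariate_confound=0.05))
        age = la1.covariates["age"].to_numpy()
        r1 = np.corrcoef(age, fm1.values[:, 0])[0, 1]
        r0 = np.corrcoef(la0.covariates["age"].to_numpy(), fm0.values[:, 0])[0, 1]
        assert abs(r1) > 0.8
        assert abs(r0) < 0.5


class TestROITimeseries:
    def test_default_shape(self):
        cfg = SyntheticCohortConfig(seed=0)
        ts, labels = generate_roi_timeseries(cfg)
        assert ts.data.shape == (132, 200, 135)
        assert labels.n_subjects == 132

    def test_seed_reproducibility(self):
        cfg = small_ts_config(seed=11)
        a, _ = generate_roi_timeseries(cfg)
        b, _ = generate_roi_timeseries(cfg)
        assert np.array_equal(a.data, b.data)

    def test_static_correlation_matches_closed_form(self):
        """With no modulation, an affected pair's correlation is the
        mixing level rho itself; long series converge to it."""
        cfg = SyntheticCohortConfig(
            group_sizes=[2, 2], group_names=("lo", "hi"),
            n_rois=4, n_affected_pairs=2, n_timepoints=5000,
            base_corr=0.4, sfc_effect=0.3, base_amplitude=0.0, dfc_effect=0.0,
            seed=21,
        )
        ts, _ = generate_roi_timeseries(cfg)
        r_lo = np.corrcoef(ts.data[0, 0], ts.data[0, 1])[0, 1]
        r_hi = np.corrcoef(ts.data[2, 0], ts.data[2, 1])[0, 1]
        assert r_lo == pytest.approx(0.4, abs=0.05)
        assert r_hi == pytest.approx(0.7, abs=0.05)

    def test_sfc_shift_without_dfc_shift(self):
        """sfc_effect moves static correlation between groups while group
        means of sliding-window correlation variance stay statistically
        equal (dfc_effect = 0)."""
        from scipy import stats

        cfg = SyntheticCohortConfig(
            group_sizes=[100, 100], group_names=("lo", "hi"),
            n_rois=8, n_affected_pairs=3, sfc_effect=0.1, dfc_effect=0.0,
            base_corr=0.2, seed=0,
        )
        ts, labels = generate_roi_timeseries(cfg)
        codes = labels.codes()
        sfc_vals = np.empty(200)
        dfc_vals = np.empty(200)
        for i in range(200):
            sfc_vals[i] = np.corrcoef(ts.data[i, 0], ts.data[i, 1])[0, 1]
            r = sliding_window_corr(ts.data[i, 0], ts.data[i, 1], 30)
            dfc_vals[i] = np.var(r, ddof=1)
        t_sfc = stats.ttest_ind(sfc_vals[codes == 0], sfc_vals[codes == 1])
        t_dfc = stats.ttest_ind(dfc_vals[codes == 0], dfc_vals[codes == 1])
        assert t_sfc.pvalue < 0.01       # static correlation shifted
        assert t_dfc.pvalue >= 0.01      # connectivity variability not

    def test_dfc_effect_raises_windowed_variance(self):
        cfg = SyntheticCohortConfig(
            group_sizes=[60, 60], group_names=("lo", "hi"),
            n_rois=8, n_affected_pairs=3, sfc_effect=0.0, dfc_effect=0.5,
            base_corr=0.2, base_amplitude=0.05, seed=4,
        )
        ts, labels = generate_roi_timeseries(cfg)
        codes = labels.codes()
        dfc_vals = np.array([
            np.var(sliding_window_corr(ts.data[i, 0], ts.data[i, 1], 30), ddof=1)
            for i in range(120)
        ])
        assert dfc_vals[codes == 1].mean() > 1.5 * dfc_vals[codes == 0].mean()

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ConfigError):
            generate_roi_timeseries(small_ts_config(n_timepoints=1))
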