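import numpy as np
import pytest
import scipy.stats

from nbrobust.core import CountMatrix, DesignMatrix, make_group_design
from nbrobust.dispersion import (
    DispersionConfig,
    _local_shared_apl,
    adjusted_profile_likelihood,
    apl_profile,
    common_dispersion,
    maximize_apl,
    tagwise_dispersion,
    trended_dispersion,
)
from nbrobust.robust import RobustConfig, estimate_robust


def apl_symbolic_two_obs(phi, y=4.0):
    """Closed-form APL for intercept-only, n=2, equal counts y=(4,4).

    The MLE mean is exactly ybar = 4 for every phi, so the APL is the NB
    log-likelihood at mu=4 minus half the log Fisher information
    log(2 * mu/(1+phi*mu)).
    """
    size = 1.0 / phi
    ll = 2.0 * scipy.stats.nbinom.logpmf(y, size, size / (size + y))
    info = 2.0 * y / (1.0 + phi * y)
    return ll - 0.5 * np.log(info)


class TestAdjustedProfileLikelihood:
    def test_unit_weights_equal_unweighted(self, small_nb_dataset):
        counts, design, _ = small_nb_dataset
        off = np.log(counts.library_sizes)
        y = counts.values[0]
        a0 = adjusted_profile_likelihood(y, design, off, 0.1)
        a1 = adjusted_profile_likelihood(y, design, off, 0.1, weights=np.ones(len(y)))
        assert a0 == pytest.approx(a1, abs=1e-10)

    @pytest.mark.parametrize("phi", [0.01, 0.1, 0.5, 2.0])
    def test_matches_symbolic_two_observation_case(self, phi):
        design = DesignMatrix(np.ones((2, 1)), ["intercept"], [])
        val = adjusted_profile_likelihood(np.array([4.0, 4.0]), design, np.zeros(2), phi)
        assert val == pytest.approx(apl_symbolic_two_obs(phi), rel=1e-6)


class TestMaximizeApl:
    grid = np.logspace(-4, 1, 101)

    def test_recovers_planted_quadratic_optimum(self):
        phi_star = 0.05
        f = lambda phi: -((np.log(phi) - np.log(phi_star)) ** 2)  # noqa: E731
        phi, ok = maximize_apl(f, self.grid)
        assert ok
        assert phi == pytest.approx(phi_star, abs=1e-4)

    def test_monotone_decreasing_returns_lower_bound_with_flag(self):
        phi, ok = maximize_apl(lambda p: -np.log(p), self.grid)
        assert phi == self.grid[0] and not ok

    def test_all_minus_inf_flagged(self):
        phi, ok = maximize_apl(lambda p: -np.inf, self.grid)
        assert phi == self.grid[0] and not ok

    def test_argmax_matches_finer_grid_scan(self, small_nb_dataset):
        """Golden-refined argmax agrees with exhaustive evaluation on a 10x
        finer grid, to within the fine grid spacing."""
        counts, design, _ = small_nb_dataset
        off = np.log(counts.library_sizes)
        coarse = np.logspace(-3, 1, 41)
        fine = np.logspace(-3, 1, 401)
        fine_apl = apl_profile(counts.values, design.values, off, fine)
        rng = np.random.default_rng(0)
        step = np.log(fine[1]) - np.log(fine[0])
        for g in rng.choice(counts.n_features, size=8, replace=False):
            obj = lambda phi, g=g: adjusted_profile_likelihood(counts.values[g], design, off, phi)
            phi_g, ok = maximize_apl(obj, coarse)
            phi_fine = fine[np.argmax(fine_apl[g])]
            if ok:
                assert abs(np.log(phi_g) - np.log(phi_fine)) <= 1.5 * step


class TestCommonDispersion:
    def test_single_feature_equals_its_own_maximizer(self, small_nb_dataset):
        counts, design, _ = small_nb_dataset
        off = np.log(counts.library_sizes)
        y = counts.values[:1]
        cfg = DispersionConfig(grid_min=1e-3, grid_max=10, grid_points=101)
        c = common_dispersion(y, design, off, cfg=cfg)
        obj = lambda phi: adjusted_profile_likelihood(y[0], design, off, phi)  # noqa: E731
        phi_own, ok = maximize_apl(obj, cfg.grid())
        assert c == pytest.approx(phi_own, rel=1e-3)

    def test_duplicating_features_leaves_estimate_unchanged(self, small_nb_dataset):
        counts, design, _ = small_nb_dataset
        off = np.log(counts.library_sizes)
        cfg = DispersionConfig(grid_min=1e-3, grid_max=10, grid_points=51)
        y = counts.values[:10]
        c1 = common_dispersion(y, design, off, cfg=cfg)
        c2 = common_dispersion(np.vstack([y, y]), design, off, cfg=cfg)
        assert c1 == pytest.approx(c2, rel=1e-6)

    def test_recovers_true_dispersion_in_simulation(self):
        rng = np.random.default_rng(42)
        G, n, phi = 500, 10, 0.1
        design = make_group_design(["A"] * 5 + ["B"] * 5)
        mu = rng.uniform(50, 500, size=(G, 1)) * np.ones((1, n))
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu))
        c = common_dispersion(y, design, np.zeros(n))
        assert abs(c - phi) / phi < 0.2


class TestTrendedDispersion:
    def test_identical_features_give_constant_trend_at_common(self):
        rng = np.random.default_rng(1)
        row = rng.negative_binomial(5, 0.05, size=8)
        y = np.tile(row, (40, 1))
        design = make_group_design(["A"] * 4 + ["B"] * 4)
        off = np.zeros(8)
        curve, trended = trended_dispersion(y, design, off)
        assert np.ptp(trended) < 1e-12
        c = common_dispersion(y, design, off)
        assert trended[0] == pytest.approx(c, rel=0.05)

    def test_recovers_planted_dispersion_mean_trend(self):
        """phi(mu) = 0.05 + 1/mu recovered within 25% over the middle 80%
        of the abundance range."""
        rng = np.random.default_rng(3)
        G, n = 2000, 10
        design = make_group_design(["A"] * 5 + ["B"] * 5)
        mu_bar = 10 ** rng.uniform(1.0, 3.5, size=G)
        phi = 0.05 + 1.0 / mu_bar
        mu = np.tile(mu_bar[:, None], (1, n))
        y = rng.negative_binomial(1 / phi[:, None], 1 / (1 + phi[:, None] * mu))
        curve, trended = trended_dispersion(y, design, np.zeros(n))
        lo, hi = np.quantile(mu_bar, [0.1, 0.9])
        mid = (mu_bar >= lo) & (mu_bar <= hi)
        rel_err = np.abs(trended[mid] - phi[mid]) / phi[mid]
        assert np.median(rel_err) < 0.25

    def test_fewer_features_than_bins_falls_back_to_common(self, small_nb_dataset):
        counts, design, _ = small_nb_dataset
        off = np.log(counts.library_sizes)
        with pytest.warns(UserWarning, match="fewer features"):
            curve, trended = trended_dispersion(
                counts.values[:5], design, off, cfg=DispersionConfig(n_bins=20)
            )
        assert np.ptp(trended) == 0.0

    def test_outlier_inflation_raises_trend_and_weights_restore_it(self):
        """Inflating 5% of observations raises the fitted trend; Huber
        down-weighting pulls it back toward the clean-data level."""
        rng = np.random.default_rng(8)
        G, n, phi = 400, 10, 0.1
        design = make_group_design(["A"] * 5 + ["B"] * 5)
        mu = rng.uniform(50, 500, size=(G, 1)) * np.ones((1, n))
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)
        _, trend_clean = trended_dispersion(y, design, np.zeros(n))
        y_out = y.copy()
        mask = rng.random((G, n)) < 0.05
        y_out[mask] = np.floor(y_out[mask] * 8)
        _, trend_out = trended_dispersion(y_out, design, np.zeros(n))
        assert trend_out.mean() > trend_clean.mean()
        res = estimate_robust(
            CountMatrix(y_out), design, robust_cfg=RobustConfig(n_iterations=4)
        )
        trend_w = res.trace[-1].trended
        assert trend_w.mean() < trend_out.mean()


class TestTagwiseDispersion:
    def _setup(self, rng, G=60, n=8):
        design = make_group_design(["A"] * 4 + ["B"] * 4)
        mu = rng.uniform(30, 800, size=(G, 1)) * np.ones((1, n))
        phi = rng.uniform(0.05, 0.4, size=G)
        y = rng.negative_binomial(1 / phi[:, None], 1 / (1 + phi[:, None] * mu))
        return y.astype(float), design, np.zeros(n)

    def test_zero_prior_df_equals_individual_maximizer(self, rng):
        y, design, off = self._setup(rng)
        cfg = DispersionConfig(prior_df=0.0, grid_min=1e-3, grid_max=10, grid_points=81)
        est = tagwise_dispersion(y, design, off, cfg=cfg)
        grid = cfg.grid()
        for g in [0, 7, 23]:
            obj = lambda phi, g=g: adjusted_profile_likelihood(y[g], design, off, phi)
            phi_own, ok = maximize_apl(obj, grid)
            if ok:
                assert abs(np.log(est.tagwise[g]) - np.log(phi_own)) < np.log(grid[1] / grid[0]) * 1.5

    def test_huge_prior_df_collapses_to_local_shared_maximizer(self, rng):
        y, design, off = self._setup(rng)
        cfg = DispersionConfig(prior_df=1e8, grid_min=1e-3, grid_max=10, grid_points=81)
        est = tagwise_dispersion(y, design, off, cfg=cfg)
        grid = cfg.grid()
        apl = apl_profile(y, design.values, off, grid)
        shared = _local_shared_apl(apl, est.abundance, cfg.window(y.shape[0]))
        shared_arg = grid[np.argmax(shared, axis=1)]
        log_step = np.log(grid[1] / grid[0])
        assert np.all(np.abs(np.log(est.tagwise) - np.log(shared_arg)) < 1.6 * log_step)

    def test_tagwise_brackets_between_individual_and_shared(self, rng):
        y, design, off = self._setup(rng, G=80)
        cfg = DispersionConfig(prior_df=10.0, grid_min=1e-3, grid_max=10, grid_points=81)
        est = tagwise_dispersion(y, design, off, cfg=cfg)
        grid = cfg.grid()
        apl = apl_profile(y, design.values, off, grid)
        shared = _local_shared_apl(apl, est.abundance, cfg.window(y.shape[0]))
        own_arg = grid[np.argmax(apl, axis=1)]
        shared_arg = grid[np.argmax(shared, axis=1)]
        lo = np.minimum(own_arg, shared_arg)
        hi = np.maximum(own_arg, shared_arg)
        step = grid[1] / grid[0]
        assert np.all(est.tagwise >= lo / step**1.5)
        assert np.all(est.tagwise <= hi * step**1.5)

    def test_unit_weights_equal_unweighted(self, rng):
        y, design, off = self._setup(rng, G=40)
        e0 = tagwise_dispersion(y, design, off)
        e1 = tagwise_dispersion(y, design, off, weights=np.ones_like(y))
        np.testing.assert_allclose(e0.tagwise, e1.tagwise, atol=1e-10)
        np.testing.assert_allclose(e0.trended, e1.trended, atol=1e-10)

    def test_feature_permutation_equivariance(self, rng):
        y, design, off = self._setup(rng, G=50)
        perm = rng.permutation(50)
        e0 = tagwise_dispersion(y, design, off)
        e1 = tagwise_dispersion(y[perm], design, off)
        np.testing.assert_allclose(e1.tagwise, e0.tagwise[perm], rtol=1e-8)

    def test_outlier_pulls_unweighted_tagwise_down_weighting_restores(self):
        """A single inflated observation drags a feature off the trend; the
        moderated unweighted estimate understates its honest dispersion and
        robust weighting raises it back."""
        rng = np.random.default_rng(21)
        G, n, phi = 200, 10, 0.1
        design = make_group_design(["A"] * 5 + ["B"] * 5)
        mu = rng.uniform(50, 500, size=(G, 1)) * np.ones((1, n))
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)
        y[0, 2] *= 8  # plant one outlier in feature 0
        off = np.zeros(n)
        cfg = DispersionConfig(prior_df=10.0)
        unweighted = tagwise_dispersion(y, design, off, cfg=cfg)
        # honest (unmoderated) estimate of the contaminated feature
        own = tagwise_dispersion(y[:1], design, off, cfg=DispersionConfig(prior_df=0.0))
        assert unweighted.tagwise[0] < own.tagwise[0]
        res = estimate_robust(CountMatrix(y), design, disp_cfg=cfg, robust_cfg=RobustConfig(n_iterations=3))
        assert res.dispersion.tagwise[0] < unweighted.tagwise[0] * 1.05
        # weights sharply reduce the outlier's influence
        assert res.weights.values[0, 2] == res.weights.values[0].min()

    def test_common_shrinkage_mode_runs(self, rng):
        y, design, off = self._setup(rng, G=40)
        est = tagwise_dispersion(y, design, off, shrink_to="common")
        assert np.all(est.tagwise > 0)
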