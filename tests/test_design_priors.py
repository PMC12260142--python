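"""Design-prior family: densities, null masses, conditioning, sampling."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from upos import (
    MixturePrior,
    NormalPrior,
    PointMassPrior,
    SkewNormalPrior,
    TruncatedNormalPrior,
    VariancePrior,
    conditional,
    prior_from_config,
    sample_joint,
)
from conftest import make_mixture


class TestNullMass:
    """Exact p0 = P(Θ ≤ 0) values for the application's prior grid."""

    @pytest.mark.parametrize(
        "theta_d, n_d, p0",
        [
            (0.198, 15, 0.35), (0.198, 46, 0.25), (0.198, 165, 0.10),
            (0.372, 15, 0.24), (0.372, 46, 0.10),
            (0.545, 15, 0.15), (0.545, 46, 0.03),
        ],
    )
    def test_normal_grid(self, theta_d, n_d, p0):
        assert round(NormalPrior(theta_d, n_d).prob_null(0.0), 2) == p0

    def test_normal_small_p0_high_precision(self):
        # the exact CDF value rounds to 0.008 at 3 d.p. (0.009 is a common
        # rounding slip)
        p0 = NormalPrior(0.372, 165).prob_null(0.0)
        assert p0 == pytest.approx(0.008442, abs=5e-6)

    @pytest.mark.parametrize("n_d, p0", [(15, 0.12), (46, 0.06), (165, 0.01)])
    def test_skew_normal_grid(self, n_d, p0):
        assert round(SkewNormalPrior(0.198, n_d, lam=1.0).prob_null(0.0), 2) == p0

    @pytest.mark.parametrize("w0, p0", [(0.25, 0.15), (0.5, 0.27), (0.75, 0.38)])
    def test_mixture_grid(self, w0, p0):
        assert round(make_mixture(w0).prob_null(0.0), 2) == p0

    def test_truncated_at_null_boundary_is_zero(self):
        assert TruncatedNormalPrior(0.198, 46, theta_L=0.0).prob_null(0.0) == 0.0

    def test_point_mass_is_indicator(self):
        assert PointMassPrior(0.372).prob_null(0.0) == 0.0
        assert PointMassPrior(-0.1).prob_null(0.0) == 1.0
        assert PointMassPrior(0.0).prob_null(0.0) == 1.0  # boundary in the null


class TestDensityAndCdf:
    @pytest.mark.parametrize("name", ["normal", "skew_normal", "truncated_normal", "mixture"])
    def test_density_integrates_to_one(self, prior_catalog, name):
        prior = prior_catalog[name]
        lo, hi = prior.support
        lo, hi = max(lo, -30.0), min(hi, 30.0)
        total, _ = integrate.quad(prior.density, lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("name", ["normal", "skew_normal", "truncated_normal", "mixture"])
    def test_cdf_monotone_with_proper_limits(self, prior_catalog, name):
        prior = prior_catalog[name]
        grid = np.linspace(-5, 5, 301)
        vals = np.asarray(prior.cdf(grid))
        assert np.all(np.diff(vals) >= 0)
        assert prior.cdf(-1e6) == pytest.approx(0.0, abs=1e-12)
        assert prior.cdf(1e6) == pytest.approx(1.0, abs=1e-12)

    def test_skew_normal_lam_zero_is_normal(self):
        skew = SkewNormalPrior(0.198, 46, lam=0.0)
        norm = NormalPrior(0.198, 46)
        grid = np.linspace(-2, 2.5, 501)
        assert np.max(np.abs(skew.density(grid) - norm.density(grid))) < 1e-12

    def test_skew_normal_cdf_matches_scipy(self):
        """Owen's-T route cross-checked against scipy's skewnorm CDF."""
        prior = SkewNormalPrior(0.198, 46, lam=1.0)
        grid = np.linspace(-1.5, 2.0, 101)
        ref = stats.skewnorm.cdf(grid, 1.0, loc=0.198, scale=2 / math.sqrt(46))
        np.testing.assert_allclose(prior.cdf(grid), ref, atol=1e-12)

    def test_truncated_support_bounds_enforced(self):
        with pytest.raises(ValueError):
            TruncatedNormalPrior(0.2, 46, theta_L=1.0, theta_U=0.5)


class TestSampling:
    def test_point_mass_sample_is_constant(self):
        assert np.all(PointMassPrior(0.372).sample(5, seed=1) == 0.372)

    @pytest.mark.parametrize("name", ["normal", "skew_normal", "truncated_normal", "mixture"])
    def test_seed_reproducibility(self, prior_catalog, name):
        prior = prior_catalog[name]
        np.testing.assert_array_equal(prior.sample(1000, seed=42), prior.sample(1000, seed=42))
        assert not np.array_equal(prior.sample(1000, seed=42), prior.sample(1000, seed=43))

    @pytest.mark.parametrize("name", ["normal", "skew_normal", "truncated_normal", "mixture"])
    def test_empirical_null_fraction_matches_p0(self, prior_catalog, name):
        prior = prior_catalog[name]
        M = 10**5
        draws = prior.sample(M, seed=7)
        p0 = prior.prob_null(0.0)
        se = math.sqrt(max(p0 * (1 - p0), 1e-12) / M)
        assert abs((draws <= 0).mean() - p0) <= max(3 * se, 1e-9)

    @pytest.mark.parametrize("name", ["normal", "skew_normal", "truncated_normal", "mixture"])
    def test_kolmogorov_smirnov_against_cdf(self, prior_catalog, name):
        prior = prior_catalog[name]
        draws = prior.sample(10**5, seed=11)
        pvalue = stats.ks_1samp(draws, prior.cdf).pvalue
        assert pvalue > 0.001

    def test_truncated_draws_respect_support(self):
        draws = TruncatedNormalPrior(0.198, 46, theta_L=0.0).sample(10**5, seed=5)
        assert draws.min() >= 0.0


class TestConditional:
    def test_density_vanishes_off_region(self):
        tilde1 = conditional(NormalPrior(0.198, 46), side=1, theta0=0.0)
        assert np.all(np.asarray(tilde1.density(np.linspace(-2, -0.01, 50))) == 0.0)
        assert tilde1.density(0.2) > 0.0

    def test_recombination_recovers_parent(self):
        parent = NormalPrior(0.198, 46)
        p0 = parent.prob_null(0.0)
        tilde0 = conditional(parent, 0, 0.0)
        tilde1 = conditional(parent, 1, 0.0)
        grid = np.linspace(-1.5, 2.0, 401)
        grid = grid[grid != 0.0]
        recombined = p0 * np.asarray(tilde0.density(grid)) + (1 - p0) * np.asarray(
            tilde1.density(grid)
        )
        np.testing.assert_allclose(recombined, parent.density(grid), atol=1e-10)

    def test_conditional_integrates_to_one(self):
        tilde1 = conditional(NormalPrior(0.198, 46), 1, 0.0)
        total, _ = integrate.quad(tilde1.density, 0.0, 5.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_conditional_mean_matches_rejection_oracle(self):
        """Inverse route vs. brute-force rejection sampling from the parent."""
        parent = NormalPrior(0.198, 46)
        tilde1 = conditional(parent, 1, 0.0)
        exact = tilde1.integrate(lambda t: t, 0.0, np.inf)
        rng = np.random.default_rng(123)
        raw = parent.sample(2 * 10**6, rng)
        oracle = raw[raw > 0].mean()
        assert exact == pytest.approx(oracle, abs=3e-4)
        draws = tilde1.sample(10**5, seed=9)
        assert draws.mean() == pytest.approx(exact, abs=5 * draws.std() / math.sqrt(len(draws)))

    def test_degenerate_conditional_raises(self):
        trunc = TruncatedNormalPrior(0.198, 46, theta_L=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            conditional(trunc, 0, 0.0)


class TestVariancePrior:
    def test_moments_of_the_application_prior(self):
        vp = VariancePrior(16, 60)
        assert vp.mean == pytest.approx(4.0, abs=1e-12)
        assert vp.sd == pytest.approx(1.0, abs=0.1)

    def test_improper_shape_rejected(self):
        with pytest.raises(ValueError):
            VariancePrior(1.0, 60)

    def test_sample_joint_moments(self):
        prior = NormalPrior(0.198, 46)
        sigma2, theta = sample_joint(prior, VariancePrior(16, 60), 4 * 10**5, seed=3)
        assert sigma2.mean() == pytest.approx(4.0, abs=3 * sigma2.std() / math.sqrt(len(sigma2)))
        # marginal null mass: (θ−θd)√(a n_d / b) is t with 2a df
        p0_exact = stats.t.cdf((0 - 0.198) * math.sqrt(16 * 46 / 60), df=32)
        assert (theta <= 0).mean() == pytest.approx(p0_exact, abs=0.003)
        assert round(p0_exact, 2) == 0.25

    def test_nearly_degenerate_variance_prior_recovers_normal(self):
        # IG with huge shape concentrates on its mean 4
        a = 10**6
        prior = NormalPrior(0.198, 46)
        _, theta = sample_joint(prior, VariancePrior(a, 4.0 * (a - 1)), 2 * 10**5, seed=4)
        ref = prior.sample(2 * 10**5, seed=4)
        assert theta.mean() == pytest.approx(ref.mean(), abs=0.003)
        assert theta.std() == pytest.approx(ref.std(), rel=0.01)


class TestConfigConstruction:
    @pytest.mark.parametrize(
        "cfg, cls",
        [
            ({"type": "point_mass", "theta_d": 0.372}, PointMassPrior),
            ({"type": "normal", "theta_d": 0.198, "n_d": 46}, NormalPrior),
            ({"type": "skew_normal", "theta_d": 0.198, "n_d": 46, "lambda": 1.0}, SkewNormalPrior),
            (
                {"type": "truncated_normal", "theta_d": 0.198, "n_d": 46, "theta_L": 0.0},
                TruncatedNormalPrior,
            ),
            (
                {
                    "type": "mixture",
                    "w0": 0.5,
                    "components": [
                        {"theta_d": 0.0, "n_d": 165},
                        {"theta_d": 0.545, "n_d": 46},
                    ],
                },
                MixturePrior,
            ),
        ],
    )
    def test_round_trip_types(self, cfg, cls):
        prior = prior_from_config(cfg, sigma=2.0)
        assert isinstance(prior, cls)

    def test_config_matches_direct_construction(self):
        built = prior_from_config({"type": "normal", "theta_d": 0.198, "n_d": 46}, sigma=2.0)
        assert built == NormalPrior(0.198, 46, sigma=2.0)

    @pytest.mark.parametrize(
        "cfg", [{"type": "nope"}, {"type": "normal"}, {"type": "mixture", "w0": 0.5, "components": []}]
    )
    def test_invalid_configs_rejected(self, cfg):
        with pytest.raises(ValueError):
            prior_from_config(cfg)
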