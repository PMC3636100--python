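import numpy as np
import pytest
from scipy.stats import norm

import condfdr as cf
from condfdr.mixture import (FourGroupsFit, TwoGroupsFit, four_groups_loglik,
                             two_groups_loglik)


def draw_two_groups(n, pi0, s0, s1, seed):
    rng = np.random.default_rng(seed)
    nonnull = rng.random(n) >= pi0
    z = rng.standard_normal(n) * np.sqrt(s0)
    z[nonnull] += rng.standard_normal(int(nonnull.sum())) * np.sqrt(s1)
    return z


class TestTwoGroupsFit:
    def test_parameter_recovery(self):
        """Generating parameters recovered at n=1e5.

        The effect-variance tolerance reflects the repeated-seed spread of
        the MLE: with ~1e3 non-null scores, pi0 and sigma1_sq trade off
        along a likelihood ridge and sigma1_sq scatters by ~10% (sd).
        """
        z = draw_two_groups(100_000, 0.99, 1.0, 4.0, seed=7)
        fit = cf.fit_two_groups(z, seed=3, restarts=5)
        assert fit.pi0 == pytest.approx(0.99, abs=0.005)
        assert fit.sigma0_sq == pytest.approx(1.0, rel=0.05)
        assert fit.sigma1_sq == pytest.approx(4.0, rel=0.25)

    def test_null_data_reports_boundary_or_high_pi0(self):
        z = np.random.default_rng(1).standard_normal(20_000)
        fit = cf.fit_two_groups(z, seed=2, restarts=2)
        assert fit.boundary or fit.pi0 >= 0.99

    def test_loglik_at_least_truth(self):
        z = draw_two_groups(30_000, 0.99, 1.0, 4.0, seed=8)
        fit = cf.fit_two_groups(z, seed=4, restarts=2)
        assert fit.loglik >= two_groups_loglik(z, 0.99, 1.0, 4.0) - 1e-6

    def test_loglik_monotone_across_iterations(self):
        z = draw_two_groups(10_000, 0.97, 1.0, 6.0, seed=9)
        fit = cf.fit_two_groups(z, seed=5, restarts=1)
        trace = fit.loglik_trace
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[:-1]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cf.fit_two_groups([])


class TestLocalFdr:
    fit = TwoGroupsFit(pi0=0.99, sigma0_sq=1.0, sigma1_sq=3.0, loglik=0.0)

    def test_pure_null_gives_one_everywhere(self):
        null_fit = TwoGroupsFit(pi0=1.0, sigma0_sq=1.0, sigma1_sq=3.0, loglik=0.0)
        for z in (0.0, 1.0, 5.0):
            assert cf.local_fdr(z, null_fit) == pytest.approx(1.0)

    def test_density_arithmetic_at_zero(self):
        expected = 0.99 * norm.pdf(0, scale=1) / (
            0.99 * norm.pdf(0, scale=1) + 0.01 * norm.pdf(0, scale=2))
        assert cf.local_fdr(0.0, self.fit) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_and_monotone(self):
        z = np.linspace(0, 10, 200)
        vals = cf.local_fdr(z, self.fit)
        np.testing.assert_allclose(cf.local_fdr(-z, self.fit), vals)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all((vals > 0) & (vals <= 1))

    def test_mixture_density_normalizes(self):
        z = np.arange(-15, 15.0005, 0.001)
        f = (self.fit.pi0 * norm.pdf(z, scale=np.sqrt(self.fit.sigma0_sq))
             + self.fit.pi1 * norm.pdf(z, scale=np.sqrt(self.fit.nonnull_variance)))
        assert np.trapezoid(f, z) == pytest.approx(1.0, abs=1e-6)


class TestFdrCutpoint:
    fit = TwoGroupsFit(pi0=0.99, sigma0_sq=1.0, sigma1_sq=8.0, loglik=0.0)

    def test_level_one_gives_zero(self):
        assert cf.fdr_cutpoint(self.fit, 1.0) == 0.0

    def test_nested_levels(self):
        assert cf.fdr_cutpoint(self.fit, 0.01) >= cf.fdr_cutpoint(self.fit, 0.05)

    def test_matches_grid_scan(self):
        cut = cf.fdr_cutpoint(self.fit, 0.05)
        grid = np.arange(0, 20, 1e-4)
        scan = grid[cf.local_fdr(grid, self.fit) <= 0.05][0]
        assert cut == pytest.approx(scan, abs=2e-4)
        assert cf.local_fdr(cut + 1e-9, self.fit) <= 0.05

    def test_unattainable_level_is_inf(self):
        flat = TwoGroupsFit(pi0=1.0 - 1e-12, sigma0_sq=1.0, sigma1_sq=1e-9,
                            loglik=0.0)
        assert cf.fdr_cutpoint(flat, 0.05) == np.inf


class TestScaleEffectiveN:
    fit = TwoGroupsFit(pi0=0.99, sigma0_sq=1.0, sigma1_sq=1.5, loglik=0.0)

    def test_identity_and_composition(self):
        assert cf.scale_effective_n(self.fit, 1.0).sigma1_sq == 1.5
        twice = cf.scale_effective_n(cf.scale_effective_n(self.fit, 2.0), 2.0)
        once = cf.scale_effective_n(self.fit, 4.0)
        assert once.sigma1_sq == 6.0
        assert twice.sigma1_sq == once.sigma1_sq
        assert twice.sigma0_sq == self.fit.sigma0_sq  # null untouched

    def test_doubling_multiplies_discoveries(self):
        # rare baseline passes; doubling effective n must lift them >= 10x
        rng = np.random.default_rng(21)
        n = 200_000
        nonnull = rng.random(n) >= self.fit.pi0
        effects = np.where(nonnull, rng.standard_normal(n), 0.0)
        noise = rng.standard_normal(n)

        def passes(fit):
            z = noise + effects * np.sqrt(fit.sigma1_sq)
            return int(np.sum((cf.local_fdr(z, fit) <= 0.05) & nonnull))

        base = passes(self.fit)
        doubled = passes(cf.scale_effective_n(self.fit, 2.0))
        assert doubled >= max(10 * base, 1)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            cf.scale_effective_n(self.fit, 0.0)


class TestFourGroupsFit:
    def test_parameter_recovery_moderate_n(self):
        params = cf.SimulationParams(n_snps=60_000, pi=(0.97, 0.009, 0.009, 0.012),
                                     sigma1_sq=(4.0, 4.0), seed=31)
        t1, t2, _ = cf.simulate_pair(params)
        fit = cf.fit_four_groups(t1["Z"].to_numpy(), t2["Z"].to_numpy(),
                                 seed=6, restarts=3)
        assert fit.pi[3] == pytest.approx(0.012, abs=0.006)
        assert fit.sigma0_sq[0] == pytest.approx(1.0, rel=0.1)

    def test_independent_null_traits_small_nonnull_mass(self):
        rng = np.random.default_rng(32)
        z1, z2 = rng.standard_normal((2, 40_000))
        fit = cf.fit_four_groups(z1, z2, seed=7, restarts=2)
        assert fit.pi[1:].sum() <= 0.01 or fit.boundary

    def test_loglik_at_least_truth_and_monotone(self):
        params = cf.SimulationParams(n_snps=30_000, sigma1_sq=(4.0, 4.0), seed=33)
        t1, t2, _ = cf.simulate_pair(params)
        z1, z2 = t1["Z"].to_numpy(), t2["Z"].to_numpy()
        fit = cf.fit_four_groups(z1, z2, seed=8, restarts=2)
        true_covs = [np.eye(2), np.diag([5.0, 1.0]), np.diag([1.0, 5.0]),
                     np.diag([5.0, 5.0])]
        assert fit.loglik >= four_groups_loglik(z1, z2, params.pi, true_covs) - 1e-6
        trace = fit.loglik_trace
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[:-1]))

    def test_component_variances_dominate_null(self):
        params = cf.SimulationParams(n_snps=30_000, sigma1_sq=(4.0, 4.0), seed=34)
        t1, t2, _ = cf.simulate_pair(params)
        fit = cf.fit_four_groups(t1["Z"].to_numpy(), t2["Z"].to_numpy(),
                                 seed=9, restarts=2)
        covs = fit.covariances
        assert covs[1][0, 0] >= covs[0][0, 0]
        assert covs[2][1, 1] >= covs[0][1, 1]
        assert abs(fit.pi.sum() - 1) < 1e-9


class TestConditionalLocalFdr:
    def make_fit(self, pi, cov3=None):
        return FourGroupsFit(
            pi=np.asarray(pi, dtype=float), sigma0_sq=np.array([1.0, 1.0]),
            sigma1_sq=9.0, sigma2_sq=9.0,
            effect_cov3=np.diag([9.0, 9.0]) if cov3 is None else cov3,
            loglik=0.0)

    def test_reduces_to_one_when_trait1_all_null(self):
        fit = self.make_fit([0.98, 0.0, 0.02, 0.0])
        assert cf.conditional_local_fdr(2.0, 3.0, fit) == pytest.approx(1.0)

    def test_monotone_in_conditioning_z_with_pleiotropy(self):
        fit = self.make_fit([0.97, 0.009, 0.009, 0.012])
        z2 = np.linspace(0, 10, 300)
        vals = cf.conditional_local_fdr(np.full_like(z2, 2.5), z2, fit)
        assert np.all(np.diff(vals) <= 1e-10)

    def test_equals_marginal_when_z2_uninformative(self):
        # no pleiotropic component and no trait-2 signal: z2 carries nothing
        fit = self.make_fit([0.99, 0.01, 0.0, 0.0])
        for z1 in (0.5, 2.0, 4.0):
            cond = cf.conditional_local_fdr(z1, 1.7, fit)
            marg = cf.marginal_local_fdr(z1, fit)
            assert cond == pytest.approx(marg, abs=1e-12)


class TestPowerCurve:
    def test_sensitivity_approaches_one(self):
        fit = TwoGroupsFit(pi0=0.99, sigma0_sq=1.0, sigma1_sq=9.0, loglik=0.0)
        curve = dict(cf.power_curve(fit, [0.999999]))
        assert curve[0.999999] == pytest.approx(1.0, abs=1e-6)

    def test_conditional_dominates_with_pleiotropy(self):
        fit = FourGroupsFit(pi=np.array([0.97, 0.009, 0.009, 0.012]),
                            sigma0_sq=np.array([1.0, 1.0]), sigma1_sq=9.0,
                            sigma2_sq=9.0, effect_cov3=np.diag([9.0, 9.0]),
                            loglik=0.0)
        levels = np.round(np.arange(0.01, 0.51, 0.02), 10)
        un = np.array([s for _, s in cf.power_curve(fit, levels, "unconditional")])
        co = np.array([s for _, s in cf.power_curve(fit, levels, "conditional")])
        assert np.all(co >= un - 1e-3)
        assert co.mean() > un.mean()

    def test_no_pleiotropy_no_gain(self):
        fit = FourGroupsFit(pi=np.array([0.97, 0.015, 0.015, 0.0]),
                            sigma0_sq=np.array([1.0, 1.0]), sigma1_sq=9.0,
                            sigma2_sq=9.0, effect_cov3=np.diag([9.0, 9.0]),
                            loglik=0.0)
        levels = np.round(np.arange(0.05, 0.51, 0.05), 10)
        un = np.array([s for _, s in cf.power_curve(fit, levels, "unconditional")])
        co = np.array([s for _, s in cf.power_curve(fit, levels, "conditional")])
        assert np.max(np.abs(co - un)) < 0.02
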