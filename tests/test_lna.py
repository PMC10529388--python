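"""Linear-noise approximation: moment ODEs, delta correction, Gaussian law."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.stats import binom

from gsm2 import cme
from gsm2.core import InitialCondition, KineticRates, MomentSet
from gsm2.lna import (
    covariance_rhs,
    delta_correction,
    gaussian_joint,
    solve_covariances,
    solve_first_moments,
)
from gsm2.macroscopic import solve_mkm, stationary_limits

LAM = 4.1


class TestFirstMoments:
    def test_zero_initial_data_stays_zero(self, rates_conc, macro_conc):
        xi, ups = solve_first_moments(rates_conc, macro_conc)
        assert np.all(xi == 0.0) and np.all(ups == 0.0)

    def test_b_zero_scalar_decay(self):
        k = KineticRates(r=4, a=0.1, b=0.0)
        grid = np.linspace(0, 2, 101)
        macro = solve_mkm(k, 1.0, 0.0, grid)
        xi, _ = solve_first_moments(k, macro, xi0=1.0)
        assert np.allclose(xi, np.exp(-LAM * grid), rtol=1e-8, atol=1e-10)

    def test_upsilon_limit_matches_quadrature(self, rates_conc):
        # oracle: high-accuracy quadrature of (2 b xbar + a) xi along the flow
        grid = np.linspace(0, 12, 241)
        macro = solve_mkm(rates_conc, 1.0, 0.0, grid)
        xi, ups = solve_first_moments(rates_conc, macro, xi0=1.0)

        def xi_ode(t):
            sol = solve_ivp(
                lambda s, z: [-(4 * rates_conc.b * macro.x_bar_at(s) + LAM) * z[0]],
                (0, t), [1.0], rtol=1e-12, atol=1e-14)
            return sol.y[0, -1]

        ref, _ = quad(lambda s: (2 * rates_conc.b * macro.x_bar_at(s)
                                 + rates_conc.a) * xi_ode(s),
                      0, 12, epsabs=1e-10, epsrel=1e-10, limit=200)
        assert ups[-1] == pytest.approx(ref, abs=5e-8)


class TestCovarianceODEs:
    def test_equilibrium_at_origin(self, rates_conc):
        d = covariance_rhs(MomentSet(t=0), 0.0, rates_conc)
        assert d == (0.0, 0.0, 0.0)

    def test_b_zero_binomial_survivor_variance(self):
        # oracle: for the linear network X(t) ~ Binom(x0, e^{-lam t})
        k = KineticRates(r=4, a=0.1, b=0.0, K=20)
        grid = np.linspace(0, 2, 101)
        macro = solve_mkm(k, 1.0, 0.0, grid)
        mom = solve_covariances(k, macro)
        p_surv = np.exp(-LAM * grid)
        assert np.allclose(20 * mom.c_xixi, 20 * p_surv * (1 - p_surv),
                           rtol=1e-7, atol=1e-9)

    def test_cross_covariance_negative(self, moments_conc):
        t = moments_conc.t
        sel = (t > 0) & (t <= 2.0)
        assert np.all(moments_conc.c_xiups[sel] < 0)

    def test_constant_when_rates_vanish(self):
        k = KineticRates(r=0, a=0, b=0)
        grid = np.linspace(0, 5, 21)
        macro = solve_mkm(k, 1.0, 0.0, grid)
        init = InitialCondition(x0=3, y0=2, mode="gaussian", sigma=(3.0, 2.0))
        mom = solve_covariances(k, macro, init)
        assert np.allclose(mom.c_xixi, 3.0, atol=1e-12)
        assert np.allclose(mom.c_upsups, 2.0, atol=1e-12)
        assert np.allclose(mom.c_xiups, 0.0, atol=1e-12)

    def test_long_time_sublethal_moments_vanish(self, moments_conc):
        assert abs(moments_conc.c_xixi[-1]) < 1e-6
        assert abs(moments_conc.c_xiups[-1]) < 1e-6

    def test_positive_semidefinite_along_horizon(self, moments_conc):
        C = moments_conc.covariance_matrices()
        eigs = np.linalg.eigvalsh(C)
        assert eigs.min() >= -1e-9

    def test_count_scale_variance_close_to_exact(self, rates_conc, rates_count,
                                                 macro_conc, moments_conc):
        # exact master-equation variance of Y at benchmark scale is the oracle
        t_obs = [0.5, 0.7, 0.9]
        dists = cme.evolve(cme.DistributionGrid.point_mass(100, 0), t_obs, rates_count)
        for t, dist in zip(t_obs, dists):
            i = int(np.argmin(np.abs(moments_conc.t - t)))
            var_lna = 100 * moments_conc.c_upsups[i]
            var_cme = cme.exact_moments(dist).var_y
            assert var_lna == pytest.approx(var_cme, rel=0.05)

    def test_lyapunov_consistency_with_ou_coefficients(self, rates_conc, macro_conc):
        # same covariance flow written as dC = MC + CM^T + D with M = -A
        from gsm2.ou import coefficients

        def rhs(s, c):
            co = coefficients(s, macro_conc, rates_conc)
            M = -co.A
            C = np.array([[c[0], c[1]], [c[1], c[2]]])
            dC = M @ C + C @ M.T + co.D
            return [dC[0, 0], dC[0, 1], dC[1, 1]]

        sol = solve_ivp(rhs, (0, 2.0), [0.0, 0.0, 0.0], rtol=1e-11, atol=1e-13,
                        t_eval=[0.5, 2.0])
        mom = solve_covariances(rates_conc, macro_conc)
        for j, t in enumerate([0.5, 2.0]):
            i = int(np.argmin(np.abs(mom.t - t)))
            assert mom.c_upsups[i] == pytest.approx(sol.y[0, j], abs=1e-9)
            assert mom.c_xiups[i] == pytest.approx(sol.y[1, j], abs=1e-9)
            assert mom.c_xixi[i] == pytest.approx(sol.y[2, j], abs=1e-9)


class TestLinearNetworkExactness:
    """For b=0 the network is linear, so the Gaussian moments are exact."""

    def test_moments_match_cme_at_all_grid_times(self):
        x0 = 20
        k = KineticRates(r=4, a=0.1, b_tilde=0.0, K=x0)
        grid = np.linspace(0, 1.5, 7)
        macro = solve_mkm(k, 1.0, 0.0, grid)
        mom = solve_covariances(k, macro)
        dists = cme.evolve(cme.DistributionGrid.point_mass(x0, 0), grid[1:], k)
        for i, dist in enumerate(dists, start=1):
            ex = cme.exact_moments(dist)
            assert x0 * macro.y_bar[i] == pytest.approx(ex.mean_y, abs=1e-8)
            assert x0 * mom.c_upsups[i] == pytest.approx(ex.var_y, abs=1e-7)
            assert x0 * mom.c_xixi[i] == pytest.approx(ex.var_x, abs=1e-7)
            assert x0 * mom.c_xiups[i] == pytest.approx(ex.cov_xy, abs=1e-7)


class TestDeltaCorrection:
    def test_starts_at_zero(self, rates_conc, macro_conc, moments_conc):
        d = delta_correction(rates_conc, macro_conc, moments_conc)
        assert d.delta[0] == 0.0

    def test_identity_with_lethal_mean(self, rates_conc, macro_conc, moments_conc):
        d = delta_correction(rates_conc, macro_conc, moments_conc)
        resid = moments_conc.c_upsups + d.delta - macro_conc.y_bar
        assert np.max(np.abs(resid)) < 1e-6

    def test_nonnegative_when_pairwise_active(self, rates_conc, macro_conc, moments_conc):
        d = delta_correction(rates_conc, macro_conc, moments_conc)
        assert np.all(d.delta >= -1e-12)
        assert d.delta_inf > 0

    def test_b_zero_binomial_gap(self):
        # even the linear network is under-dispersed from a deterministic
        # start: mean - variance = x0 p^2 with p = a/(a+r) at long times
        x0 = 20
        k = KineticRates(r=4, a=0.1, b_tilde=0.0, K=x0)
        grid = np.linspace(0, 15, 1501)
        macro = solve_mkm(k, 1.0, 0.0, grid)
        mom = solve_covariances(k, macro)
        d = delta_correction(k, macro, mom)
        p_inf = 0.1 / LAM
        assert x0 * d.delta_inf == pytest.approx(x0 * p_inf ** 2, rel=1e-6)

    def test_stationary_variance_identity(self, rates_conc, macro_conc, moments_conc):
        d = delta_correction(rates_conc, macro_conc, moments_conc)
        _, y_inf = stationary_limits(rates_conc, 1.0, 0.0)
        assert moments_conc.c_upsups[-1] == pytest.approx(y_inf - d.delta_inf, abs=1e-8)

    def test_grid_mismatch_rejected(self, rates_conc, macro_conc, moments_conc):
        short = solve_mkm(rates_conc, 1.0, 0.0, np.linspace(0, 1, 11))
        with pytest.raises(ValueError):
            delta_correction(rates_conc, short, moments_conc)


class TestGaussianJoint:
    def test_degenerate_point_mass(self, rates_conc, macro_conc):
        law = gaussian_joint(0.0, MomentSet(t=0.0), macro_conc, 100)
        cm = law.count_moments()
        assert (cm.mean_x, cm.mean_y) == pytest.approx((100.0, 0.0))
        assert cm.var_x == cm.var_y == 0.0

    def test_count_scale_marginals(self, rates_conc, macro_conc, moments_conc):
        i = int(np.argmin(np.abs(moments_conc.t - 0.5)))
        law = gaussian_joint(moments_conc.t[i], moments_conc.at(i), macro_conc, 100)
        ym = law.y_marginal()
        cm = law.count_moments()
        assert ym.mean() == pytest.approx(cm.mean_y)
        assert ym.var() == pytest.approx(cm.var_y)
        # density integrates to one over a wide grid
        grid = np.linspace(cm.mean_y - 30, cm.mean_y + 30, 20001)
        assert np.trapezoid(ym.pdf(grid), grid) == pytest.approx(1.0, abs=1e-6)

    def test_under_dispersion_at_benchmark(self, rates_conc, macro_conc, moments_conc):
        i = int(np.argmin(np.abs(moments_conc.t - 0.9)))
        law = gaussian_joint(moments_conc.t[i], moments_conc.at(i), macro_conc, 100)
        cm = law.count_moments()
        assert cm.var_y / cm.mean_y < 1.0

    def test_non_psd_rejected(self, macro_conc):
        bad = MomentSet(t=0.5, c_xixi=1.0, c_upsups=1.0, c_xiups=2.0)
        with pytest.raises(ValueError):
            gaussian_joint(0.5, bad, macro_conc, 100)
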