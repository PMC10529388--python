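"""Linear-noise approximation: Gaussian fluctuations around the MKM limit.

The order-one balance of the system-size expansion is a linear
Fokker-Planck equation for the fluctuation density P(t, upsilon, xi) with
time-dependent drift and diffusion read off the macroscopic trajectory.
On the (upsilon, xi) ordering the drift matrix M (dZ = M Z dt + ...) and
diffusion matrix D are

    M(t) = [[0,  2*b*xbar + a       ],
            [0, -(4*b*xbar + a + r) ]],

    D(t) = [[ a*xbar + b*xbar**2,      -(a*xbar + 2*b*xbar**2)      ],
            [-(a*xbar + 2*b*xbar**2),  (a+r)*xbar + 4*b*xbar**2     ]].

With Gaussian (or deterministic) initial data the solution stays Gaussian,
so it is fully described by the first moments (xibar, upsbar) — identically
zero for centred initial data — and by the covariance matrix

    C = [[c_upsups, c_xiups], [c_xiups, c_xixi]],

which solves the Lyapunov ODE dC/dt = M C + C M^T + D, i.e. componentwise

    d c_upsups/dt = 2*(2*b*xbar + a)*c_xiups + a*xbar + b*xbar**2,
    d c_xiups/dt  = (2*b*xbar + a)*c_xixi - (4*b*xbar + a + r)*c_xiups
                    - (a*xbar + 2*b*xbar**2),
    d c_xixi/dt   = -2*(4*b*xbar + a + r)*c_xixi + (a+r)*xbar + 4*b*xbar**2.

The lethal-lesion variance satisfies the identity

    c_upsups(t) = c_upsups(0) + (ybar(t) - ybar(0)) - delta(t),
    delta(t) := -Integral_0^t 2*(2*b*xbar(s) + a) * c_xiups(s) ds,

and since the cross-covariance c_xiups is strictly negative (lethal lesions
are produced exactly by consuming sublethal ones), delta > 0: the
lethal-lesion count is under-dispersed relative to a Poisson law with the
same mean.  ``delta_correction`` quantifies that deviation.

All quantities here live on the fluctuation scale; use
``core.count_scale_moments`` or ``gaussian_joint`` for count-scale output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_simpson, solve_ivp
from scipy.stats import multivariate_normal, norm

from .core import CountMoments, InitialCondition, KineticRates, MomentSet, count_scale_moments
from .macroscopic import MacroTrajectory, stationary_limits

__all__ = [
    "MomentTrajectory",
    "GaussianLaw",
    "DeltaCorrection",
    "solve_first_moments",
    "covariance_rhs",
    "solve_covariances",
    "delta_correction",
    "gaussian_joint",
]


@dataclass(frozen=True)
class MomentTrajectory:
    """Fluctuation moments along a time grid (arrays share the grid)."""

    t: np.ndarray
    xi_bar: np.ndarray
    upsilon_bar: np.ndarray
    c_xixi: np.ndarray
    c_xiups: np.ndarray
    c_upsups: np.ndarray

    def at(self, i: int) -> MomentSet:
        """MomentSet at grid index ``i``."""
        return MomentSet(t=float(self.t[i]), xi_bar=float(self.xi_bar[i]),
                         upsilon_bar=float(self.upsilon_bar[i]),
                         c_xixi=float(self.c_xixi[i]), c_xiups=float(self.c_xiups[i]),
                         c_upsups=float(self.c_upsups[i]))

    def covariance_matrices(self) -> np.ndarray:
        """Stack of 2x2 covariance matrices on the (upsilon, xi) ordering."""
        C = np.empty((self.t.size, 2, 2))
        C[:, 0, 0] = self.c_upsups
        C[:, 0, 1] = C[:, 1, 0] = self.c_xiups
        C[:, 1, 1] = self.c_xixi
        return C


@dataclass(frozen=True)
class GaussianLaw:
    """Bivariate Gaussian fluctuation law at one time, with count-scale views."""

    t: float
    mean: np.ndarray       # (upsilon_bar, xi_bar)
    cov: np.ndarray        # 2x2 on the (upsilon, xi) ordering
    macro_x_bar: float
    macro_y_bar: float
    K: float

    def joint(self):
        """Frozen scipy bivariate normal of (upsilon, xi)."""
        return multivariate_normal(mean=self.mean, cov=self.cov, allow_singular=True)

    def count_moments(self) -> CountMoments:
        m = MomentSet(t=self.t, xi_bar=self.mean[1], upsilon_bar=self.mean[0],
                      c_xixi=self.cov[1, 1], c_xiups=self.cov[0, 1],
                      c_upsups=self.cov[0, 0])
        from .core import MacroState
        return count_scale_moments(m, MacroState(self.t, self.macro_x_bar, self.macro_y_bar), self.K)

    def x_marginal(self):
        """Count-scale Gaussian marginal of X (scipy frozen normal)."""
        cm = self.count_moments()
        return norm(loc=cm.mean_x, scale=np.sqrt(max(cm.var_x, 0.0)))

    def y_marginal(self):
        """Count-scale Gaussian marginal of Y (scipy frozen normal)."""
        cm = self.count_moments()
        return norm(loc=cm.mean_y, scale=np.sqrt(max(cm.var_y, 0.0)))


@dataclass(frozen=True)
class DeltaCorrection:
    """Accumulated non-Poissonian correction delta(t) and its limit."""

    t: np.ndarray
    delta: np.ndarray
    delta_inf: float


def solve_first_moments(rates: KineticRates, macro: MacroTrajectory,
                        xi0: float = 0.0, upsilon0: float = 0.0,
                        rtol: float = 1e-12, atol: float = 1e-14) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the fluctuation first-moment ODEs along ``macro.t``.

    The system is linear and homogeneous in (xibar, upsbar): with zero
    initial data the solution is identically zero (centred fluctuations),
    which the solver reproduces exactly.
    """
    t = macro.t
    a, r, b = rates.a, rates.r, rates.b

    if xi0 == 0.0 and upsilon0 == 0.0:
        # homogeneous linear system from the origin: exact zero, no solver noise
        return np.zeros_like(t), np.zeros_like(t)

    def rhs(s, z):
        xb = macro.x_bar_at(s)
        xi, ups = z
        return (-(4.0 * b * xb + a + r) * xi, (2.0 * b * xb + a) * xi)

    sol = solve_ivp(rhs, (float(t[0]), float(t[-1])), [xi0, upsilon0],
                    t_eval=t, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"first-moment integration failed: {sol.message}")
    return sol.y[0], sol.y[1]


def covariance_rhs(m: MomentSet, x_bar: float, rates: KineticRates) -> tuple[float, float, float]:
    """Time derivative of (c_upsups, c_xiups, c_xixi) at macroscopic state ``x_bar``."""
    a, r, b = rates.a, rates.r, rates.b
    xb = x_bar
    g = 2.0 * b * xb + a          # production coupling
    h = 4.0 * b * xb + a + r      # sublethal relaxation rate
    d_upsups = 2.0 * g * m.c_xiups + a * xb + b * xb * xb
    d_xiups = g * m.c_xixi - h * m.c_xiups - (a * xb + 2.0 * b * xb * xb)
    d_xixi = -2.0 * h * m.c_xixi + (a + r) * xb + 4.0 * b * xb * xb
    return (d_upsups, d_xiups, d_xixi)


def _integrate_covariances(rates: KineticRates, macro: MacroTrajectory,
                           c0: tuple[float, float, float], t_grid: np.ndarray,
                           rtol: float, atol: float) -> np.ndarray:
    a, r, b = rates.a, rates.r, rates.b

    def rhs(s, c):
        xb = float(macro.x_bar_at(s))
        m = MomentSet(t=s, c_upsups=c[0], c_xiups=c[1], c_xixi=c[2])
        return covariance_rhs(m, xb, rates)

    sol = solve_ivp(rhs, (float(t_grid[0]), float(t_grid[-1])), list(c0),
                    t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"covariance integration failed: {sol.message}")
    return sol.y


def solve_covariances(rates: KineticRates, macro: MacroTrajectory,
                      init: InitialCondition | None = None,
                      rtol: float = 1e-10, atol: float = 1e-13) -> MomentTrajectory:
    """Integrate the covariance ODEs along ``macro.t``.

    ``init=None`` (or deterministic mode) starts all covariances at zero;
    a Gaussian initial law starts from ``c_xixi(0) = sigma_x / K``,
    ``c_upsups(0) = sigma_y / K`` and zero cross-covariance.
    """
    t = np.asarray(macro.t, dtype=float)
    if init is None or init.mode == "deterministic":
        c0 = (0.0, 0.0, 0.0)
    else:
        sx, sy = init.fluctuation_covariance(rates.K)
        c0 = (sy, 0.0, sx)
    y = _integrate_covariances(rates, macro, c0, t, rtol, atol)
    zeros = np.zeros_like(t)
    return MomentTrajectory(t=t, xi_bar=zeros, upsilon_bar=zeros,
                            c_upsups=y[0], c_xiups=y[1], c_xixi=y[2])


def delta_correction(rates: KineticRates, macro: MacroTrajectory,
                     covariances: MomentTrajectory) -> DeltaCorrection:
    """Non-Poissonian correction by quadrature of the cross-covariance.

    ``delta(t)`` is computed with cumulative Simpson quadrature on the
    covariance grid; the identity ``c_upsups = c_upsups(0) + ybar - ybar0
    - delta`` then holds to quadrature accuracy (refine the grid to
    tighten it).  ``delta_inf`` is obtained from the stationary lethal mean
    and a long-horizon covariance solve, which is exact to solver tolerance.
    """
    t = covariances.t
    if t.size != macro.t.size or not np.allclose(t, macro.t):
        raise ValueError("covariance trajectory and macroscopic trajectory grids differ")
    a, b = rates.a, rates.b
    xb = macro.x_bar_at(t)
    integrand = -2.0 * (2.0 * b * xb + a) * covariances.c_xiups
    if t.size < 3:
        delta = np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5
                                                 * (integrand[1:] + integrand[:-1]))])
    else:
        delta = cumulative_simpson(integrand, x=t, initial=0.0)

    lam = a + rates.r
    _, y_inf = stationary_limits(rates, macro.x0, macro.y0)
    c0 = (float(covariances.c_upsups[0]), float(covariances.c_xiups[0]),
          float(covariances.c_xixi[0]))
    t_long = max(float(t[-1]), 40.0 / lam if lam > 0 else float(t[-1]))
    grid = np.array([t[0], t_long])
    c_long = _integrate_covariances(rates, macro, c0, grid, rtol=1e-10, atol=1e-13)
    if np.isfinite(y_inf):
        delta_inf = c0[0] + (y_inf - macro.y0) - float(c_long[0, -1])
    else:
        delta_inf = float("nan")
    return DeltaCorrection(t=t, delta=delta, delta_inf=delta_inf)


def gaussian_joint(t: float, moments: MomentSet, macro: MacroTrajectory,
                   K: float) -> GaussianLaw:
    """Gaussian fluctuation law at time ``t`` with count-scale marginals.

    The covariance must be (numerically) positive semidefinite; a negative
    eigenvalue beyond roundoff signals an upstream solver failure.
    """
    K = float(K)
    C = np.array([[moments.c_upsups, moments.c_xiups],
                  [moments.c_xiups, moments.c_xixi]])
    eigs = np.linalg.eigvalsh(C)
    scale = max(1.0, float(np.abs(C).max()))
    if eigs.min() < -1e-9 * scale:
        raise ValueError(f"covariance matrix is not PSD (eigenvalues {eigs})")
    mean = np.array([moments.upsilon_bar, moments.xi_bar])
    return GaussianLaw(t=float(t), mean=mean, cov=C,
                       macro_x_bar=float(macro.x_bar_at(t)),
                       macro_y_bar=float(macro.y_bar_at(t)), K=K)
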