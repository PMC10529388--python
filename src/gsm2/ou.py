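"""Time-dependent Ornstein-Uhlenbeck sampling of the fluctuation law.

The Gaussian fluctuation density solved by the linear Fokker-Planck
equation is also the law of the time-inhomogeneous OU process

    dZ(t) = -A(t) Z(t) dt + Q(t) dW(t),     Z = (upsilon, xi),

with W a standard 2-D Brownian motion,

    A(t) = [[0, -(2*b*xbar + a)], [0, 4*b*xbar + a + r]],

and Q any factor of the Fokker-Planck diffusion matrix, Q Q^T = D (the
law depends on D only).  Simulating OU paths gives a cheap sampler of the
approximate lesion statistics at any system size, where the exact
stochastic simulation may be expensive.

On the count scale the original process is absorbed at x = 0 (no channel
fires without sublethal lesions).  With ``boundary="absorb"`` a path whose
count-scale X = K*xbar + sqrt(K)*xi reaches <= 0 is pinned there: xi
tracks the moving boundary value -sqrt(K)*xbar(t) (X stays 0) and upsilon
freezes, since lethal lesions cannot change once sublethal ones are gone.

Integration is Euler-Maruyama with a fixed step; the macroscopic state is
evaluated from the exact closed form at every substep, so the only errors
are the O(dt) weak discretisation error and Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InitialCondition, KineticRates
from .macroscopic import MacroTrajectory

__all__ = ["OUCoefficients", "OUEnsemble", "coefficients", "simulate_ou"]


@dataclass(frozen=True)
class OUCoefficients:
    """Drift A, diffusion D and factor Q (QQ^T = D) at one time."""

    t: float
    A: np.ndarray
    D: np.ndarray
    Q: np.ndarray


def _diffusion(x_bar: float, rates: KineticRates) -> np.ndarray:
    a, r, b = rates.a, rates.r, rates.b
    duu = a * x_bar + b * x_bar ** 2
    dux = -(a * x_bar + 2.0 * b * x_bar ** 2)
    dxx = (a + r) * x_bar + 4.0 * b * x_bar ** 2
    return np.array([[duu, dux], [dux, dxx]])


def _factor(D: np.ndarray) -> np.ndarray:
    """Square-root factor of a (near-)PSD 2x2 matrix."""
    try:
        return np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(D)
        scale = max(1.0, float(np.abs(D).max()))
        if w.min() < -1e-9 * scale:
            raise ValueError(f"diffusion matrix not PSD (eigenvalues {w})")
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def coefficients(t: float, macro: MacroTrajectory, rates: KineticRates) -> OUCoefficients:
    """OU drift/diffusion at time ``t`` along the macroscopic trajectory."""
    xb = float(macro.x_bar_at(t))
    a, r, b = rates.a, rates.r, rates.b
    A = np.array([[0.0, -(2.0 * b * xb + a)],
                  [0.0, 4.0 * b * xb + a + r]])
    D = _diffusion(xb, rates)
    Q = _factor(D)
    return OUCoefficients(t=float(t), A=A, D=D, Q=Q)


@dataclass(frozen=True)
class OUEnsemble:
    """OU fluctuation paths recorded at observation times.

    ``upsilon``/``xi`` have shape (n_paths, n_times).  Count-scale views
    use the stored macroscopic trajectory and system size.
    """

    t_points: np.ndarray
    upsilon: np.ndarray
    xi: np.ndarray
    K: float
    macro: MacroTrajectory
    seed: int
    dt: float
    boundary: str

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Count-scale (X, Y) arrays, shape (n_paths, n_times)."""
        s = np.sqrt(self.K)
        xb = self.macro.x_bar_at(self.t_points)
        yb = self.macro.y_bar_at(self.t_points)
        X = self.K * xb + s * self.xi
        Y = self.K * yb + s * self.upsilon
        if self.boundary == "absorb":
            # pinned paths are exactly at the boundary up to roundoff
            X = np.where(np.abs(X) < 1e-9, 0.0, X)
        return X, Y


def simulate_ou(rates: KineticRates, macro: MacroTrajectory, K: float,
                t_points, n_paths: int, dt: float = 1e-3, seed: int = 0,
                boundary: str = "none",
                init: InitialCondition | None = None) -> OUEnsemble:
    """Euler-Maruyama OU paths of (upsilon, xi) recorded at ``t_points``.

    ``init=None`` (or deterministic mode) starts every path at the origin;
    a Gaussian initial law draws Z(0) ~ N(0, diag(sigma)/K) — centred,
    because fluctuations are deviations from the macroscopic mean.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if boundary not in ("none", "absorb"):
        raise ValueError("boundary must be 'none' or 'absorb'")
    t_points = np.atleast_1d(np.asarray(t_points, dtype=float))
    if np.any(t_points < 0) or np.any(np.diff(t_points) <= 0):
        raise ValueError("t_points must be non-negative and strictly increasing")

    rng = np.random.default_rng([seed, 7])
    sK = np.sqrt(K)
    z = np.zeros((n_paths, 2))  # columns: (upsilon, xi)
    if init is not None and init.mode == "gaussian":
        sx, sy = init.fluctuation_covariance(K)
        z[:, 0] = rng.normal(0.0, np.sqrt(sy), size=n_paths)
        z[:, 1] = rng.normal(0.0, np.sqrt(sx), size=n_paths)

    absorbed = np.zeros(n_paths, dtype=bool)
    if boundary == "absorb":
        x_counts = K * float(macro.x_bar_at(0.0)) + sK * z[:, 1]
        absorbed |= x_counts <= 0
        z[absorbed, 1] = -sK * float(macro.x_bar_at(0.0))

    out_u = np.empty((n_paths, t_points.size))
    out_x = np.empty((n_paths, t_points.size))
    a, r, b = rates.a, rates.r, rates.b

    t = 0.0
    next_obs = 0
    # record t=0 if requested
    while next_obs < t_points.size and t_points[next_obs] <= t + 1e-15:
        out_u[:, next_obs] = z[:, 0]
        out_x[:, next_obs] = z[:, 1]
        next_obs += 1

    t_end = float(t_points[-1])
    while t < t_end - 1e-15:
        # land exactly on the next observation time
        h = min(dt, t_end - t)
        if next_obs < t_points.size:
            h = min(h, t_points[next_obs] - t)
        xb = float(macro.x_bar_at(t))
        g = 2.0 * b * xb + a
        hrel = 4.0 * b * xb + a + r
        Q = _factor(_diffusion(xb, rates))
        eta = rng.standard_normal((n_paths, 2))
        noise = (eta @ Q.T) * np.sqrt(h)
        du = g * z[:, 1] * h + noise[:, 0]
        dx = -hrel * z[:, 1] * h + noise[:, 1]
        active = ~absorbed
        z[active, 0] += du[active]
        z[active, 1] += dx[active]
        t += h
        if boundary == "absorb":
            xb_new = float(macro.x_bar_at(t))
            x_counts = K * xb_new + sK * z[:, 1]
            newly = (x_counts <= 0) & ~absorbed
            absorbed |= newly
            z[absorbed, 1] = -sK * xb_new  # pin X at exactly 0
        while next_obs < t_points.size and t_points[next_obs] <= t + 1e-12:
            out_u[:, next_obs] = z[:, 0]
            out_x[:, next_obs] = z[:, 1]
            next_obs += 1

    return OUEnsemble(t_points=t_points, upsilon=out_u, xi=out_x, K=float(K),
                      macro=macro, seed=int(seed), dt=float(dt), boundary=boundary)
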