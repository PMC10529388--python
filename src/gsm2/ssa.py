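"""Exact stochastic simulation (Gillespie direct method) of the lesion network.

Simulates the jump process (Y(t), X(t)) whose law solves the master
equation: three reaction channels with count-scale propensities

    repair    X -> 0       rate r * x
    direct    X -> Y       rate x * (a + a_logistic * x)
    pairwise  X + X -> Y   rate b_tilde * x * (x - 1)

The pairwise propensity uses ``x*(x-1)`` exactly (no 1/2 symmetry factor),
mirroring the master equation, so SSA, master-equation solver and the
expansion are bit-consistent about what ``b`` means.

Every channel consumes sublethal lesions, so x is non-increasing, y is
non-decreasing, and a path makes at most ``x(0)`` jumps before hitting the
absorbing state x = 0.  That bound lets each path pre-draw its entire
random stream (one exponential and one uniform per jump), which keeps the
pure-Python event loop fast enough for 1e4-path ensembles.

Reproducibility: path ``i`` of an ensemble uses the stream seeded by
``(master_seed, i)``, so ensembles are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CellState, InitialCondition, KineticRates

__all__ = [
    "Trajectory",
    "Ensemble",
    "propensities",
    "apply_reaction",
    "simulate_path",
    "ensemble",
    "sample_initial_state",
]

CHANNELS = ("repair", "direct", "pairwise")


def propensities(state: CellState, rates: KineticRates, logistic: bool = False
                 ) -> tuple[float, float, float]:
    """Channel propensities (repair, direct-lethal, pairwise) at ``state``."""
    x = state.x
    a_eff = rates.a + (rates.a_logistic * x if logistic else 0.0)
    return (rates.r * x, a_eff * x, rates.b_tilde * x * (x - 1))


def apply_reaction(state: CellState, channel: str) -> CellState:
    """State after one firing of ``channel``; raises if the channel cannot fire."""
    x, y = state.x, state.y
    if channel == "repair":
        if x < 1:
            raise ValueError("repair requires at least one sublethal lesion")
        return CellState(x=x - 1, y=y)
    if channel == "direct":
        if x < 1:
            raise ValueError("direct conversion requires at least one sublethal lesion")
        return CellState(x=x - 1, y=y + 1)
    if channel == "pairwise":
        if x < 2:
            raise ValueError("pairwise conversion requires at least two sublethal lesions")
        return CellState(x=x - 2, y=y + 1)
    raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")


@dataclass(frozen=True)
class Trajectory:
    """One exact sample path: state after each jump (event-driven storage)."""

    times: np.ndarray      # event times, times[0] = 0
    x: np.ndarray          # sublethal count after each event
    y: np.ndarray          # lethal count after each event
    rates: KineticRates
    seed: object = None

    def states(self) -> list[CellState]:
        return [CellState(x=int(xi), y=int(yi)) for xi, yi in zip(self.x, self.y)]

    def sample(self, t_points) -> tuple[np.ndarray, np.ndarray]:
        """Right-continuous step-function values of (x, y) at ``t_points``."""
        t_points = np.asarray(t_points, dtype=float)
        idx = np.searchsorted(self.times, t_points, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("t_points must not precede the trajectory start")
        return self.x[idx], self.y[idx]


def sample_initial_state(init: InitialCondition, rng: np.random.Generator) -> CellState:
    """Integer initial state; Gaussian mode rounds to nearest and clamps at 0."""
    if init.mode == "deterministic":
        return CellState(x=int(round(init.x0)), y=int(round(init.y0)))
    sx, sy = init.sigma
    x = rng.normal(init.x0, np.sqrt(sx))
    y = rng.normal(init.y0, np.sqrt(sy))
    return CellState(x=max(int(round(x)), 0), y=max(int(round(y)), 0))


def _run_path(x: int, y: int, rates: KineticRates, logistic: bool, t_max: float,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r, a, bt, al = rates.r, rates.a, rates.b_tilde, rates.a_logistic
    n_max = x  # every jump consumes >= 1 sublethal lesion
    exps = rng.exponential(size=n_max)
    unis = rng.random(size=n_max)
    times = np.empty(n_max + 1)
    xs = np.empty(n_max + 1, dtype=np.int64)
    ys = np.empty(n_max + 1, dtype=np.int64)
    times[0], xs[0], ys[0] = 0.0, x, y
    t = 0.0
    k = 0
    for i in range(n_max):
        p1 = r * x
        p2 = (a + al * x) * x if logistic else a * x
        p3 = bt * x * (x - 1)
        total = p1 + p2 + p3
        if total <= 0.0:
            break
        t += exps[i] / total
        if t > t_max:
            break
        u = unis[i] * total
        if u < p1:
            x -= 1
        elif u < p1 + p2:
            x -= 1
            y += 1
        else:
            x -= 2
            y += 1
        k += 1
        times[k], xs[k], ys[k] = t, x, y
    return times[:k + 1], xs[:k + 1], ys[:k + 1]


def simulate_path(rates: KineticRates, init: InitialCondition, t_max: float,
                  seed) -> Trajectory:
    """One statistically exact master-equation sample path up to ``t_max``.

    ``seed`` is anything ``numpy.random.default_rng`` accepts (int, sequence,
    Generator).  The path halts at x = 0 (absorbing) or at ``t_max``.
    """
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = sample_initial_state(init, rng)
    logistic = rates.a_logistic > 0
    times, xs, ys = _run_path(state.x, state.y, rates, logistic, float(t_max), rng)
    return Trajectory(times=times, x=xs, y=ys, rates=rates, seed=seed)


@dataclass(frozen=True)
class Ensemble:
    """Empirical law of (X, Y) at fixed observation times from many SSA paths."""

    t_points: np.ndarray
    x_samples: np.ndarray   # (n_paths, n_times) integer counts
    y_samples: np.ndarray
    rates: KineticRates
    seed: int
    n_paths: int

    def x_marginal(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(support, pmf) of X at observation time index ``i``."""
        counts = np.bincount(self.x_samples[:, i])
        return np.arange(counts.size), counts / self.n_paths

    def y_marginal(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        counts = np.bincount(self.y_samples[:, i])
        return np.arange(counts.size), counts / self.n_paths

    @property
    def mean_x(self) -> np.ndarray:
        return self.x_samples.mean(axis=0)

    @property
    def mean_y(self) -> np.ndarray:
        return self.y_samples.mean(axis=0)

    @property
    def var_x(self) -> np.ndarray:
        return self.x_samples.var(axis=0, ddof=1)

    @property
    def var_y(self) -> np.ndarray:
        return self.y_samples.var(axis=0, ddof=1)

    @property
    def cov_xy(self) -> np.ndarray:
        xc = self.x_samples - self.mean_x
        yc = self.y_samples - self.mean_y
        return (xc * yc).sum(axis=0) / (self.n_paths - 1 if self.n_paths > 1 else 1)


def ensemble(rates: KineticRates, init: InitialCondition, t_points,
             n_paths: int, seed: int) -> Ensemble:
    """Simulate ``n_paths`` independent paths and record them at ``t_points``.

    Bitwise reproducible for a fixed ``seed`` regardless of execution order
    (each path derives its stream from ``(seed, path_index)``).
    """
    t_points = np.atleast_1d(np.asarray(t_points, dtype=float))
    if t_points.size == 0:
        raise ValueError("t_points must be non-empty")
    if n_paths < 1:
        raise ValueError("n_paths must be at least 1")
    if np.any(t_points < 0):
        raise ValueError("t_points must be non-negative")
    t_max = float(t_points.max())
    logistic = rates.a_logistic > 0
    xs = np.empty((n_paths, t_points.size), dtype=np.int64)
    ys = np.empty((n_paths, t_points.size), dtype=np.int64)
    for i in range(n_paths):
        rng = np.random.default_rng([seed, i])
        state = sample_initial_state(init, rng)
        times, px, py = _run_path(state.x, state.y, rates, logistic, t_max, rng)
        idx = np.searchsorted(times, t_points, side="right") - 1
        xs[i] = px[idx]
        ys[i] = py[idx]
    return Ensemble(t_points=t_points, x_samples=xs, y_samples=ys,
                    rates=rates, seed=int(seed), n_paths=int(n_paths))
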