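"""Shared domain types and the system-size scaling maps.

The model tracks two lesion species in an irradiated cell nucleus:
sublethal lesions ``X`` (reparable DNA damage) and lethal lesions ``Y``
(irreparable damage leading to cell inactivation).  Sublethal lesions are
removed through three channels,

    X --r--> 0        repair
    X --a--> Y        direct lethal conversion
    X + X --b--> Y    pairwise (clustering) lethal conversion,

with constant rates ``r``, ``a`` and ``b``.  The pairwise channel makes the
master equation nonlinear and is the source of the non-Poissonian behaviour
of the lethal-lesion count.

Counts relate to a dimensionless system size ``K`` through the van Kampen
ansatz

    X(t) = K*xbar(t) + sqrt(K)*xi(t),
    Y(t) = K*ybar(t) + sqrt(K)*upsilon(t),

where ``(xbar, ybar)`` is the deterministic macroscopic trajectory (the
microdosimetric kinetic model, MKM) and ``(xi, upsilon)`` are the centred
fluctuation processes whose law is Gaussian in the large-``K`` limit.  The
pairwise rate scales with the system size: the count-scale rate is
``b_tilde = b / K``, so that the macroscopic rate ``b`` stays of order one.

This module holds the parameter and state containers used throughout the
package and the (bi-directional) scaling maps between count and fluctuation
coordinates, including the moment identities

    E[X]   = K*xbar + sqrt(K)*E[xi],      Var[X] = K*Var[xi],
    E[Y]   = K*ybar + sqrt(K)*E[upsilon], Var[Y] = K*Var[upsilon],
    Cov[X, Y] = K*Cov[xi, upsilon].

Counts mapped back from fluctuation coordinates are real-valued and may be
negative; clamping at zero is the responsibility of sampling/reporting
layers (the master equation itself never leaves the non-negative lattice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "KineticRates",
    "CellState",
    "MacroState",
    "FluctuationState",
    "InitialCondition",
    "MomentSet",
    "CountMoments",
    "to_fluctuations",
    "from_fluctuations",
    "count_scale_moments",
]


@dataclass(frozen=True)
class KineticRates:
    """Reaction-rate parameter set governing all modules.

    Exactly one of ``b`` (macroscopic, concentration-scale pairwise rate)
    and ``b_tilde`` (count-scale pairwise rate) must be given; the other is
    derived at construction through ``b = b_tilde * K``.

    Parameters
    ----------
    r
        Repair rate (1/time).
    a
        Direct lethal-conversion rate (1/time).
    b, b_tilde
        Pairwise interaction rate on the concentration scale (``b``) or on
        the count scale (``b_tilde``); linked by ``b = b_tilde * K``.
    K
        System size (dimensionless, > 0).  ``K = 1`` makes count and
        concentration scales coincide.
    a_logistic
        Optional logistic death increment: with it, the direct-conversion
        propensity becomes ``x * (a + a_logistic * x)``.  Default 0.
    """

    r: float
    a: float
    b: float | None = None
    b_tilde: float | None = None
    K: float = 1.0
    a_logistic: float = 0.0

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"system size K must be positive, got {self.K}")
        if (self.b is None) == (self.b_tilde is None):
            raise ValueError("give exactly one of b (macroscopic) or b_tilde (count scale)")
        if self.b is None:
            object.__setattr__(self, "b", self.b_tilde * self.K)
        else:
            object.__setattr__(self, "b_tilde", self.b / self.K)
        for name in ("r", "a", "b", "a_logistic"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative, got {getattr(self, name)}")

    def with_K(self, K: float) -> "KineticRates":
        """Same count-scale kinetics under a different system-size convention."""
        return KineticRates(r=self.r, a=self.a, b_tilde=self.b_tilde, K=K,
                            a_logistic=self.a_logistic)

    def to_dict(self) -> dict[str, float]:
        return {"r": self.r, "a": self.a, "b_tilde": self.b_tilde,
                "K": self.K, "a_logistic": self.a_logistic}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "KineticRates":
        known = {"r", "a", "b", "b_tilde", "K", "a_logistic"}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown rate parameters: {sorted(extra)}")
        return cls(**{k: d[k] for k in d})


@dataclass(frozen=True)
class CellState:
    """Integer lesion counts: ``x`` sublethal, ``y`` lethal."""

    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"lesion counts must be non-negative, got (x={self.x}, y={self.y})")


@dataclass(frozen=True)
class MacroState:
    """A point of the deterministic macroscopic trajectory."""

    t: float
    x_bar: float
    y_bar: float


@dataclass(frozen=True)
class FluctuationState:
    """Centred, sqrt(K)-scaled deviation from the macroscopic trajectory."""

    xi: float
    upsilon: float


@dataclass(frozen=True)
class InitialCondition:
    """Initial lesion law: a deterministic point or a diagonal Gaussian.

    In ``gaussian`` mode, counts are drawn from N((x0, y0), diag(sigma))
    with ``sigma = (var_x, var_y)`` on the count scale; the default assigns
    Poisson-like variance equal to the mean of each coordinate
    (``sigma = (x0, y0)``).  Samplers round to the nearest integer and
    clamp at zero, since the master equation lives on the integer lattice.
    """

    x0: float
    y0: float
    mode: str = "deterministic"
    sigma: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("deterministic", "gaussian"):
            raise ValueError(f"mode must be 'deterministic' or 'gaussian', got {self.mode!r}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("initial lesion counts must be non-negative")
        if self.mode == "gaussian" and self.sigma is None:
            object.__setattr__(self, "sigma", (float(self.x0), float(self.y0)))
        if self.sigma is not None and (self.sigma[0] < 0 or self.sigma[1] < 0):
            raise ValueError("initial variances must be non-negative")

    def fluctuation_covariance(self, K: float) -> tuple[float, float]:
        """(c_xixi(0), c_upsups(0)) implied on the fluctuation scale: sigma / K."""
        if self.mode == "deterministic":
            return (0.0, 0.0)
        return (self.sigma[0] / K, self.sigma[1] / K)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"x0": self.x0, "y0": self.y0, "mode": self.mode}
        if self.sigma is not None:
            d["sigma"] = list(self.sigma)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "InitialCondition":
        sigma = d.get("sigma")
        return cls(x0=d["x0"], y0=d["y0"], mode=d.get("mode", "deterministic"),
                   sigma=tuple(sigma) if sigma is not None else None)


@dataclass(frozen=True)
class MomentSet:
    """Fluctuation moments at one time: means and covariance entries.

    ``c_xixi = Var[xi]``, ``c_upsups = Var[upsilon]``,
    ``c_xiups = Cov[xi, upsilon]``.
    """

    t: float
    xi_bar: float = 0.0
    upsilon_bar: float = 0.0
    c_xixi: float = 0.0
    c_xiups: float = 0.0
    c_upsups: float = 0.0


@dataclass(frozen=True)
class CountMoments:
    """First and second moments of (X, Y) on the count scale."""

    mean_x: float
    var_x: float
    mean_y: float
    var_y: float
    cov_xy: float


def _check_K(K: float) -> float:
    if not K > 0:
        raise ValueError(f"system size K must be positive, got {K}")
    return float(K)


def to_fluctuations(state: CellState, macro: MacroState, K: float) -> FluctuationState:
    """Invert the scaling ansatz: counts -> fluctuation coordinates.

    Returns ``xi = (x - K*xbar)/sqrt(K)`` and
    ``upsilon = (y - K*ybar)/sqrt(K)``.
    """
    K = _check_K(K)
    s = math.sqrt(K)
    return FluctuationState(xi=(state.x - K * macro.x_bar) / s,
                            upsilon=(state.y - K * macro.y_bar) / s)


def from_fluctuations(fluct: FluctuationState, macro: MacroState, K: float) -> tuple[float, float]:
    """Fluctuation coordinates -> real-valued count pair ``(x, y)``.

    The result may be negative; boundary policy is the caller's concern.
    """
    K = _check_K(K)
    s = math.sqrt(K)
    return (K * macro.x_bar + s * fluct.xi, K * macro.y_bar + s * fluct.upsilon)


def count_scale_moments(moments: MomentSet, macro: MacroState, K: float) -> CountMoments:
    """Map fluctuation-scale moments to count-scale moments of (X, Y)."""
    K = _check_K(K)
    if moments.c_xixi < 0 or moments.c_upsups < 0:
        raise ValueError("fluctuation variances must be non-negative")
    s = math.sqrt(K)
    return CountMoments(
        mean_x=K * macro.x_bar + s * moments.xi_bar,
        var_x=K * moments.c_xixi,
        mean_y=K * macro.y_bar + s * moments.upsilon_bar,
        var_y=K * moments.c_upsups,
        cov_xy=K * moments.c_xiups,
    )
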