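"""Configuration, comparison metrics and tabular reports.

The three reports mirror the standard verification experiments for this
model family:

* ``report_density_comparison`` — marginal lesion-count distributions at a
  few observation times: SSA histograms vs the count-scale Gaussian of the
  linear-noise approximation (LNA), plus the exact master-equation
  marginals when the lattice is small enough, with total-variation and
  Kolmogorov-Smirnov distances.
* ``report_moments`` — time evolution of the macroscopic means, the
  fluctuation covariances, the non-Poissonian correction delta and the
  lethal-lesion dispersion index (variance/mean; < 1 means under-dispersed).
* ``report_paths`` — a handful of SSA and OU sample paths around the
  macroscopic mean curve on a shared grid.

Tables are the contract; plotting is an optional extra on top of them.
All randomness is derived from the config seed, and every run can write
its resolved configuration next to its outputs for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import cme, lna, macroscopic, ou, ssa
from .core import InitialCondition, KineticRates

__all__ = [
    "RunConfig",
    "tv_distance",
    "ks_distance_counts",
    "report_density_comparison",
    "report_moments",
    "report_paths",
]

# Lattice-size guard for the exact master-equation oracle (~40k states).
CME_MAX_X0 = 200


class RunConfig(BaseModel):
    """Resolved run configuration (benchmark defaults: r=4, a=0.1,
    b_tilde=0.01, x0=100, y0=0, observation times 0.5/0.7/0.9 a.u.)."""

    r: float = 4.0
    a: float = 0.1
    b_tilde: float = 0.01
    a_logistic: float = 0.0
    x0: float = 100.0
    y0: float = 0.0
    mode: str = "deterministic"
    sigma: Optional[tuple[float, float]] = None
    K: Optional[float] = Field(default=None, description="system size; default x0")
    t_points: list[float] = Field(default_factory=lambda: [0.5, 0.7, 0.9])
    t_max: Optional[float] = None
    n_paths: int = 10_000
    n_display_paths: int = 10
    dt: float = 1e-3
    seed: int = 42
    moment_grid_points: int = 401
    include_cme: Optional[bool] = None
    out_dir: Optional[str] = None

    @field_validator("t_points")
    @classmethod
    def _sorted_positive(cls, v: list[float]) -> list[float]:
        if not v or any(t < 0 for t in v) or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("t_points must be non-empty, non-negative, strictly increasing")
        return v

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.n_paths < 1 or self.n_display_paths < 0:
            raise ValueError("path counts must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        return self

    # -- derived objects ------------------------------------------------
    @property
    def K_eff(self) -> float:
        return float(self.K if self.K is not None else max(self.x0, 1.0))

    def rates(self) -> KineticRates:
        return KineticRates(r=self.r, a=self.a, b_tilde=self.b_tilde,
                            K=self.K_eff, a_logistic=self.a_logistic)

    def initial_condition(self) -> InitialCondition:
        return InitialCondition(x0=self.x0, y0=self.y0, mode=self.mode, sigma=self.sigma)

    def horizon(self) -> float:
        return float(self.t_max if self.t_max is not None else max(self.t_points))

    def macro(self, t_grid=None) -> macroscopic.MacroTrajectory:
        """Concentration-scale macroscopic solve under this config."""
        if t_grid is None:
            t_grid = np.linspace(0.0, self.horizon(), self.moment_grid_points)
        return macroscopic.solve_mkm(self.rates(), self.x0 / self.K_eff,
                                     self.y0 / self.K_eff, t_grid)

    def use_cme(self) -> bool:
        if self.include_cme is not None:
            return self.include_cme
        return self.mode == "deterministic" and self.x0 <= CME_MAX_X0

    def write_resolved(self, out_dir: Path) -> Path:
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "resolved_config.json"
        path.write_text(json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n")
        return path


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two pmfs on integer support."""
    n = max(p.size, q.size)
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[:p.size] = p
    qq[:q.size] = q
    return 0.5 * float(np.abs(pp - qq).sum())


def ks_distance_counts(pmf: np.ndarray, gaussian) -> float:
    """KS distance between an integer-count pmf and a continuous law.

    The continuous CDF is evaluated with a +0.5 continuity correction so
    the discrete and continuous laws are compared at matching cell edges.
    """
    k = np.arange(pmf.size)
    emp_cdf = np.cumsum(pmf)
    model_cdf = gaussian.cdf(k + 0.5)
    return float(np.max(np.abs(emp_cdf - model_cdf)))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _lna_at_times(config: RunConfig, t_points) -> list[lna.GaussianLaw]:
    grid = np.unique(np.concatenate([np.linspace(0.0, max(t_points), 201),
                                     np.asarray(t_points, dtype=float)]))
    macro = config.macro(grid)
    moments = lna.solve_covariances(config.rates(), macro, config.initial_condition())
    laws = []
    for t in t_points:
        i = int(np.argmin(np.abs(moments.t - t)))
        laws.append(lna.gaussian_joint(t, moments.at(i), macro, config.K_eff))
    return laws


def report_density_comparison(config: RunConfig):
    """Marginal-density comparison at each observation time.

    Returns ``(tables, summary)``: ``tables`` maps each time to a DataFrame
    over the integer count support with SSA/LNA (and optionally exact CME)
    columns per lesion type; ``summary`` collects KS/TV distances and the
    moment comparison.  Writes CSVs when ``config.out_dir`` is set.
    """
    t_points = np.asarray(config.t_points, dtype=float)
    rates = config.rates()
    init = config.initial_condition()
    ens = ssa.ensemble(rates, init, t_points, config.n_paths, config.seed)
    laws = _lna_at_times(config, t_points)

    cme_dists = None
    if config.use_cme():
        p0 = cme.DistributionGrid.from_initial(init)
        cme_dists = cme.evolve(p0, t_points, rates)

    tables: dict[float, pd.DataFrame] = {}
    rows = []
    for i, t in enumerate(t_points):
        _, px_ssa = ens.x_marginal(i)
        _, py_ssa = ens.y_marginal(i)
        nmax = max(px_ssa.size, py_ssa.size)
        law = laws[i]
        if cme_dists is not None:
            px_cme = cme.x_marginal(cme_dists[i])
            py_cme = cme.y_marginal(cme_dists[i])
            nmax = max(nmax, px_cme.size, py_cme.size)
        k = np.arange(nmax)

        def pad(p):
            out = np.zeros(nmax)
            out[:p.size] = p
            return out

        xm, ym = law.x_marginal(), law.y_marginal()
        tab = pd.DataFrame({
            "count": k,
            "ssa_pmf_x": pad(px_ssa),
            "ssa_pmf_y": pad(py_ssa),
            "lna_density_x": xm.pdf(k),
            "lna_density_y": ym.pdf(k),
        })
        for species, p_ssa, gaus in (("x", px_ssa, xm), ("y", py_ssa, ym)):
            row = {
                "t": t, "species": species,
                "ks_ssa_lna": ks_distance_counts(pad(p_ssa), gaus),
                "ssa_mean": float(k @ pad(p_ssa)),
                "lna_mean": float(gaus.mean()),
                "lna_var": float(gaus.var()),
            }
            row["ssa_var"] = float(pad(p_ssa) @ (k - row["ssa_mean"]) ** 2)
            rows.append(row)
        if cme_dists is not None:
            tab["cme_pmf_x"] = pad(px_cme)
            tab["cme_pmf_y"] = pad(py_cme)
            rows[-2]["tv_ssa_cme"] = tv_distance(px_ssa, px_cme)
            rows[-1]["tv_ssa_cme"] = tv_distance(py_ssa, py_cme)
            rows[-2]["ks_cme_lna"] = ks_distance_counts(pad(px_cme), xm)
            rows[-1]["ks_cme_lna"] = ks_distance_counts(pad(py_cme), ym)
        tables[float(t)] = tab

    summary = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        config.write_resolved(out)
        for t, tab in tables.items():
            tab.to_csv(out / f"density_t{t:g}.csv", index=False)
        summary.to_csv(out / "density_summary.csv", index=False)
    return tables, summary


def report_moments(config: RunConfig) -> pd.DataFrame:
    """Count-scale moment trajectories with the non-Poissonian correction.

    Columns: macroscopic means, fluctuation covariances, count-scale
    variances, delta(t) and the lethal dispersion index Var[Y]/E[Y].
    """
    K = config.K_eff
    rates = config.rates()
    macro = config.macro()
    moments = lna.solve_covariances(rates, macro, config.initial_condition())
    delta = lna.delta_correction(rates, macro, moments)
    mean_y = K * macro.y_bar
    var_y = K * moments.c_upsups
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean_y > 0, var_y / np.where(mean_y > 0, mean_y, 1.0), np.nan)
    df = pd.DataFrame({
        "t": macro.t,
        "x_bar": K * macro.x_bar,
        "y_bar": mean_y,
        "c_xixi": moments.c_xixi,
        "c_xiups": moments.c_xiups,
        "c_upsups": moments.c_upsups,
        "var_x": K * moments.c_xixi,
        "var_y": var_y,
        "cov_xy": K * moments.c_xiups,
        "delta": K * delta.delta,
        "dispersion_y": dispersion,
    })
    df.attrs["delta_inf"] = K * delta.delta_inf
    df.attrs["checks"] = {
        "cov_negative_for_t_positive": bool(np.all(moments.c_xiups[macro.t > 0] < 0)),
        "under_dispersed": bool(np.all(var_y[macro.t > 0] < mean_y[macro.t > 0])),
        "c_xixi_final": float(moments.c_xixi[-1]),
        "c_xiups_final": float(moments.c_xiups[-1]),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        config.write_resolved(out)
        df.to_csv(out / "moments.csv", index=False)
        (out / "moment_checks.json").write_text(
            json.dumps({"delta_inf": df.attrs["delta_inf"], **df.attrs["checks"]},
                       indent=2) + "\n")
    return df


def report_paths(config: RunConfig, n_grid: int = 101) -> pd.DataFrame:
    """Sample paths (SSA and OU) around the macroscopic mean, long format.

    ``n_display_paths`` paths per simulator; columns
    (source, path_id, t, x, y) on a shared grid; the mean curve has
    source ``"mean"`` and path_id -1.
    """
    grid = np.linspace(0.0, config.horizon(), n_grid)
    rates = config.rates()
    init = config.initial_condition()
    K = config.K_eff
    macro = config.macro(grid)
    frames = [pd.DataFrame({"source": "mean", "path_id": -1, "t": grid,
                            "x": K * macro.x_bar, "y": K * macro.y_bar})]
    n = config.n_display_paths
    if n > 0:
        for i in range(n):
            traj = ssa.simulate_path(rates, init, grid[-1], [config.seed, i])
            xs, ys = traj.sample(grid)
            frames.append(pd.DataFrame({"source": "ssa", "path_id": i, "t": grid,
                                        "x": xs, "y": ys}))
        oue = ou.simulate_ou(rates, macro, K, grid, n, dt=config.dt,
                             seed=config.seed, boundary="absorb", init=init)
        X, Y = oue.counts()
        for i in range(n):
            frames.append(pd.DataFrame({"source": "ou", "path_id": i, "t": grid,
                                        "x": X[i], "y": Y[i]}))
    df = pd.concat(frames, ignore_index=True)
    if config.out_dir:
        out = Path(config.out_dir)
        config.write_resolved(out)
        df.to_csv(out / "paths.csv", index=False)
    return df
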