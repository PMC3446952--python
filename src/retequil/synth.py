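"""Synthetic inputs: parameter draws around the registry means, Monte-Carlo
uncertainty propagation, and noisy binding titrations with known Kd.

Every random quantity is drawn from a generator seeded through the config, so
identical configs give bit-identical output.  Parameters with a published SD
use it; those without one (kd1, kd4, kd5) use ``default_cv * mean``, and that
choice is echoed in every summary.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .equilibrium import solve_binary
from .errors import ChainBreakdownError, ConvergenceError
from .parameters import CORE_FIELDS, OPTIONAL_FIELDS, ParameterSet
from .perturbation import METHODS, _free_retinol_chain, _free_retinol_exact

DISTRIBUTION = "truncated-normal-at-zero"


@dataclass(frozen=True)
class MCConfig:
    n_draws: int = 2000
    seed: int = 0
    distribution: str = DISTRIBUTION
    default_cv: float = 0.10

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.distribution != DISTRIBUTION:
            raise ValueError(f"only {DISTRIBUTION!r} is supported")
        if self.default_cv < 0:
            raise ValueError("default_cv must be >= 0")


def _field_sd(params: ParameterSet, name: str, cv: float) -> float:
    mean = getattr(params, name)
    return params.sd.get(name, cv * mean)


def sample_parameter_sets(params: ParameterSet,
                          cfg: MCConfig) -> list[ParameterSet]:
    """Draw ``cfg.n_draws`` parameter sets, truncated-normal at zero.

    Each numeric field present in ``params`` is drawn independently around
    its value; zero-SD fields stay at their mean.
    """
    rng = np.random.default_rng(cfg.seed)
    fields = [name for name in CORE_FIELDS + OPTIONAL_FIELDS
              if getattr(params, name) is not None]
    draws: dict[str, np.ndarray] = {}
    for name in fields:  # fixed order -> reproducible stream
        mean = getattr(params, name)
        sd = _field_sd(params, name, cfg.default_cv)
        if sd == 0 or mean == 0:
            draws[name] = np.full(cfg.n_draws, mean)
        else:
            a = (0.0 - mean) / sd  # truncate at zero
            draws[name] = stats.truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd,
                size=cfg.n_draws, random_state=rng)
    return [params.with_updates(**{name: float(draws[name][i])
                                   for name in fields})
            for i in range(cfg.n_draws)]


@dataclass(frozen=True)
class MCSummary:
    """Distributional summary of the % change in free retinol."""

    scenario_percent: float
    method: str
    n_draws: int
    n_success: int
    n_infeasible: int
    mean: float
    sd: float
    p2_5: float
    p97_5: float
    default_cv: float
    seed: int
    per_draw: tuple[float, ...] = field(repr=False, default=())

    def to_dict(self, include_draws: bool = False) -> dict:
        out = {k: getattr(self, k) for k in (
            "scenario_percent", "method", "n_draws", "n_success",
            "n_infeasible", "mean", "sd", "p2_5", "p97_5",
            "default_cv", "seed")}
        if include_draws:
            out["per_draw"] = list(self.per_draw)
        return out

    def per_draw_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["draw", "pct_change_free_retinol"])
        for i, value in enumerate(self.per_draw):
            writer.writerow([i, repr(value)])
        return buf.getvalue()


def propagate_uncertainty(params: ParameterSet, cfg: MCConfig,
                          scenario_percent: float,
                          method: str = "exact") -> MCSummary:
    """Propagate registry uncertainties to the % change in free retinol.

    For each draw, free retinol is computed at the reference RBP4 level and
    at the scenario level; draws where either computation fails (chain
    breakdown, non-convergence) are counted as infeasible and excluded.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    compute = _free_retinol_exact if method == "exact" else _free_retinol_chain
    results = []
    infeasible = 0
    for draw in sample_parameter_sets(params, cfg):
        try:
            ref_free, _ = compute(draw)
            new_free, _ = compute(draw.scale_p1(scenario_percent))
        except (ChainBreakdownError, ConvergenceError):
            infeasible += 1
            continue
        if ref_free == 0:
            infeasible += 1
            continue
        results.append((new_free - ref_free) / ref_free * 100.0)
    if not results:
        raise ChainBreakdownError(
            f"all {cfg.n_draws} draws infeasible for scenario "
            f"{scenario_percent:+}%", step="propagate_uncertainty")
    arr = np.asarray(results)
    return MCSummary(
        scenario_percent=scenario_percent, method=method,
        n_draws=cfg.n_draws, n_success=len(results), n_infeasible=infeasible,
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        p2_5=float(np.percentile(arr, 2.5)),
        p97_5=float(np.percentile(arr, 97.5)),
        default_cv=cfg.default_cv, seed=cfg.seed,
        per_draw=tuple(results))


@dataclass(frozen=True)
class TitrationDataset:
    """Seeded synthetic 1:1 titration: noisy bound values over a ligand grid."""

    protein_total: float
    ligand_total: tuple[float, ...]
    observed_bound: tuple[float, ...]
    noise_sd: float
    true_kd: float
    seed: int

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["ligand_total", "observed_bound"])
        for l, b in zip(self.ligand_total, self.observed_bound):
            writer.writerow([repr(l), repr(b)])
        return buf.getvalue()

    def to_json(self, **kwargs) -> str:
        return json.dumps({
            "protein_total": self.protein_total,
            "ligand_total": list(self.ligand_total),
            "observed_bound": list(self.observed_bound),
            "noise_sd": self.noise_sd,
            "true_kd": self.true_kd,
            "seed": self.seed}, **kwargs)


def generate_titration(true_kd: float, protein_total: float,
                       ligand_grid: Sequence[float], noise_sd: float,
                       seed: int) -> TitrationDataset:
    """Closed-form binary binding curve plus seeded Gaussian noise, clipped at 0."""
    if true_kd < 0 or protein_total < 0 or noise_sd < 0:
        raise ValueError("true_kd, protein_total and noise_sd must be >= 0")
    grid = tuple(float(l) for l in ligand_grid)
    if any(l < 0 for l in grid):
        raise ValueError("ligand grid must be non-negative")
    rng = np.random.default_rng(seed)
    clean = np.array([solve_binary(l, protein_total, true_kd) for l in grid])
    noisy = clean + rng.normal(0.0, noise_sd, size=len(grid)) if grid else clean
    observed = tuple(float(v) for v in np.clip(noisy, 0.0, None))
    return TitrationDataset(protein_total=protein_total, ligand_total=grid,
                            observed_bound=observed, noise_sd=noise_sd,
                            true_kd=true_kd, seed=seed)


def fit_kd(data: TitrationDataset) -> tuple[float, float]:
    """Least-squares Kd estimate (and standard error) from a titration.

    Fits the closed-form 1:1 binding curve with the protein total known.
    Requires at least three grid points spanning the protein total so that
    the curve's curvature is identifiable.
    """
    grid = np.asarray(data.ligand_total)
    obs = np.asarray(data.observed_bound)
    if len(grid) < 3:
        raise ValueError("need >= 3 titration points to fit a Kd")
    if not (grid.min() < data.protein_total < grid.max()):
        raise ValueError(
            "ligand grid must span the protein total (points below and above)")

    def model(l, kd):
        return np.array([solve_binary(x, data.protein_total, kd) for x in l])

    popt, pcov = optimize.curve_fit(
        model, grid, obs, p0=[max(data.protein_total / 2.0, 1e-6)],
        bounds=(1e-12, np.inf), maxfev=10000)
    kd_hat = float(popt[0])
    se = float(math.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return kd_hat, se
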