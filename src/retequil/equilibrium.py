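"""Exact simultaneous mass-action equilibrium for acyclic 1:1 networks.

Two independent routes are provided:

* :func:`solve_equilibrium` — damped Newton iteration on log-transformed free
  concentrations (positivity for free; analytic Jacobian; bisection fallback).
* :func:`oracle_bisection` — Gauss–Seidel sweeps where each species' free
  concentration is found by interval bisection of its own conservation
  equation, which is strictly monotone in that concentration for acyclic
  cascades.  Slower, but derivative-free and used as an oracle in tests.

For a single 1:1 reaction :func:`solve_binary` gives the closed-form answer.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConvergenceError
from .network import BindingNetwork

DEFAULT_TOLERANCE = 1e-10
DEFAULT_MAX_ITERATIONS = 200


@dataclass(frozen=True)
class EquilibriumState:
    """Free/complex speciation with per-species conservation residuals."""

    free: dict[str, float]
    complexes: dict[str, float]
    residuals: dict[str, float]
    converged: bool
    iterations: int
    tolerance: float

    @property
    def max_residual(self) -> float:
        return max((abs(r) for r in self.residuals.values()), default=0.0)

    def bound(self, species: str, network: BindingNetwork) -> float:
        """Total amount of ``species`` sequestered in complexes."""
        comp = network.composition()
        return sum(n * self.complexes[c]
                   for c, counts in comp.items()
                   for s, n in counts.items() if s == species)

    def to_csv(self, network: BindingNetwork) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["kind", "name", "concentration", "total", "residual"])
        totals = network.totals
        for name, value in self.free.items():
            writer.writerow(["species", name, repr(value),
                             repr(totals[name]), repr(self.residuals[name])])
        for name, value in self.complexes.items():
            writer.writerow(["complex", name, repr(value), "", ""])
        return buf.getvalue()


def solve_binary(l_total: float, p_total: float, kd: float) -> float:
    """Closed-form bound concentration for one 1:1 association.

    Uses the numerically stable form of the quadratic root so that small
    bound fractions do not suffer cancellation.
    """
    if l_total < 0 or p_total < 0 or kd < 0:
        raise ValueError("solve_binary inputs must be >= 0")
    if l_total == 0 or p_total == 0:
        return 0.0
    s = l_total + p_total + kd
    disc = s * s - 4.0 * l_total * p_total
    # disc >= (l-p)^2 >= 0 mathematically; clip rounding noise
    root = math.sqrt(max(disc, 0.0))
    # stable: bound = 2lp / (s + sqrt(disc))
    return 2.0 * l_total * p_total / (s + root)


def _complex_concs(free: dict[str, float], comp, kprod) -> dict[str, float]:
    out = {}
    for name, counts in comp.items():
        value = 1.0 / kprod[name]
        for s, n in counts.items():
            value *= free[s] ** n
        out[name] = value
    return out


def _residuals(network: BindingNetwork, free: dict[str, float],
               comp, kprod) -> dict[str, float]:
    cx = _complex_concs(free, comp, kprod)
    res = {}
    for name, total in network.species:
        bound = sum(counts[name] * cx[c]
                    for c, counts in comp.items() if name in counts)
        res[name] = free[name] + bound - total
    return res


def _state_from_free(network: BindingNetwork, free: dict[str, float],
                     converged: bool, iterations: int,
                     tolerance: float) -> EquilibriumState:
    comp = network.composition()
    kprod = network.kd_products()
    cx = _complex_concs(free, comp, kprod)
    res = _residuals(network, free, comp, kprod)
    return EquilibriumState(free=dict(free), complexes=cx, residuals=res,
                            converged=converged, iterations=iterations,
                            tolerance=tolerance)


def _bisect_species(name: str, total: float, free: dict[str, float],
                    comp, kprod) -> float:
    """Solve this species' conservation equation by bisection, others fixed."""
    if total == 0.0:
        return 0.0

    def g(f: float) -> float:
        trial = dict(free)
        trial[name] = f
        bound = 0.0
        for c, counts in comp.items():
            if name not in counts:
                continue
            value = 1.0 / kprod[c]
            for s, n in counts.items():
                value *= trial[s] ** n
            bound += counts[name] * value
        return f + bound - total

    lo, hi = 0.0, total
    # g(0) = -total < 0 and g(total) >= 0: bound fraction is non-negative
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if g(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def oracle_bisection(network: BindingNetwork,
                     tolerance: float = DEFAULT_TOLERANCE,
                     max_sweeps: int = 20000) -> EquilibriumState:
    """Reference solver: Gauss–Seidel with per-species interval bisection."""
    comp = network.composition()
    kprod = network.kd_products()
    free = {name: total for name, total in network.species}
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        for name, total in network.species:
            free[name] = _bisect_species(name, total, free, comp, kprod)
        res = _residuals(network, free, comp, kprod)
        if max(abs(r) for r in res.values()) < tolerance if res else True:
            return _state_from_free(network, free, True, sweeps, tolerance)
    state = _state_from_free(network, free, False, sweeps, tolerance)
    raise ConvergenceError(
        f"bisection oracle did not reach {tolerance} in {max_sweeps} sweeps "
        f"(best residual {state.max_residual})", state=state)


def solve_equilibrium(network: BindingNetwork,
                      tolerance: float = DEFAULT_TOLERANCE,
                      max_iterations: int = DEFAULT_MAX_ITERATIONS) -> EquilibriumState:
    """Damped Newton on log free concentrations; bisection fallback.

    Deterministic: identical inputs give bit-identical outputs.  Raises
    :class:`ConvergenceError` (carrying the best iterate) only if both the
    Newton route and the bisection fallback fail.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    comp = network.composition()
    kprod = network.kd_products()
    active = [(name, total) for name, total in network.species if total > 0]
    zero = {name: 0.0 for name, total in network.species if total == 0}
    if not active:
        return _state_from_free(network, dict(zero), True, 0, tolerance)

    # complexes involving a zero-total species vanish identically
    reactive = {name for name, _ in active}
    live = {c: counts for c, counts in comp.items()
            if all(s in reactive for s in counts)}
    in_reaction = {s for counts in live.values() for s in counts}
    # species outside every live complex equilibrate trivially: free == total
    inert = {name: total for name, total in active if name not in in_reaction}
    active = [(name, total) for name, total in active if name in in_reaction]
    if not active:
        free = dict(zero)
        free.update(inert)
        return _state_from_free(network, free, True, 0, tolerance)

    names = [name for name, _ in active]
    totals = np.array([total for _, total in active])
    idx = {name: i for i, name in enumerate(names)}
    count_mat = {c: np.array([counts.get(name, 0) for name in names])
                 for c, counts in live.items()}

    def residual_vec(x: np.ndarray) -> np.ndarray:
        f = np.exp(x)
        res = f - totals
        for c, counts in count_mat.items():
            conc = math.exp(float(counts @ x)) / kprod[c]
            res = res + counts * conc
        return res

    def jacobian(x: np.ndarray) -> np.ndarray:
        f = np.exp(x)
        jac = np.diag(f)
        for c, counts in count_mat.items():
            conc = math.exp(float(counts @ x)) / kprod[c]
            jac = jac + conc * np.outer(counts, counts)
        return jac

    x = np.log(totals) - math.log(2.0)  # start at half the totals
    res = residual_vec(x)
    norm = float(np.max(np.abs(res)))
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        if norm < tolerance:
            break
        try:
            step = np.linalg.solve(jacobian(x), -res)
        except np.linalg.LinAlgError:
            break
        # cap the log-space step to keep the iteration in a sane range
        scale = float(np.max(np.abs(step)))
        if scale > 5.0:
            step = step * (5.0 / scale)
        improved = False
        damp = 1.0
        for _ in range(60):
            x_new = x + damp * step
            res_new = residual_vec(x_new)
            norm_new = float(np.max(np.abs(res_new)))
            if norm_new < norm:
                x, res, norm = x_new, res_new, norm_new
                improved = True
                break
            damp *= 0.5
        if not improved:
            break

    if norm < tolerance:
        free = dict(zero)
        free.update(inert)
        free.update({name: float(math.exp(x[idx[name]])) for name in names})
        return _state_from_free(network, free, True, iterations, tolerance)

    # fallback: derivative-free route
    try:
        return oracle_bisection(network, tolerance)
    except ConvergenceError as exc:
        newton_free = dict(zero)
        newton_free.update(inert)
        newton_free.update({name: float(math.exp(x[idx[name]]))
                            for name in names})
        newton_state = _state_from_free(network, newton_free, False,
                                        iterations, tolerance)
        best = min((newton_state, exc.state), key=lambda s: s.max_residual)
        raise ConvergenceError(
            f"equilibrium solve failed (best residual {best.max_residual})",
            state=best) from exc
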