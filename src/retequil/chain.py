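"""Stepwise approximation chain for free RBP4 and the inferred retinol Kd.

This is a faithful reimplementation of a published back-of-envelope
calculation, approximations included, so that its intermediate numbers can be
reproduced and audited.  Each approximation applied is recorded in
``ChainResult.assumptions``; the exact simultaneous alternative lives in
:mod:`retequil.equilibrium`.

The chain, with default parameters, proceeds:

1. ternary step — with free retinol neglected and holo-complex ≈ ternary
   complex ≈ total retinol, the ternary mass-action law collapses to
   ``free P2 = kd_ternary`` (0.075);
2. residual TTR — ``p2_total - free P2`` (4.835);
3. apo step — the apoRBP·TTR complex is taken at its ceiling ``p1_total``,
   leaving ``free P2 = residual - p1_total`` (1.605) and by mass action
   ``free P1 = kd3 * p1_total / free P2`` (0.664);
4. Kd inference — ``kd1 = rt_free * free P1 / holo`` with ``rt_free`` and
   ``holo`` both set to total retinol, hence ``kd1 = free P1`` (0.664).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from .errors import ChainBreakdownError
from .parameters import ParameterSet

A_NEGLECT_FREE_RT = "free retinol neglected; holo == ternary == total retinol"
A_COMPLEX_AT_CEILING = "apoRBP-TTR complex taken at its ceiling p1_total"
A_RT_FREE_EQ_HOLO = "free retinol and holo-complex both set to total retinol"


@dataclass(frozen=True)
class ChainResult:
    """The four intermediate values plus the inferred dissociation constant."""

    ternary_free_p2: float
    residual_p2: float
    free_p2_for_apo: float
    free_p1: float
    inferred_kd1: float
    assumptions: tuple[str, ...] = field(default_factory=tuple)

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.ternary_free_p2, self.residual_p2, self.free_p2_for_apo,
                self.free_p1, self.inferred_kd1)

    def to_dict(self) -> dict:
        return {
            "ternary_free_p2": self.ternary_free_p2,
            "residual_p2": self.residual_p2,
            "free_p2_for_apo": self.free_p2_for_apo,
            "free_p1": self.free_p1,
            "inferred_kd1": self.inferred_kd1,
            "assumptions": list(self.assumptions),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["quantity", "value"])
        for key, value in self.to_dict().items():
            if key == "assumptions":
                continue
            writer.writerow([key, repr(value)])
        return buf.getvalue()


def ternary_step(rt_total: float, kd_ternary: float,
                 complex_ratio: float = 1.0) -> float:
    """Free TTR at the ternary equilibrium under the equal-complex collapse.

    With holo-complex and ternary complex both approximated by total retinol,
    the mass-action law leaves ``free P2 = kd_ternary * complex_ratio`` where
    ``complex_ratio`` is holo/ternary (1 under the published approximation).
    ``rt_total`` is accepted for interface symmetry and validated only.
    """
    if rt_total < 0 or kd_ternary < 0:
        raise ValueError("ternary_step inputs must be >= 0")
    if complex_ratio <= 0:
        raise ValueError("complex_ratio must be > 0")
    return kd_ternary * complex_ratio


def residual_prealbumin(p2_total: float, ternary_free_p2: float) -> float:
    """TTR remaining after the ternary step: ``p2_total - ternary_free_p2``."""
    result = p2_total - ternary_free_p2
    if result < 0:
        raise ChainBreakdownError(
            f"residual TTR is negative ({result}): free TTR at the ternary "
            f"step ({ternary_free_p2}) exceeds total TTR ({p2_total})",
            step="residual_prealbumin")
    return result


def apo_step(p1_total: float, residual_p2: float,
             kd3: float) -> tuple[float, float]:
    """Free TTR and free RBP4 after the apoRBP·TTR step.

    The apoRBP·TTR complex is taken at its ceiling ``p1_total``; the leftover
    TTR is ``residual_p2 - p1_total`` and mass action gives
    ``free_p1 = kd3 * p1_total / free_p2``.
    """
    free_p2 = residual_p2 - p1_total
    if free_p2 <= 0:
        raise ChainBreakdownError(
            f"total RBP4 ({p1_total} µmol/L) meets or exceeds the residual "
            f"TTR ({residual_p2} µmol/L): the chain's assumption that all "
            "RBP4 can be TTR-bound leaves no free TTR, so the approximation "
            "breaks down (this happens for RBP4 upregulation of about +50%)",
            step="apo_step")
    free_p1 = kd3 * p1_total / free_p2
    return free_p2, free_p1


def infer_kd1(rt_free: float, holo_complex: float, free_p1: float) -> float:
    """Dissociation constant ``rt_free * free_p1 / holo_complex``.

    Equals ``free_p1`` whenever ``rt_free == holo_complex`` — the published
    choice sets both to total retinol, so the retinol terms cancel.
    """
    if holo_complex <= 0:
        raise ValueError("holo_complex must be > 0")
    return rt_free * free_p1 / holo_complex


def run_chain(params: ParameterSet) -> ChainResult:
    """Run the full approximation chain on a parameter set."""
    ternary_free_p2 = ternary_step(params.rt_total, params.kd2)
    residual_p2 = residual_prealbumin(params.p2_total, ternary_free_p2)
    free_p2, free_p1 = apo_step(params.p1_total, residual_p2, params.kd3)
    kd1 = infer_kd1(params.rt_total, params.rt_total, free_p1)
    return ChainResult(
        ternary_free_p2=ternary_free_p2,
        residual_p2=residual_p2,
        free_p2_for_apo=free_p2,
        free_p1=free_p1,
        inferred_kd1=kd1,
        assumptions=(A_NEGLECT_FREE_RT, A_COMPLEX_AT_CEILING,
                     A_RT_FREE_EQ_HOLO),
    )
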