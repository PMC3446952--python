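"""Closed-form radical kinetics: second-order half-life and the
spontaneous-dismutation vs enzymatic-decomposition crossover.

Rate constants carry a units string that is checked before use, so a
first-order constant cannot be passed where a second-order one is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .errors import UnitError

SECOND_ORDER = "M^-1 s^-1"
FIRST_ORDER = "s^-1"
_KNOWN_UNITS = (SECOND_ORDER, FIRST_ORDER)


@dataclass(frozen=True)
class RateConstant:
    """A rate constant with explicit units (``M^-1 s^-1`` or ``s^-1``)."""

    value: float
    units: str

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"rate constant must be > 0, got {self.value}")
        if self.units not in _KNOWN_UNITS:
            raise UnitError(
                f"unknown units {self.units!r}; expected one of {_KNOWN_UNITS}")

    def require(self, units: str) -> float:
        if self.units != units:
            raise UnitError(
                f"expected a {units} rate constant, got {self.units}")
        return self.value

    def to_dict(self) -> dict:
        return {"value": self.value, "units": self.units}


def second_order_halflife(k: "RateConstant | float", c0: float) -> float:
    """Half-life ``1 / (k * c0)`` of a species decaying by self-reaction.

    ``k`` in M^-1 s^-1, ``c0`` in mol/L, result in seconds.  The inverse
    dependence on the initial concentration is the signature of second-order
    decay: dilute radicals persist far longer than concentrated ones.
    """
    if isinstance(k, RateConstant):
        k = k.require(SECOND_ORDER)
    if k <= 0 or c0 <= 0:
        raise ValueError("k and c0 must be > 0")
    return 1.0 / (k * c0)


def dismutation_vs_enzyme(k_dismutation: "RateConstant | float",
                          kcat_over_km: "RateConstant | float",
                          enzyme_conc: float) -> float:
    """Radical concentration where spontaneous and enzymatic rates match.

    The spontaneous route is second order in the radical (rate ``k * c^2``)
    while the enzymatic route is pseudo-first order (``(kcat/Km) * E * c``);
    they are equal at ``c = (kcat/Km) * E / k``.  Below the crossover the
    enzyme wins; above it, spontaneous dismutation does.
    """
    if isinstance(k_dismutation, RateConstant):
        k_dismutation = k_dismutation.require(SECOND_ORDER)
    if isinstance(kcat_over_km, RateConstant):
        kcat_over_km = kcat_over_km.require(SECOND_ORDER)
    if k_dismutation <= 0 or kcat_over_km <= 0:
        raise ValueError("rate constants must be > 0")
    if enzyme_conc < 0:
        raise ValueError("enzyme_conc must be >= 0")
    return kcat_over_km * enzyme_conc / k_dismutation


def to_json(result: float, label: str, **kwargs) -> str:
    return json.dumps({label: result}, **kwargs)
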