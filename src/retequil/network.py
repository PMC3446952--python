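"""Binding-network description: species, 1:1 reactions, dissociation constants.

A network is an acyclic cascade of 1:1 association reactions.  Each reaction
joins two reactants — either base species or previously defined complexes —
into a named complex with a dissociation constant.  Acyclicity (a complex may
only be built from things defined before it) makes every total→free map
monotone, which both solvers rely on.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigError
from .parameters import ParameterSet


@dataclass(frozen=True)
class Reaction:
    """1:1 association ``side_a + side_b <-> product`` with dissociation Kd."""

    side_a: str
    side_b: str
    product: str
    kd: float

    def __post_init__(self):
        if self.kd <= 0:
            raise ConfigError(
                f"reaction {self.product!r}: Kd must be > 0, got {self.kd}")


@dataclass(frozen=True)
class BindingNetwork:
    """Species with total concentrations plus an ordered reaction cascade."""

    species: tuple[tuple[str, float], ...]
    reactions: tuple[Reaction, ...] = ()

    def __post_init__(self):
        names = [name for name, _ in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate species names")
        for name, total in self.species:
            if total < 0:
                raise ConfigError(f"species {name!r}: total must be >= 0")
        defined = set(names)
        for rxn in self.reactions:
            for side in (rxn.side_a, rxn.side_b):
                if side not in defined:
                    raise ConfigError(
                        f"reaction {rxn.product!r}: reactant {side!r} not yet "
                        "defined (networks must be acyclic cascades)")
            if rxn.product in defined:
                raise ConfigError(f"complex {rxn.product!r} defined twice")
            defined.add(rxn.product)

    # ------------------------------------------------------------- structure
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.species)

    @property
    def totals(self) -> dict[str, float]:
        return dict(self.species)

    @property
    def complex_names(self) -> tuple[str, ...]:
        return tuple(rxn.product for rxn in self.reactions)

    def composition(self) -> dict[str, Counter]:
        """Base-species composition of every complex.

        Resolved by walking the cascade in order, so a ternary complex built
        from a binary one counts each base species once.
        """
        comp: dict[str, Counter] = {name: Counter({name: 1})
                                    for name in self.species_names}
        for rxn in self.reactions:
            comp[rxn.product] = comp[rxn.side_a] + comp[rxn.side_b]
        return {name: comp[name] for name in self.complex_names}

    def kd_products(self) -> dict[str, float]:
        """Cumulative Kd product per complex.

        ``[complex] = prod(free base concentrations) / kd_product``, obtained
        by chaining the per-step mass-action laws down the cascade.
        """
        kprod: dict[str, float] = {name: 1.0 for name in self.species_names}
        for rxn in self.reactions:
            kprod[rxn.product] = kprod[rxn.side_a] * kprod[rxn.side_b] * rxn.kd
        return {name: kprod[name] for name in self.complex_names}

    # --------------------------------------------------------- serialization
    def to_json(self, **kwargs) -> str:
        payload = {
            "species": [{"name": n, "total": t} for n, t in self.species],
            "reactions": [{"side_a": r.side_a, "side_b": r.side_b,
                           "product": r.product, "kd": r.kd}
                          for r in self.reactions],
        }
        return json.dumps(payload, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "BindingNetwork":
        payload = json.loads(text)
        species = tuple((s["name"], float(s["total"]))
                        for s in payload["species"])
        reactions = tuple(Reaction(r["side_a"], r["side_b"],
                                   r["product"], float(r["kd"]))
                          for r in payload.get("reactions", []))
        return cls(species, reactions)


# canonical species / complex names used throughout
RT = "Rt"
P1 = "P1"
P2 = "P2"
P3 = "P3"
P4 = "P4"
RA = "RA"
HOLO = "Rt-P1"          # retinol·RBP4
TERNARY = "Rt-P1-P2"    # retinol·RBP4·TTR
APO_TTR = "P1-P2"       # apoRBP·TTR
RA_P3 = "RA-P3"
RA_P4 = "RA-P4"


def build_network(params: ParameterSet, include_ra: bool = False) -> BindingNetwork:
    """Assemble the carrier-protein network from a parameter set.

    The retinol side always contains three coupled reactions: retinol+RBP4,
    holoRBP+TTR (ternary), and apoRBP+TTR.  With ``include_ra`` the retinoic
    acid side (RA+CRABP1, RA+CRABP2) is appended, which requires the optional
    totals to be present.
    """
    species: list[tuple[str, float]] = [
        (RT, params.rt_total),
        (P1, params.p1_total),
        (P2, params.p2_total),
    ]
    reactions: list[Reaction] = [
        Reaction(RT, P1, HOLO, params.kd1),
        Reaction(HOLO, P2, TERNARY, params.kd2),
        Reaction(P1, P2, APO_TTR, params.kd3),
    ]
    if include_ra:
        missing = [name for name in ("ra_total", "p3_total", "p4_total")
                   if getattr(params, name) is None]
        if missing:
            raise ConfigError(
                "include_ra requires ra_total, p3_total and p4_total; "
                f"missing: {missing}")
        species += [(RA, params.ra_total), (P3, params.p3_total),
                    (P4, params.p4_total)]
        reactions += [
            Reaction(RA, P3, RA_P3, params.kd4_umol()),
            Reaction(RA, P4, RA_P4, params.kd5_umol()),
        ]
    return BindingNetwork(tuple(species), tuple(reactions))
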