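"""Parameter registry for the retinol carrier-protein equilibrium model.

All concentrations and dissociation constants are handled in µmol/L unless a
per-constant unit says otherwise (``kd4``/``kd5`` may be flagged as nmol/L,
reflecting the two unit conventions found in the source literature for the
CRABP constants).  Molecular weights are stored in Da.

The default registry corresponds to the published plasma/cytoplasm values:

======== =========== ===== ==========================================
field    value       sd    meaning
======== =========== ===== ==========================================
rt_total 1.73        0.34  total retinol
p1_total 3.23        0.62  total RBP4
p2_total 4.91        1.27  total prealbumin (transthyretin)
kd1      0.664       --    retinol·RBP4 (alternate 0.20)
kd2      0.075       0.015 holoRBP·TTR ternary step
kd3      0.33        0.11  apoRBP·TTR (alternate 0.4)
kd4      0.06        --    RA·CRABP1
kd5      0.13        --    RA·CRABP2
======== =========== ===== ==========================================
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .errors import ConfigError

#: fields that always carry a value (µmol/L except the kd4/kd5 unit switch)
CORE_FIELDS = ("rt_total", "p1_total", "p2_total",
               "kd1", "kd2", "kd3", "kd4", "kd5")

#: fields that are user-supplied only (the literature prints no totals)
OPTIONAL_FIELDS = ("p3_total", "p4_total", "ra_total")

#: extra configuration keys accepted by :func:`load_parameters`
META_KEYS = ("kd45_unit",)

DEFAULTS: dict[str, float] = {
    "rt_total": 1.73,
    "p1_total": 3.23,
    "p2_total": 4.91,
    "kd1": 0.664,
    "kd2": 0.075,
    "kd3": 0.33,
    "kd4": 0.06,
    "kd5": 0.13,
}

DEFAULT_SD: dict[str, float] = {
    "rt_total": 0.34,
    "p1_total": 0.62,
    "p2_total": 1.27,
    "kd2": 0.015,
    "kd3": 0.11,
}

#: alternate published values selectable by the string "alt"
ALTERNATES: dict[str, float] = {
    "kd1": 0.20,   # recombinant-protein determination
    "kd3": 0.4,    # recombinant TTR, two equivalent sites
}

#: molecular weights in Da (the source table prints "kDa" where Da is
#: chemically required; stored here in Da)
DEFAULT_MW: dict[str, float] = {
    "retinol": 286.0,
    "rbp4": 21000.0,
    "prealbumin": 55000.0,
    "ternary_complex": 55286.0,
}

VALID_KEYS = CORE_FIELDS + OPTIONAL_FIELDS + META_KEYS

PROVENANCE_DEFAULT = "default"
PROVENANCE_USER = "user"


@dataclass(frozen=True)
class ParameterSet:
    """Immutable bundle of totals and dissociation constants.

    ``sd`` maps field name -> standard deviation where one is published;
    ``provenance`` maps field name -> "default" | "user".
    """

    rt_total: float = DEFAULTS["rt_total"]
    p1_total: float = DEFAULTS["p1_total"]
    p2_total: float = DEFAULTS["p2_total"]
    kd1: float = DEFAULTS["kd1"]
    kd2: float = DEFAULTS["kd2"]
    kd3: float = DEFAULTS["kd3"]
    kd4: float = DEFAULTS["kd4"]
    kd5: float = DEFAULTS["kd5"]
    p3_total: Optional[float] = None
    p4_total: Optional[float] = None
    ra_total: Optional[float] = None
    kd45_unit: str = "umol/L"
    sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SD))
    mw: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MW))
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in CORE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ConfigError(f"parameter {name!r} must be >= 0, got {value}")
        for name in OPTIONAL_FIELDS:
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ConfigError(f"parameter {name!r} must be >= 0, got {value}")
        for name, value in self.sd.items():
            if value < 0:
                raise ConfigError(f"sd for {name!r} must be >= 0, got {value}")
        if self.kd45_unit not in ("umol/L", "nmol/L"):
            raise ConfigError(
                f"kd45_unit must be 'umol/L' or 'nmol/L', got {self.kd45_unit!r}")
        prov = dict(self.provenance)
        for name in CORE_FIELDS + OPTIONAL_FIELDS:
            prov.setdefault(name, PROVENANCE_DEFAULT)
        object.__setattr__(self, "provenance", prov)
        object.__setattr__(self, "sd", dict(self.sd))
        object.__setattr__(self, "mw", dict(self.mw))

    # ------------------------------------------------------------------ units
    def kd4_umol(self) -> float:
        """kd4 expressed in µmol/L regardless of the declared unit."""
        return self.kd4 * (1e-3 if self.kd45_unit == "nmol/L" else 1.0)

    def kd5_umol(self) -> float:
        """kd5 expressed in µmol/L regardless of the declared unit."""
        return self.kd5 * (1e-3 if self.kd45_unit == "nmol/L" else 1.0)

    # ------------------------------------------------------------- accessors
    def with_updates(self, **kwargs: float) -> "ParameterSet":
        """Return a copy with the given fields replaced (provenance 'user')."""
        prov = dict(self.provenance)
        for key in kwargs:
            if key not in CORE_FIELDS + OPTIONAL_FIELDS + META_KEYS:
                raise ConfigError(
                    f"unknown parameter {key!r}; valid keys: {sorted(VALID_KEYS)}")
            prov[key] = PROVENANCE_USER
        return replace(self, provenance=prov, **kwargs)

    def scale_p1(self, level_percent: float) -> "ParameterSet":
        """Copy with total RBP4 scaled by ``(1 + level_percent/100)``."""
        return self.with_updates(p1_total=self.p1_total * (1.0 + level_percent / 100.0))

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {name: getattr(self, name) for name in CORE_FIELDS}
        for name in OPTIONAL_FIELDS:
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        out["kd45_unit"] = self.kd45_unit
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def registry_csv(self) -> str:
        """Machine-readable dump: columns name,value,sd,units,source."""
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["name", "value", "sd", "units", "source"])
        for name in CORE_FIELDS + OPTIONAL_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            units = self.kd45_unit if name in ("kd4", "kd5") else "umol/L"
            writer.writerow([name, value, self.sd.get(name, ""),
                             units, self.provenance[name]])
        for name, mw in self.mw.items():
            writer.writerow([f"mw_{name}", mw, "", "Da", PROVENANCE_DEFAULT])
        return buf.getvalue()


def _parse_config(source) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config {path} must be a flat key->value map")
    return dict(data)


def load_parameters(source=None) -> ParameterSet:
    """Build a :class:`ParameterSet` from defaults plus optional overrides.

    ``source`` may be a mapping, a path to a JSON/YAML file, or ``None``.
    Numeric values override the defaults; the string ``"alt"`` selects the
    alternate published value where one exists (kd1, kd3).  Unknown keys and
    negative values are hard errors.
    """
    config = _parse_config(source) if source is not None else {}
    unknown = set(config) - set(VALID_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown parameter key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(VALID_KEYS)}")
    updates: dict[str, Any] = {}
    for key, value in config.items():
        if isinstance(value, str) and key not in META_KEYS:
            if value == "alt" and key in ALTERNATES:
                updates[key] = ALTERNATES[key]
            else:
                raise ConfigError(
                    f"non-numeric value {value!r} for {key!r} "
                    f"(only 'alt' is accepted, for {sorted(ALTERNATES)})")
        else:
            updates[key] = value
    return ParameterSet().with_updates(**updates) if updates else ParameterSet()
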