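"""End-to-end report: chain, perturbation scans, reference comparison,
headline metrics and Monte-Carlo summary in one JSON-serializable object."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import __version__
from .chain import run_chain
from .errors import ChainBreakdownError, ConfigError
from .parameters import ParameterSet, load_parameters
from .perturbation import (compare_to_reference, fold_to_percent,
                           percent_change, scan_rbp4)
from .reference import (ASSAY_MEANS, PROTEIN_FOLD_CHANGES, RBP4_SPOT,
                        REFERENCE_SCAN, reference_row)
from .synth import MCConfig, propagate_uncertainty

DEFAULT_LEVELS = (50.0, 40.0, 30.0, 0.0, -30.0, -40.0, -50.0)
#: measured RBP4 downregulation driving the headline scenario
DEFAULT_SCENARIO_PERCENT = -32.0


@dataclass(frozen=True)
class AnalysisReport:
    sections: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return self.sections

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.sections, **kwargs)


def _load_report_config(source) -> dict[str, Any]:
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"report config {path} must be a mapping")
    return dict(data)


def _headline(params: ParameterSet, scenario_percent: float) -> dict[str, Any]:
    ref = reference_row(0.0)
    down = reference_row(-30.0)
    exact_scan = scan_rbp4(params, [0.0, scenario_percent], method="exact")
    exact_pct = exact_scan[1].pct_change_free_vs_reference
    return {
        "rbp4_fold_change": PROTEIN_FOLD_CHANGES[RBP4_SPOT],
        "rbp4_percent_change": fold_to_percent(
            PROTEIN_FOLD_CHANGES[RBP4_SPOT], convention="paper"),
        "reference_free_retinol_pct_change_at_-30": round(
            percent_change(ref.rt_free, down.rt_free), 1),
        "exact_free_retinol_pct_change_at_scenario": exact_pct,
        "scenario_percent": scenario_percent,
        "assay_percent_changes": {
            name: round(percent_change(control, treated), 1)
            for name, (control, treated) in ASSAY_MEANS.items()},
    }


def run_full_analysis(config=None) -> AnalysisReport:
    """Assemble every analysis stage into one report.

    ``config`` may be ``None``, a mapping, or a JSON/YAML path with optional
    keys ``parameters`` (flat override map), ``levels``, ``scenario_percent``
    and ``mc`` (``n_draws``/``seed``/``default_cv``/``method``;
    ``n_draws: 0`` omits the Monte-Carlo section).
    """
    cfg = _load_report_config(config)
    unknown = set(cfg) - {"parameters", "levels", "scenario_percent", "mc"}
    if unknown:
        raise ConfigError(f"unknown report config key(s) {sorted(unknown)}")
    params = load_parameters(cfg.get("parameters"))
    levels = [float(l) for l in cfg.get("levels", DEFAULT_LEVELS)]
    if 0.0 not in levels:
        levels.append(0.0)
    scenario = float(cfg.get("scenario_percent", DEFAULT_SCENARIO_PERCENT))
    mc_cfg = dict(cfg.get("mc", {}))
    mc_n = int(mc_cfg.pop("n_draws", 1000))
    mc_method = mc_cfg.pop("method", "exact")
    mc_seed = int(mc_cfg.pop("seed", 0))
    mc_cv = float(mc_cfg.pop("default_cv", 0.10))
    if mc_cfg:
        raise ConfigError(f"unknown mc config key(s) {sorted(mc_cfg)}")

    sections: dict[str, Any] = {}
    sections["parameters"] = params.to_dict()

    try:
        sections["chain"] = run_chain(params).to_dict()
    except ChainBreakdownError as exc:
        sections["chain"] = {"error": str(exc), "step": exc.step}

    exact = scan_rbp4(params, levels, method="exact")
    chain = scan_rbp4(params, levels, method="chain")
    sections["scan"] = {
        "exact": [row.to_dict() for row in exact],
        "chain": [row.to_dict() for row in chain],
    }
    sections["reference_comparison"] = compare_to_reference(
        [row for row in exact
         if row.level_percent in {r.level_percent for r in REFERENCE_SCAN}]
    ).to_dict()
    sections["headline"] = _headline(params, scenario)

    if mc_n > 0:
        summary = propagate_uncertainty(
            params, MCConfig(n_draws=mc_n, seed=mc_seed, default_cv=mc_cv),
            scenario_percent=scenario, method=mc_method)
        sections["mc"] = summary.to_dict()

    sections["provenance"] = {
        "tool": "retequil",
        "version": __version__,
        "parameter_sources": dict(params.provenance),
        "mc_seed": mc_seed if mc_n > 0 else None,
        "mc_default_cv": mc_cv if mc_n > 0 else None,
        "levels": levels,
    }
    return AnalysisReport(sections=sections)
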