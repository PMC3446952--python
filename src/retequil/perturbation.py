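"""RBP4-level perturbation scans and the headline percent-change metrics.

Two routes produce each scan row:

* ``"exact"`` — the three-reaction network is re-solved simultaneously at the
  scaled total RBP4;
* ``"chain"`` — the stepwise approximation chain is re-run, after which
  retinol is partitioned by ``rt_free/rt_bound = kd1/free_p1`` together with
  retinol conservation.  Levels where the chain breaks down are flagged, not
  fabricated.

The published bound/free columns cannot be regenerated from any single
mass-action relation with the printed Kd (the implied constant differs row to
row), so they are shipped as a read-only fixture (:mod:`retequil.reference`)
and compared against, never asserted equal.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .chain import run_chain
from .equilibrium import solve_equilibrium
from .errors import ChainBreakdownError
from .network import RT, build_network
from .parameters import ParameterSet
from .reference import REFERENCE_RT_TOTAL, REFERENCE_SCAN, ReferenceScanRow

METHODS = ("exact", "chain")


@dataclass(frozen=True)
class PerturbationRow:
    level_percent: float
    p1_total: float
    rt_bound: Optional[float]
    rt_free: Optional[float]
    pct_change_free_vs_reference: Optional[float]
    method: str
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "level_percent": self.level_percent,
            "p1_total": self.p1_total,
            "rt_bound": self.rt_bound,
            "rt_free": self.rt_free,
            "pct_change_free_vs_reference": self.pct_change_free_vs_reference,
            "method": self.method,
            "status": self.status,
        }


def percent_change(reference: float, new: float) -> float:
    """Signed percent change ``(new - reference) / reference * 100``."""
    if reference == 0:
        raise ValueError("percent_change reference must be nonzero")
    return (new - reference) / reference * 100.0


def fold_to_percent(fold: float, convention: str = "paper") -> float:
    """Convert a signed fold change to a signed percent change.

    ``"paper"`` uses the sign-magnitude reading common in proteomics tables:
    ``sign(fold) * (|fold| - 1) * 100`` (so -1.32 -> -32%); it requires
    ``|fold| >= 1``.  ``"ratio"`` treats a negative fold -f as the ratio
    1/f: ``(1/|fold| - 1) * 100`` for negative folds, ``(|fold| - 1) * 100``
    for positive ones.
    """
    if fold == 0:
        raise ValueError("fold change cannot be 0")
    if convention == "paper":
        if abs(fold) < 1:
            raise ValueError(
                f"sign-magnitude convention requires |fold| >= 1, got {fold}")
        return math.copysign((abs(fold) - 1.0) * 100.0, fold)
    if convention == "ratio":
        if fold < 0:
            return (1.0 / abs(fold) - 1.0) * 100.0
        return (fold - 1.0) * 100.0
    raise ValueError(f"unknown convention {convention!r}")


def _free_retinol_exact(params: ParameterSet) -> tuple[float, float]:
    state = solve_equilibrium(build_network(params))
    rt_free = state.free[RT]
    return rt_free, params.rt_total - rt_free


def _free_retinol_chain(params: ParameterSet) -> tuple[float, float]:
    result = run_chain(params)
    # rt_free / rt_bound = kd1 / free_p1, plus retinol conservation
    rt_free = params.rt_total * params.kd1 / (params.kd1 + result.free_p1)
    return rt_free, params.rt_total - rt_free


def scan_rbp4(params: ParameterSet, levels: Sequence[float],
              method: str = "exact") -> list[PerturbationRow]:
    """Scan signed % changes of total RBP4; one row per level.

    ``levels`` must contain 0, the reference against which the per-row
    percent change of free retinol is computed.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if 0 not in levels and 0.0 not in levels:
        raise ValueError("levels must include 0 (the reference level)")
    compute = _free_retinol_exact if method == "exact" else _free_retinol_chain

    values: dict[float, tuple[Optional[float], Optional[float], str]] = {}
    for level in levels:
        scaled = params.scale_p1(level)
        try:
            rt_free, rt_bound = compute(scaled)
            values[level] = (rt_free, rt_bound, "ok")
        except ChainBreakdownError:
            values[level] = (None, None, "chain-breakdown")

    ref_free = values[0][0]
    rows = []
    for level in levels:
        rt_free, rt_bound, status = values[level]
        pct = None
        if status == "ok" and ref_free:
            pct = percent_change(ref_free, rt_free)
            if level == 0:
                pct = 0.0  # exact by definition, not merely within epsilon
        rows.append(PerturbationRow(
            level_percent=float(level),
            p1_total=params.p1_total * (1.0 + level / 100.0),
            rt_bound=rt_bound, rt_free=rt_free,
            pct_change_free_vs_reference=pct,
            method=method, status=status))
    return rows


@dataclass(frozen=True)
class ComparisonRow:
    level_percent: float
    rt_bound_scan: Optional[float]
    rt_free_scan: Optional[float]
    rt_bound_ref: float
    rt_free_ref: float
    abs_diff_bound: Optional[float]
    abs_diff_free: Optional[float]
    rel_diff_free: Optional[float]

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass(frozen=True)
class ComparisonReport:
    """Per-row differences against the published reference scan.

    Reports discrepancies; it deliberately never asserts agreement, because
    the reference columns are not regenerable from a single mass-action
    relation.
    """

    rows: tuple[ComparisonRow, ...]
    fixture_conserves_retinol: bool

    def to_dict(self) -> dict:
        return {
            "fixture_conserves_retinol": self.fixture_conserves_retinol,
            "rows": [r.to_dict() for r in self.rows],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def fixture_self_test(rows: Iterable[ReferenceScanRow] = REFERENCE_SCAN,
                      rt_total: float = REFERENCE_RT_TOTAL) -> bool:
    """True iff every reference row conserves total retinol exactly.

    The printed values are 2-decimal; "exactly" means exact at that printed
    precision (comparison after rounding both sides to 2 decimals).
    """
    return all(round(r.rt_bound + r.rt_free, 2) == round(rt_total, 2)
               for r in rows)


def compare_to_reference(scan: Sequence[PerturbationRow]) -> ComparisonReport:
    """Diff a scan against the published reference rows, level by level."""
    by_level = {row.level_percent: row for row in REFERENCE_SCAN}
    rows = []
    for row in scan:
        if row.level_percent not in by_level:
            raise KeyError(
                f"scan level {row.level_percent:+}% has no reference row")
        ref = by_level[row.level_percent]
        ok = row.status == "ok"
        rows.append(ComparisonRow(
            level_percent=row.level_percent,
            rt_bound_scan=row.rt_bound, rt_free_scan=row.rt_free,
            rt_bound_ref=ref.rt_bound, rt_free_ref=ref.rt_free,
            abs_diff_bound=row.rt_bound - ref.rt_bound if ok else None,
            abs_diff_free=row.rt_free - ref.rt_free if ok else None,
            rel_diff_free=(row.rt_free - ref.rt_free) / ref.rt_free if ok else None,
        ))
    return ComparisonReport(rows=tuple(rows),
                            fixture_conserves_retinol=fixture_self_test())


def scan_to_csv(rows: Sequence[PerturbationRow]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=[
        "level_percent", "p1_total", "rt_bound", "rt_free",
        "pct_change_free_vs_reference", "method", "status"])
    writer.writeheader()
    for row in rows:
        writer.writerow(row.to_dict())
    return buf.getvalue()


def scan_to_json(rows: Sequence[PerturbationRow], **kwargs) -> str:
    return json.dumps([row.to_dict() for row in rows], **kwargs)
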