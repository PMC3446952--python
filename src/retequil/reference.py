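"""Published reference values shipped as read-only fixtures.

These numbers come straight from the source study's printed tables.  They are
inputs to the analysis (and the yardstick the exact solver is compared
against), never outputs of it.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceScanRow:
    """One row of the published RBP4-perturbation table."""

    level_percent: float      # signed % change of total RBP4
    p1_total: float           # µmol/L
    rt_bound: float           # µmol/L, as printed
    rt_free: float            # µmol/L, as printed


#: the published perturbation table: RBP4 level vs bound/free retinol
REFERENCE_SCAN: tuple[ReferenceScanRow, ...] = (
    ReferenceScanRow(+50.0, 4.85, 1.50, 0.23),
    ReferenceScanRow(+40.0, 4.52, 1.43, 0.30),
    ReferenceScanRow(+30.0, 4.20, 1.37, 0.36),
    ReferenceScanRow(0.0, 3.23, 1.17, 0.56),
    ReferenceScanRow(-30.0, 2.26, 0.95, 0.78),
    ReferenceScanRow(-40.0, 1.94, 0.85, 0.88),
    ReferenceScanRow(-50.0, 1.62, 0.75, 0.98),
)

#: total retinol the reference table conserves (µmol/L)
REFERENCE_RT_TOTAL = 1.73

#: published assay means (control, treated) per analyte
ASSAY_MEANS: dict[str, tuple[float, float]] = {
    "hdac": (2.2, 1.0),                 # nmol/mg protein
    "sod": (0.57, 0.45),                # U/mg protein
    "hydrogen_peroxide": (6.0, 7.7),    # nmol/mg protein
}

#: published proteomic fold changes (treated/control, sign-magnitude) by spot
PROTEIN_FOLD_CHANGES: dict[int, float] = {
    24: -1.32,    # retinol-binding protein 4
    33: -1.16,    # protein SET
    48: -1.18,    # apolipoprotein A-1
    51: -1.14,    # carbonic anhydrase 2
    58: -1.17,    # NADH-cytochrome b5 reductase
    141: -1.10,   # ovotransferrin
    146: -1.27,   # unidentified
    233: -1.12,   # ovotransferrin
    258: -1.27,   # ovotransferrin
    275: +1.11,   # 60S ribosomal protein L22
}

#: spot number of RBP4 in the proteomic table
RBP4_SPOT = 24


def reference_row(level_percent: float) -> ReferenceScanRow:
    """Fetch the reference row at a given perturbation level."""
    for row in REFERENCE_SCAN:
        if row.level_percent == level_percent:
            return row
    raise KeyError(f"no reference row at level {level_percent:+}%")
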