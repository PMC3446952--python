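# retequil

Mass-action equilibrium analysis of the retinol / RBP4 / transthyretin /
CRABP carrier-protein system: how a change in the level of the carrier
protein RBP4 propagates to the unbound ("free") retinol pool.

The package provides:

- **Parameter registry** (`retequil.parameters`) — the published totals and
  dissociation constants (µmol/L) with their standard deviations, alternate
  literature values selectable by name, and strict JSON/YAML config loading
  (unknown keys are hard errors).
- **Binding networks** (`retequil.network`) — acyclic cascades of 1:1
  association reactions (retinol+RBP4, holoRBP+TTR, apoRBP+TTR, optionally
  RA+CRABP1/2).
- **Stepwise approximation chain** (`retequil.chain`) — a faithful
  reimplementation of the published back-of-envelope calculation (residual
  TTR 4.835, free TTR 1.605, free RBP4 0.664, inferred Kd 0.664 µmol/L),
  with every approximation recorded and a typed breakdown error where the
  approximation fails (≈ +50% RBP4).
- **Exact solver** (`retequil.equilibrium`) — damped Newton on log free
  concentrations with an independent Gauss–Seidel bisection oracle and the
  closed-form binary special case; conservation residuals below 1e-10.
- **Perturbation scans** (`retequil.perturbation`) — RBP4-level scans by the
  exact solver and by the chain, percent-change and fold-change metrics, and
  a discrepancy report against the published reference table (shipped as a
  read-only fixture in `retequil.reference`; its bound/free columns are not
  regenerable from a single mass-action relation, so they are compared
  against, never asserted).
- **RA partitioning and Michaelis–Menten comparison** (`retequil.rapartition`),
  **closed-form radical kinetics** (`retequil.radicals`).
- **Synthetic data / Monte Carlo** (`retequil.synth`) — truncated-normal
  parameter draws, uncertainty propagation to the free-retinol change,
  seeded synthetic titrations and Kd recovery by least squares.

## CLI

Every stage is independently invocable; numeric output goes to stdout
(`--format csv|json`), logs to stderr (`-v`/`-vv`):

```sh
retequil params                          # effective parameter registry
retequil chain                           # stepwise approximation chain
retequil solve [--oracle] [--include-ra] # exact equilibrium speciation
retequil scan --levels 50,0,-30 --method both --compare-table
retequil partition --ra-total 0.1 --p3-total 1 --p4-total 1
retequil radical --c0 2e-4 --kcat-over-km 7e9 --enzyme-conc 1e-9
retequil mc --n 2000 --seed 1 --scenario -32
retequil fit --noise-sd 0.02 --seed 1    # synthetic titration + Kd recovery
retequil report --config cfg.json --out report.json
```

Parameter configs are flat JSON/YAML maps (e.g. `{"p1_total": 2.26}`;
`"alt"` selects the alternate published value for `kd1`/`kd3`). The `report`
command accepts a broader config with `parameters`, `levels`,
`scenario_percent` and `mc` sections.

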