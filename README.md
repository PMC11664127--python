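# bcehi

Ecosystem health scoring for blue carbon ecotones (mangrove, salt marsh,
seagrass) on a 1°×1° coastal pixel grid.

Each pixel×ecotone record is scored as

```
EHI = B × [1 − (P × T)]
```

- **B (benefit)** — mean of min-max-normalized fitness indicators (area,
  fragment area, age, height, aboveground biomass, soil organic carbon for
  mangrove; area alone for salt marsh and seagrass).
- **P (pressure)** — mean of four compound pressure scores (climate, land,
  marine, species threat) built from raw pressure layers; salt marsh
  excludes the species compound.
- **T (transformation risk)** — collapsed from pairwise Sørensen overlaps of
  per-ecotone 5-D climatic kernel-density hypervolumes (PAR, tidal
  amplitude, SST, air temperature, precipitation; log10 scale, Silverman
  bandwidths), computed per continent with a worldwide fallback.

Downstream: exact Fisher–Jenks 3-class classification (High/Medium/Low +
NoData bookkeeping), first-order Sobol sensitivity analysis with bootstrap
SEs, 1°-binned latitudinal trend regressions, record-level covariate
regressions, and a profile-REML random-intercept mixed model.

Because no public per-pixel dataset exists for this analysis, the package
ships a first-class synthetic-world generator (`bcehi.synthetic_world`)
with ecotone latitude bands, latitudinal climate/fitness gradients and
configurable missingness, so every stage is testable offline.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: method-level
oracles (closed-form Sobol indices, dense-grid hypervolume integration,
exhaustive Jenks search, parameter-recovery simulations, end-to-end
byte-level determinism) at fixed tolerances.

## CLI

```bash
bcehi simulate --n 1000 --seed 1 --out out/          # synthetic pixel table
bcehi run-all --seed 1 --out out/                    # full pipeline
bcehi run-all --config config.yaml --out out/        # YAML-configured run
bcehi score|hypervolume|ehi|classify|gsa|trends ...  # run up to a stage
bcehi validate out/pixel_table.csv                   # schema check
```

A full run writes `pixel_table.csv` (when synthesized), `ehi_table.csv`,
`overlap_matrices.csv`, `class_breaks.csv`, `class_summary.csv`,
`sobol.csv`, `trends.csv`, `provenance.json` and the echoed `config.yaml`.
Reruns with the same configuration are byte-identical.

## Layout

```
src/bcehi/
  synthetic_world.py   # pixel-table generator (bands, gradients, missingness)
  indicators.py        # normalization, benefit and pressure scores
  hypervolume.py       # KDE hypervolumes, Sørensen overlaps, region matrices
  ehi.py               # transformation risk, EHI, Jenks breaks, classes
  stats.py             # Sobol indices, trend OLS, random-intercept REML
  io.py                # CSV/GeoJSON/YAML IO, RunConfig, run_pipeline
  cli.py               # click subcommand CLI (`bcehi`)
```
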