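# hrmsquant

Targeted LC-HRMS quantification, method validation, and MRL compliance
screening for veterinary drug residues (sulfonamides and trimethoprim in
fish tissue), together with a synthetic measurement generator that stands
in for raw instrument data.

The package covers the computational side of a matrix-matched residue
assay:

* **`chem_mass`** — Hill-formula parsing, monoisotopic masses from a
  curated atomic-mass table, adduct m/z ([M+H]+ by default), ppm
  mass-error arithmetic.
* **`identification`** — accurate-mass + retention-time matching of peaks
  against an analyte target list and identification-point (IP) scoring
  (2.0 per HR precursor, 2.5 per HR fragment) with per-group confirmation
  thresholds.
* **`calibration`** — unweighted least-squares calibration in three
  preparation modes (solvent / fortified extract / matrix matched) with an
  R² ≥ 0.99 linearity gate, back-calculation with dilution and
  tissue factors, S/N estimation on chromatograms, and LOD (S/N ≥ 3) /
  LOQ (replicate CV ≤ 20%) assignment.
* **`validation`** — matrix effect, recovery, intraday/interday precision
  (CV%), decision limit CCα = MRL + 1.64·SD(20 blanks fortified at the
  MRL) and detection capability CCβ = CCα + 1.64·SD(20 blanks fortified
  at CCα).
* **`compliance`** — per-analyte MRL screening (nonconforming requires a
  confirmed identity *and* concentration ≥ CCα) and the summed-sulfonamide
  group rule (100 ng/g), plus LOQ policy checks.
* **`simulate`** — deterministic synthetic peak tables, Gaussian
  chromatograms, and full validation-campaign bundles with multiplicative
  lognormal noise, per-analyte recovery and matrix-effect factors.
* **`io` / `workflow` / `cli`** — delimited-text ingestion/serialization,
  end-to-end campaign analysis, and the command-line surface.

A default 8-analyte target list (name, formula, retention time, fragment
m/z, regulatory group, MRL) ships with the package and is used when no
`--targets` file is given.

## Command-line usage

```bash
# synthetic peak table + ground truth
hrmsquant simulate --seed 1 --concs 10,50,100 --out out/sim

# full simulated validation campaign -> report tables
# (nonzero exit when an acceptance gate fails; the gate is named)
hrmsquant validate --seed 1 --noise-cv 0.05 --out out/val

# quantify a peak table against stored curves
hrmsquant quantify --peaks out/sim/peaks.csv --curves out/val/curves.csv \
    --out out/quant.csv

# MRL compliance decisions per sample
hrmsquant screen --peaks out/sim/peaks.csv --curves out/val/curves.csv \
    --records out/val/records.json --out out/decisions.csv

# re-render report tables from stored validation records
hrmsquant report --records out/val/records.json --out out/reports
```

`validate` writes `records.json` (machine-readable validation records),
`curves.csv`, and three report tables: `method_parameters.csv` (working
range, linearity, sensitivity, matrix effect, recovery, LOD/LOQ),
`precision.csv` (intraday/interday CV grids) and `decision_limits.csv`
(CCα/CCβ). All outputs are byte-reproducible for a fixed seed.

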