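# fluorospec

Label-free tissue fluorescence spectroscopy toolkit: emission-scan I/O,
fluorophore peak-ratio analysis, derivative spectroscopy, group statistics,
and a FRET-based forward simulator of AD-like vs normal-like tissue scans.

The package analyzes emission scans taken at 266/300/340 nm excitation,
where the dominant intrinsic fluorophores are tryptophan (~331-335 nm
emission), NADH (~435-492 nm, center depends on excitation), and FAD
(~557 nm). The analysis chain is:

1. group replicate scans per (condition, excitation),
2. average with per-wavelength SD and normalize both conditions to the
   maximum of the AD averaged spectrum,
3. extract fluorophore peaks in per-excitation windows,
4. compute tryptophan/NADH (or NADH/FAD) peak ratios, AD/N fold changes,
   first-derivative profiles with their ascending/descending extrema, and a
   Welch two-sample comparison.

Because no raw scans are publicly deposited, the package ships (a) the
published replicate peak table as a packaged JSON fixture, reproduced
exactly by the pipeline, and (b) a forward simulator (`synthetic_data`)
whose calibrated presets generate replicate scans with the same statistical
structure (band positions, ~1.6-2x AD brightness folds, FRET coupling of
the tryptophan→NADH pair, few-percent replicate variability), so the entire
pipeline is testable offline.

## CLI

```bash
# generate calibrated synthetic scans (CSV + YAML manifest)
fluorospec simulate --seed 42 --out scratch/run

# run the full analysis on a manifest
fluorospec analyze --manifest scratch/run/manifest.yaml --out scratch/out
# -> scratch/out/summary.json (ratios, folds, derivative extrema, Welch p)
#    scratch/out/peaks.csv    (per-replicate peak table)

# recompute the published replicate-table statistics; exit 1 on mismatch
fluorospec reproduce-table1 [--json]
```

All commands are deterministic given `--seed`; outputs embed the tool
version and a configuration hash. Exit codes: 0 ok, 1 regression mismatch,
2 usage/input error.

Scan files are two-column CSV (`wavelength_nm,intensity`) with optional
`#` comments; metadata is embedded as `# key: value` comments. Manifests
are YAML mapping `condition -> excitation -> [scan files]`. Emission points
at or below excitation + bandpass are excluded at read time.

## Known quirks of the published table

Two printed cells are internally inconsistent with their own replicate
rows: the N-group mean ratio at 340 nm prints 2.928 where the ratio column
averages to 2.926, and the AD mean peak-2 intensity at 340 nm prints 0.352
where the column averages to 0.3514. The fixture keeps the printed values
verbatim; the regression check reports both cells as known discrepancies
without failing. The printed per-replicate ratio column was computed from
unrounded raw intensities, so it cannot be reproduced exactly from the
3-decimal printed intensities (e.g. 0.522/0.174 = 3.00 vs printed 3.01);
per-replicate ratio cells are therefore not part of the exact regression.

Fold-change modes: `unrounded` (divide raw replicate means; reproduces the
published 2.01, 1.58, 1.88, 1.65, 1.70) and `printed` (divide 3-decimal
printed means; required for the published 1.61 NADH fold at 300 nm).
Rounding is half-away-from-zero throughout.
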