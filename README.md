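# spermraman

Tools for discriminating X- from Y-chromosome-bearing human sperm by DNA
content in single-cell confocal Raman spectra.

An X-bearing sperm carries the ~156 Mb X chromosome, a Y-bearing sperm
the ~57 Mb Y, on a ~2,875 Mb haploid autosome background — about 3% more
DNA in the X sperm. That difference is, in principle, readable from the
nucleic-acid backbone bands of a sperm-head Raman spectrum: the
785 cm⁻¹ O–P–O stretch (**I785**) and the 714.30–1161.86 cm⁻¹ DNA–PO₄
skeleton band area (**Area₇₁₄₋₁₁₆₂**). In practice the between-cell
variability of single-cell Raman intensities is an order of magnitude
larger than the genomic effect, so the question is statistical: given a
cohort of labeled cells, how well do these two scores separate the
classes, and where should a classification cutoff sit?

The package implements the full analysis chain and a calibrated
synthetic-cohort generator so that every stage is testable without
access to instrument data (none is publicly deposited for this problem):

* `spectra_io` — spectrum/label data model; plain-CSV readers/writers
  (two-column per scan, or one long-format table).
* `synthetic_data` — sperm-head scan simulator: Gaussian/Lorentzian
  band table with DNA-linked bands at 728/785/1050/1095/1250/1578 cm⁻¹,
  glass/fluorescence baseline, per-scan detector noise, 15-scan
  accumulation, and a per-cell log-normal DNA-content factor whose
  defaults are calibrated to published cohort summaries (median I785
  ratio 27,242/22,321; I785 AUC 0.662).
* `preprocess` — resample → Savitzky–Golay (11/5) → baseline (ALS or
  iterative polynomial) → denoise (SG 7/3) → average scans → crop to
  650–1800 cm⁻¹.
* `features` — I785 (windowed apex, ±8 cm⁻¹) and the band area
  (trapezoid with exact-edge interpolation).
* `stats_classify` — PCA with Hotelling-T² outlier screening and
  deterministic 2-means grouping; Shapiro–Wilk; exact/corrected
  Mann–Whitney U; ROC with AUC and Youden-index cutoff; frequency
  histograms with a CDF-gap breakpoint.
* `pipeline` / `cli` — end-to-end orchestration with full config echo
  and a `spermraman` command-line entry point.

## Worked example

Simulate the calibrated default cohort at the modeled study's sizes
(39 X, 20 Y; 15 scans per cell over 60–3,400 cm⁻¹) and run everything:

```python
from spermraman import default_run_config, run_pipeline, render_report

report = run_pipeline(default_run_config(seed=1))
render_report(report, "report.json")   # also writes report.txt
```

`report.txt` from this exact call:

```
spermraman 0.1.0 run report
cells: 59 (X: 39, Y: 20)
[I785] median X/Y: 25840.2 / 20507.6
[I785] Mann-Whitney U = 544.0, p = 0.01397 (normal_approx)
[I785] AUC = 0.697, Youden cutoff = 24737.5 (sens 0.56, spec 0.85)
[I785] histogram breakpoint = 25000.0
[area_714_1162] median X/Y: 2604922.6 / 2188270.8
[area_714_1162] Mann-Whitney U = 544.0, p = 0.01397 (normal_approx)
[area_714_1162] AUC = 0.697, Youden cutoff = 2522958.2 (sens 0.56, spec 0.85)
[area_714_1162] histogram breakpoint = 2250000.0
PCA: 2 components, groups A/B = 19/39, excluded 1 cells
```

Reading it: X cells score higher on both DNA-content features (median
I785 25,840 vs 20,508 a.u.); the two-sided Mann–Whitney test rejects
equal distributions at p ≈ 0.014; the ROC area of ≈ 0.70 says a randomly
chosen X cell outscores a randomly chosen Y cell 70% of the time — a
real but far-from-clean separation, as expected when a 22% median shift
meets ~35% between-cell variability; and the Youden-optimal cutoff
(call "X" above ≈ 24,700 a.u.) trades 56% sensitivity against 85%
specificity. One cell failed the Hotelling-T² screen, and the
unsupervised PCA grouping (19/39 after exclusion) does not coincide
with the true 39/20 labels — unsupervised grouping of these spectra is
dominated by overall intensity variability, not chromosome content.

The same run from the shell:

```sh
spermraman run --seed 1 --out results/
spermraman simulate --out data/ --seed 1      # spectra.csv + labels.csv
spermraman preprocess --spectra data/spectra.csv --labels data/labels.csv --out processed.csv
spermraman features --spectra processed.csv --labels data/labels.csv --out features.csv
spermraman analyze --features features.csv --out analysis.json
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's reference analysis from scratch: it simulates
the calibrated 39 X / 20 Y cohort with the given seed, runs the full
preprocessing/feature/statistics pipeline, writes the measured target
values as JSON to `--out`, and prints a one-line summary of the I785
comparison.

## Scope

The package covers the computational pipeline only: semen processing,
FISH labeling chemistry, instrument control, and Raman chemical mapping
are out of scope, as is any claim about aneuploidy screening in assisted
reproduction. See `docs/methods.md` for the model, the calibration
derivation, numerical choices, and known limitations.
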