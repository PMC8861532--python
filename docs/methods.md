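# Methods

## Scientific setting

A haploid human sperm carries either the X chromosome (~156 Mb) or the Y
chromosome (~57 Mb) on top of ~2,875 Mb of autosomal DNA, so an X-bearing
sperm holds about

    100 * (156 - 57) / (2875 + 57)  ≈  3.4 %

more DNA than a Y-bearing one (`dna_content_difference`). Confocal Raman
microspectroscopy of the sperm head reads total DNA content through the
intensity of nucleic-acid backbone vibrations, principally the 785 cm⁻¹
O–P–O stretch and the broader DNA–PO₄ skeleton region at
714.30–1161.86 cm⁻¹. The package implements the full chain from raw
per-scan spectra to a classification cutoff, and a synthetic-cohort
generator that makes every stage testable without instrument data.

## Spectral model of the generator

A scan of one cell at one spot is

    I(ν) = b(ν) + Σ_k a_k · s · f_k(ν)  +  ε(ν)

* `b(ν)` — glass/fluorescence background, a low-order polynomial
  (default quadratic, ~3,500–8,000 counts over 60–3,400 cm⁻¹).
* `f_k` — Gaussian lineshapes by default (Lorentzian available); the
  default band table holds six DNA-linked bands (728, 785, 1050, 1095,
  1250, 1578 cm⁻¹) and seven label-independent protein/lipid bands
  (852, 938, 1003, 1125, 1450, 1660, 2930 cm⁻¹). No lineshape fits
  exist for the real spectra, so Gaussian is the neutral choice.
* `s` — the cell's DNA-content factor. It multiplies DNA-linked
  amplitudes only and only in nucleus profiles (`acrosome` and `glass`
  profiles exist for spot-position contrasts). Per cell,
  `s ~ LogNormal(median = dna_scale_label, cv = cell_cv)`.
* `ε` — i.i.d. Gaussian detector noise per channel per scan
  (default σ = 800 counts, i.e. ~SNR 28 at the 785 apex for a 0.5 s
  exposure class of instrument); 15 scans per cell are averaged
  downstream, as in the acquisition protocol the package mirrors.

Reproducibility: each cell draws from `default_rng([seed, cell_index])`,
so enlarging a cohort never reshuffles earlier cells.

### Calibration of the defaults

The defaults are fixed once, from two published summary numbers of the
59-cell study the package models (39 X, 20 Y):

* **Effect size.** `dna_scale_x / dna_scale_y` equals the published ratio
  of group medians of I785, 27,242 / 22,321 ≈ 1.2204. Because the factor
  is multiplicative and log-normal, group medians of I785 inherit this
  ratio exactly regardless of spread. The 785-band amplitude equals the
  published Y median, so absolute simulated medians also land near the
  printed values (before ALS attenuation, see below).
* **Spread.** For two equal-σ log-normal score distributions,
  `AUC = Φ(Δμ_log / (σ_log √2))`. Solving with the published I785 AUC of
  0.662 gives `σ_log = ln(1.2204) / (Φ⁻¹(0.662)·√2) ≈ 0.337`, i.e.
  `cell_cv = √(exp(σ²)−1) ≈ 0.347`. A between-cell CV of ~35% — an order
  of magnitude above the 3% genomic effect — encodes the focus, spot-
  placement and chromatin-packing variability that makes single-cell
  sexing hard, and is exactly why the published AUC is modest.

The generator parametrizes the log-normal by its **median**, not its
mean: the calibration anchors ratios of medians, which are identical
under either convention, and the median convention keeps the absolute
medians on the printed scale.

The published Area(714–1,162) medians imply an X/Y ratio of ~1.39,
larger than the I785 ratio of 1.22. A single multiplicative DNA factor
cannot produce two different ratios from the same cells, so the area
ratio is *not* a calibration target; simulated areas land at the printed
order of magnitude (~2–3·10⁶ a.u.·cm⁻¹) with ratio ≈ 1.17, the DNA-linked
fraction of the band. Likewise the published "17 and 19% higher" mean
differences are internally inconsistent with the printed means and are
not targeted.

### What a green test does not establish

The generator emulates the statistical geometry of the published cohort,
not sperm photophysics: no fluorescence bleaching, no cosmic-ray spikes,
no wavenumber miscalibration drift, no cell-shape or focal-plane
structure, and independent Gaussian channel noise rather than shot noise.
Green acceptance tests establish that the pipeline recovers the stated
effect from data *with the stated structure* — they say nothing about
performance on real instrument output.

## Preprocessing

Fixed stage order (changing it is a config violation, not silent):

    resample → SG smooth → baseline subtract → denoise → average → crop

* **Savitzky–Golay** smoothing, window 11 / degree 5. Edges use
  one-sided truncated-window polynomial fits (scipy `mode="interp"`) so
  no data are invented beyond the measured range.
* **Baseline.** Default is asymmetric least squares (ALS; Eilers–
  Boelens) with λ = 1e5, p = 0.01, 10 reweighting iterations, solved as
  a pentadiagonal banded system (a numba LDLᵀ fast path batched over
  scans; the scipy `solve_banded` implementation is the reference and
  the two are asserted equal in tests). An iterative polynomial fit
  (degree 5, 3σ peak rejection) is the alternative. ALS is mildly
  *contractive*: its baseline rises under any peak, removing ~5–10% of
  apex height, proportionally to amplitude. Absolute scores therefore
  sit a few percent below the noiseless truth while ratios between
  groups — everything the statistics consume — are preserved (verified
  deterministically: X/Y ratio 1.2211 after the full chain vs 1.2205
  configured).
* **Denoise.** A second, gentler SG pass (window 7 / degree 3), the
  analogue of a vendor "denoising option"; identity when disabled.
* **Averaging** of the 15 scans happens after per-scan processing by
  default (`average_first` flips the order; with identical scans the two
  agree to 1e-9, and the spec of the original workflow does not state
  the order).
* **Crop** to 650–1800 cm⁻¹, the fingerprint window used for PCA and all
  statistics.

Numerical choices: grids must match exactly within a scan set —
resampling (linear, never extrapolating, default 1 cm⁻¹) is always an
explicit step; negative post-baseline intensities are kept for
integration (clipping biases areas upward); band integrals interpolate
to the exact band edges so results do not depend on grid phase.

## Features

* `I785` — maximum baseline-corrected intensity within ±8 cm⁻¹ of
  785 cm⁻¹. A windowed maximum (rather than the single channel at 785)
  tolerates ~1-channel wavenumber miscalibration; the published analysis
  never states its extraction rule, so this is a package choice, and the
  window is configurable.
* `area_714_1162` — trapezoidal integral over 714.30–1161.86 cm⁻¹ of the
  baseline-corrected signal, no additional band-local baseline (the
  chain subtracts one global background, and a second local correction
  would double-count).

## Statistics

* **PCA** over 650–1800 cm⁻¹, channel-mean-centered, absolute
  intensities (vector normalization would erase the DNA-content signal,
  which lives in overall intensity). Retained components: smallest
  number explaining ≥ 90% variance, minimum 2. Deterministic sign:
  largest-|loading| channel positive.
* **Outlier screen.** Hotelling T² over retained scores against
  `k(n−1)(n+1)/(n(n−k)) · F₁₋α(k, n−k)`, α = 0.025, one refit. Two
  small-sample facts are documented rather than hidden: the expected
  false-flag count in clean data is ~αn (the limit is a per-cell
  quantile), and a single outlier's T² cannot exceed (n−1)²/n, so the
  screen has no power below n ≈ 15.
* **Unsupervised grouping.** 2-means on retained scores, initialized at
  the two cells at maximal score distance (fully deterministic); group
  "A" is the cluster with higher mean I785.
* **Group comparison.** Shapiro–Wilk per group decides the path
  (any p < 0.05 → nonparametric; the modeled data are log-normal, so
  this is the expected branch). Mann–Whitney U with
  `U = #{x > y} + ½#{x = y}`: exact two-sided p by full enumeration when
  n_x + n_y ≤ 14 without ties, else normal approximation with tie and
  continuity corrections. Two-sided throughout; the two features are
  reported unadjusted for multiplicity, matching the workflow modeled.
* **ROC.** Thresholds are midpoints between consecutive unique scores
  plus ±∞ sentinels; positive call is `score ≥ threshold` with X
  positive (X carries more DNA). AUC by trapezoid — equal to
  `U/(n_x·n_y)` under the half-tie convention, an identity the tests
  check to 1e-12. The operating cutoff maximizes Youden's J = TPR − FPR,
  ties resolved toward the lower threshold (favoring sensitivity).
* **Frequency histogram.** Bins anchored at 0 (defaults 2,500 a.u. for
  I785; 250,000 for the area), and a breakpoint at the bin edge
  maximizing the empirical CDF gap |F̂_X − F̂_Y| — the reproducible
  version of reading a "frequency difference trend" off a histogram.

## Known limitations

* ALS attenuation makes absolute feature values (not ratios, ranks, or
  AUCs) depend on peak width and λ; cross-study absolute comparisons
  would need an intensity standard.
* The unsupervised PCA/2-means grouping is reported with its agreement
  to the labels, but nothing forces it to align with X/Y — in the
  modeled study it did not (22/31 grouping vs 39/20 truth), and the
  package makes no attempt to reproduce that particular disagreement.
* Exact Mann–Whitney enumeration is capped at n_x + n_y ≤ 14
  (C(14,7) = 3,432 assignments); beyond that the corrected normal
  approximation is used, which the tests validate against a permutation
  oracle at n = 50/50.
* The preprocessing chain is deterministic; all stochasticity enters
  through the generator seed.
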