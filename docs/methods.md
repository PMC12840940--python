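# Methods

This note documents the models behind `plumfusion`, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## The calibration problem

Soluble solid content (SSC, °Brix) of intact fruit is predicted from two
simultaneously acquired modalities: a Vis/NIR reflectance spectrum
(400–1100 nm) and an RGB image. The spectral modality responds to the
sugar-related absorption features of the flesh; the visual modality sees
skin colour and texture, which correlate with ripeness and hence weakly
with SSC. The fusion model exists because the two error sources are
largely independent: spectral error is dominated by the mismatch between
the optically probed flesh and the destructively measured reference, while
visual error is dominated by colour variation unrelated to sugar.

## Modelling pipeline

### Reflectance calibration

`R(λ) = (S − D)/(W − D)` per sample and wavelength, with dark current `D`
and white-board reference `W` on the same grid. `W > D` everywhere is a
precondition; violations raise an error naming the first offending
wavelength rather than producing silent infinities.

### Preprocessing

* **SG** — Savitzky–Golay smoothing, default window 11 points / order 2, a
  conventional Vis/NIR choice; both are exposed in configuration. Edges
  are handled by evaluating the boundary window's polynomial at the edge
  positions (`scipy.signal.savgol_filter(mode="interp")`), so the output
  grid equals the input grid and selection indices stay aligned.
* **SNV** — per-spectrum `(x − mean)/sd` with the *sample* (n−1) SD. The
  `[1, 2, 3] → [−1, 0, 1]` contract depends on that denominator choice,
  so it is stated explicitly. Zero-variance spectra raise an error naming
  the row — degenerate inputs should be visible, not silently zeroed.
* **MSC** — per-spectrum least-squares fit `x = a + b·ref` followed by
  `(x − a)/b`. With `reference="mean"` the reference is the mean spectrum
  of the fitted (training) set, frozen at fit time and replayed on test
  data, so the correction never sees test rows.
* Chains (`"SG+SNV"`, `"SG+MSC"`) apply left to right inside an sklearn
  `Pipeline`; stateful steps follow the same train-only fitting rule.

Both SNV and MSC cancel per-sample affine intensity distortions
`x → αx + β` (α > 0); that scatter-correction contract is property-tested.
Modelling is done on reflectance; absorbance `log(1/R)` is not applied by
default and no claim is made about which the original instrument used.

### Wavelength selection

All three selectors are fitted on the training partition only and are
deterministic given (X, y, config, seed).

* **CARS** (default): 50 Monte-Carlo runs, 80% calibration subsets.
  Each run fits a PLSR on the retained variables, weights variables by
  normalized |regression coefficient|, keeps the top `⌈r_i·p⌉` under the
  enforced exponential schedule `r_i = a·e^(−k·i)` pinned by `r_1 = 1` and
  `r_N = 2/p`, then resamples `⌈r_i·p⌉` draws with replacement in
  proportion to weight (de-duplicated). Runs are scored by 5-fold RMSECV
  **at a fixed small latent-variable count** (default 5, shared with the
  weighting fits). Scoring each candidate subset at its own
  cross-validated best count was tried and rejected: the argmin over 50
  adaptively constructed subsets then chases fold noise, and the winning
  subset generalizes measurably worse. Ties prefer fewer variables, then
  the earlier run.
* **SPA**: from every candidate start column, a chain is grown by
  repeatedly appending the column with the largest projection norm onto
  the orthogonal complement of the chain's span (chain construction is
  y-blind, as in the classical algorithm); every (start, length) chain
  within [min_vars, max_vars] is scored by held-out least-squares RMSE on
  a seeded 80/20 split. Ties prefer shorter chains, then lower start.
* **UVE**: p artificial noise columns (uniform, scaled by 1e−10 so they
  never perturb the fit) are appended; per-variable PLS coefficients are
  collected over leave-one-out folds; the stability score is
  `c_j = mean(b_j)/sd(b_j)`; real variables are kept when `|c_j|` exceeds
  the 99th percentile of |c| among the noise columns. The percentile (not
  the max) is used for robustness to a single extreme noise reliability.
  A zero coefficient spread sets `c_j = 0` with a warning.

### Visual features

The frozen 16-vector: mean and population SD of R, G, B and of CIELAB
L\*, a\*, b\* (sRGB, D65/2°; pixels are the full population of the imaged
region, hence ddof = 0), then four GLCM properties — contrast,
dissimilarity, energy and homogeneity — on BT.601 luminance quantized to
32 gray levels, one-pixel offset, angles 0°/45°/90°/135°, symmetric and
normalized matrices, each property averaged over the four angles. Energy
is the angular second moment Σ P² itself (some libraries report its
square root). 32 levels stabilize the co-occurrence matrix for small
fruit regions. An optional Otsu-style fruit mask is supported for the
colour statistics (GLCM then uses the mask's bounding box) but masking is
off by default. Source descriptions of this feature block disagree on its
dimension (15 vs 16); this implementation uses the fully enumerated
16 = 12 + 4 version.

### Fusion and regression

Each block is Z-scored with training statistics (sample SD). Two weighting
modes exist:

* **per_block** (default): a PLSR is fitted inside each block, its
  *out-of-fold* predictions (seeded 5-fold) are collected, and an OLS of y
  on the two prediction vectors yields two scalars broadcast across their
  blocks. Out-of-fold predictions matter: with in-sample predictions the
  OLS collapses onto whichever block has more capacity to overfit (the
  wide spectral block), giving the visual block a near-zero weight and the
  fusion no effect.
* **per_feature**: absolute per-feature coefficients of a single OLS of y
  on `[Z_spec | Z_vis]`. This is the most literal reading of "concatenate
  and learn weights by OLS", and it is kept and tested, but it is fragile
  in the realistic regime where the spectral block is wide and collinear:
  the OLS is rank-deficient or high-variance, the downstream
  cross-validation then admits many latent variables, and the fused model
  overfits. That observed failure is why per_block is the default.

Absolute values are used as weights because a signed weight only flips a
standardized feature's sign, which the downstream PLSR absorbs.

The fused matrix (spectral block first) is regressed on SSC by a
single-response, deflation-based PLSR on centered, unscaled data
(`sklearn` `PLSRegression(scale=False)`). The latent-variable count is the
argmin of the 5-fold cross-validated RMSE (shuffled folds, seed 42, upper
bound 25; ties resolve to the smallest count). The spectral-only model is
a PLSR on the selected, preprocessed (not Z-scored) wavelengths; the
vision-only model is a PLSR on the Z-scored 16-vector.

### Evaluation

`R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²`, `RMSE = √mean((y−ŷ)²)`, and on the test
partition `RPD = SD(y_test; n−1)/RMSEV` — the dominant chemometrics
convention for RPD. Zero variance in the reference values is an error;
zero RMSE reports RPD as +inf.

### No-leakage contract

The split is performed once and shared by all three models. The MSC
reference, the preprocessing chain state, wavelength selection, the
Z-score parameters, the fusion weights and the latent-count selection are
all functions of the training partition only. Fitting twice — with the
held-out data replaced by arbitrary other data — yields bit-identical
models; the test suite asserts this.

## The synthetic data generator

The generator defines the study conditions; all randomness flows from one
integer seed through named substreams (`ssc`, `spectra`, `images`) so each
block can be regenerated independently.

**SSC cohort.** n = 120 values from N(13.00, 1.25²) °Brix truncated by
rejection (not clipping, which would distort both moments) to
[10.2, 15.3] °Brix — the fitted distribution of a model-building plum
cohort. Note the truncation makes the population SD of the generated
cohort ≈ 1.10 °Brix, below the nominal 1.25; that is a property of the
stated distribution, not of the sampler.

**Spectra.** Reflectance shape = smooth cubic baseline + two Gaussian
peaks (720 and 820 nm, FWHM ≈ 40 nm) − a narrow valley (740 nm, sd 5 nm),
on a 1 nm grid over 400–1100 nm (the instrument's pixel grid is unknown;
1 nm is a neutral choice). The baseline cubic has zero slope at exactly
720 and 820 nm so the band maxima stay on their grid points for any
amplitude. Band amplitudes are affine in the *optically probed* sugar
content `ssc + δ`, with four nuisance components chosen to mirror the
failure modes of real acquisitions:

| component | default | emulates |
|---|---|---|
| `ssc_nuisance_sd` (δ) | 0.45 °Brix | refractometer-vs-flesh mismatch; bounds spectral R²v at ≈ 0.85 |
| `band_noise_sd` | 0.003 refl. | band-specific biological variation |
| `baseline_drift_sd` | 0.02 refl. | per-fruit smooth baseline tilt/curvature (size, skin, path length) |
| `scatter_multiplier_sd`, `additive_offset_sd` | 0.08, 5 counts | multiplicative/additive scatter — what SNV/MSC exist to remove |
| `noise_sd` | 1 count | white detector noise after scan averaging |

The structure of the nuisances matters more than their size. Two earlier
variants failed to reproduce known qualitative behaviour of wavelength
selection and were replaced: (i) a large *independent* per-band jitter
couples into every SNV row-SD and smears SSC information across all 701
channels, making any sparse wavelength subset genuinely worse than the
full spectrum — which real CARS calibrations are not; (ii) without
baseline drift, off-band channels carry no real variation, so their
variance is pure detector noise and a coefficient-driven selector can
cherry-pick channels whose noise aligns with the training response. With
the defaults above, a PLSR on CARS-selected wavelengths performs within a
few percent of the full-spectrum model, as it should.

Acquisition parameters act purely as scalar knobs: counts scale linearly
with integration time and inversely with spot diameter (so longer
integration raises overall intensity and a smaller spot concentrates it);
white-noise SD grows with motor speed; posture selects a gain (A 1.00,
B 0.98, C 0.85 — stem-end illumination loses signal). No physical optics
is simulated, and the absolute intensity scale (1000 counts) is arbitrary
by necessity.

**Images.** An elliptical fruit on a near-black background; skin colour is
affine in SSC (default slopes 6/3/1 8-bit counts per °Brix in R/G/B) plus
a per-fruit colour jitter, a low-frequency texture field, and per-pixel
noise, all driven by one `noise_sd` knob (jitter 1×, texture 0.8×, pixel
0.6×). The jitter-to-signal ratio (default `noise_sd` 7.0) was calibrated
once so that a vision-only model reaches held-out R² ≈ 0.3–0.4 — the
regime in which skin colour is a real but weak SSC proxy — and is a
config value, not a hard-coded constant.

**What passing tests show — and don't.** The synthetic benchmark
demonstrates internal correctness (oracles, invariances, no leakage) and
the qualitative phenomenology: fused ≥ spectral-only ≥ vision-only
held-out R² (median over seeds), selection not harming the spectral
model, R² → 1 as generator noise → 0. It does not demonstrate performance
on real fruit: real spectra have richer chemistry (water, chlorophyll,
temperature effects), nonlinear scatter, and instrument drift; real
images have specular highlights, pose variation and defects. Absolute R²
values on the synthetic data are properties of the chosen noise levels.

## Numerical choices and degenerate inputs

* PLSR operates on centered, variance-unscaled X; fusion inputs are
  already Z-scored, so scaling only affects the spectral-only model,
  whose SNV/MSC preprocessing has normalized scale anyway.
* MSC slopes below 1e−12, zero-variance SNV rows, zero-variance Z-score
  columns and zero-variance responses are errors naming the offending row
  or column.
* Rank-deficient fusion OLS falls back to minimum-norm least squares with
  a warning rather than failing.
* The enforced-reduction schedule guards its boundary values against
  floating-point round-up (`ceil(2 + ε)` must be 2, not 3).
* Ties: CARS → fewer variables then earlier run; SPA → shorter chain then
  lower start; latent-count CV → smallest count.

## Problem sizes

The default experiment is the full study size: 120 fruits, 701
wavelengths, 96×96 images, 50 CARS runs, 5-fold CV up to 25 latent
variables (one run ≈ 2 s). Property suites use reduced sizes (e.g. 8×8
images for the brute-force GLCM oracle, 60×20 matrices for the UVE null
simulation, 20 seeds for median-based claims) chosen so each suite stays
well under a minute.

## Known limitations

* CARS at n ≈ 84 training samples remains a high-variance procedure; its
  selected count fluctuates widely across seeds (tens to low hundreds),
  consistent with its Monte-Carlo character.
* The per_feature fusion mode is faithful to its definition but not
  robust when `n_selected + 16` approaches the training-set size; it
  warns and proceeds via minimum-norm OLS.
* UVE's leave-one-out protocol is O(n) PLS fits per call; it is tractable
  at n = 120 but the dominant cost if used inside the pipeline.
* The generator couples all three band amplitudes to a single latent
  sugar variable; it cannot emulate calibrations where distinct chemical
  constituents compete for the same bands.
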