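# Methods

This note documents the models and procedures implemented in
`herbspec`, the assumptions behind the synthetic study, the defaults
that matter, and what the passing test suite does and does not
demonstrate about real hyperspectral data.

## Spectral axis

The emulated camera records 256 bands on a uniform grid anchored at
band 30 = 975.0 nm with a 3.3719 nm pitch, spanning ≈874–1734 nm. The
pitch is quoted to four decimals, so accumulated rounding can move edge
bands by up to ~0.01 nm over the grid; band-in-window membership is
therefore decided with a 0.02 nm absolute tolerance (far below the band
pitch), which keeps the 975–1646 nm analysis window at exactly 200
bands. Head and tail bands outside that window are discarded as noisy.

## Synthetic study

**Design.** Eleven sulfur-fumigation doses (0–100 g/kg in steps of 10)
with 15 replicate bulbs each: 165 samples.

**Dose–response.** Each analyte's mean content follows a two-plateau
piecewise-linear curve: constant at `c_lo` up to 50 g/kg, linear decay
to `c_hi` at 70 g/kg, constant beyond. Defaults (in % w/w): peimine
0.18 → 0.09, peiminine 0.095 → 0.048. Per-bulb truth is the curve value
times `1 + ε`, `ε ~ N(0, 0.10)` (between-sample CV 10%), floored at 10%
of the curve value so contents stay positive. These defaults were
chosen so the 165-sample population min/max track the reference content
ranges (peimine 0.0729–0.2261, peiminine 0.0382–0.1203 % w/w); the
underlying per-dose means and SDs are parameterisations, not measured
values.

**Optics.** Reflectance is Beer–Lambert:
`R(px, λ) = B(λ)·10^(−Σₖ cₖ(px)·εₖ(λ))`, with

* `B(λ)` — a fixed smooth baseline inside [0.3, 0.9] (sine plus tilt),
  representing the instrument/matrix background;
* `εₖ(λ)` — a fixed absorptivity signature per analyte, the sum of
  three Gaussian bands. Centers sit at wavelengths that the successive
  projections algorithm singles out for each analyte on real bulbs
  (peimine 1416/1517/1558 nm, peiminine 1305/1348/1379 nm). The quoted
  band widths (20–40 nm) are full-widths-at-half-maximum — the standard
  meaning of "width" for a spectral band — giving Gaussian σ of roughly
  9–15 nm. Amplitudes (per % w/w) are set so the strongest band sits
  near 0.4 absorbance at typical contents, the regime in which
  reflectance is most sensitive to content;
* `cₖ(px)` — the bulb's true content modulated by a smooth spatial
  field (Gaussian-filtered noise, σ = 3 px) with a 5% within-bulb CV,
  floored at 10% of the bulb content.

Background pixels have flat reflectance 0.02. Raw digital numbers are
`dark + R·(white − dark) + N(0, noise_sd)` with white ≈ 3500 DN, dark ≈
120 DN (each with ±2–5% smooth spatial non-uniformity, constant across
bands) and `noise_sd` defaulting to 0.5% of the white−dark span. By
construction the standard reflectance calibration inverts the renderer
exactly at zero noise, and to within the sensor noise otherwise.

**Geometry.** Bulbs are non-overlapping axis-aligned ellipses on a grid
(default scenes 96×128 px, 15 bulbs, ≈330 px per bulb). Overlap or
out-of-frame ellipses are rejected, as are signature centers outside
the spectral axis.

**Determinism.** Every generator is a pure function of its inputs and a
seed; identical seeds give bitwise-identical tables and cubes.

**What the phantom does not emulate.** Real bulb spectra carry
multiplicative scatter differences between samples, baseline drift,
geometric shading, specular highlights, dead pixels and wavelength-
correlated noise; the phantom has none of these, and its two analytes
are the only spectrally active constituents. Consequences for
interpreting results are discussed under "Selector behaviour" below.

## Preprocessing

* Calibration: `(raw − dark)/(white − dark)`, element-wise, no
  clipping; any band with `white ≤ dark` raises an error naming the
  band.
* Segmentation: Otsu threshold on the single band nearest 1200 nm,
  hole filling, removal of components below 50 px, relabelling 1..K in
  row-major first-pixel order. The threshold value itself is
  data-driven (Otsu), not a fixed constant.
* Smoothing: per-pixel Daubechies-8 wavelet decomposition at level 3
  with symmetric boundary extension; detail coefficients are
  soft-thresholded, the approximation is untouched. The default
  threshold is universal, `σ̂·√(2·ln n)` per spectrum with `σ̂` the
  median absolute deviation of the finest detail level divided by
  0.6745; a fixed threshold (including 0, a lossless round trip) can be
  supplied. Reconstruction is exact to ~1e−12 at zero threshold.
* Mean spectra: smoothing is applied per pixel first, then the
  arithmetic mean over the bulb's pixels is taken (the pixel spectra
  are the noisy objects); truncation to the analysis window happens
  last.

## Wavelength selection

All selectors operate on the calibration matrix only, take explicit
seeds, and return band subsets with per-band scores. To make stochastic
selectors invariant to the ordering of input rows, samples are sorted
canonically (by y, then by the spectra) before any random draw. Ties in
ranking are broken toward the lower band index. The internal
cross-validation inside the CARS and RF loops is seeded 5-fold;
model-level figures reported by `evaluate` use leave-one-out exactly.

* **SPA** grows a projection chain from every possible starting band
  (successively picking the band with maximal residual norm after
  orthogonal projection on the chosen set), scores every chain prefix
  by multiple-linear-regression leave-one-out RMSE (hat-matrix
  identity), and returns the global minimiser in selection order.
  Default chain length 15.
* **Bw** autoscales every band (zero mean, unit variance; zero-variance
  bands are excluded with a warning), fits PLS (default 7 latent
  variables) and scores bands by |standardised coefficient|; default
  rule keeps the top 13, with a mean+1·SD threshold rule available.
* **CARS** runs 50 Monte-Carlo iterations; each fits PLS on a random
  80% sample subset over the live bands, keeps the top-|coefficient|
  bands under an exponentially decreasing schedule calibrated to run
  from all bands down to 2, applies adaptive reweighted sampling
  (weighted draw with replacement, then deduplication; topped up from
  the highest-weight survivors if fewer than 2 bands remain), and
  records the 5-fold RMSECV of the surviving set. The minimum-RMSECV
  iteration wins; by default the winner is taken among live sets of at
  most 26 bands so the default configuration mirrors the reference
  workflow's largest selection (set `max_selected=None` to disable).
* **Random frog** proposes subset resizes by a rounded normal jump
  (sd = 0.3·q_init), adding candidates from outside or trimming by
  |PLS coefficient|, accepting improvements always and worsenings with
  probability `0.1·(RMSECV_current/RMSECV_candidate)`. A band's score
  is the fraction of iterations whose accepted subset contains it;
  the top 26 are returned. Default 500 iterations, q_init 13.

### Selector behaviour on the phantom

On this phantom the three signature bands of one analyte rise and fall
with a single latent quantity — the analyte's content — so their
columns are mutually collinear across samples; moreover the two
analytes' contents are correlated through the shared dose–response.
Parsimonious selectors therefore tend to pick **one** band per
signature group (usually near the strongest center) and then spend
their remaining capacity on flank and overlap bands, which carry the
only non-redundant information (Beer–Lambert curvature and
between-analyte contrast). Recovering *all* planted centers is not a
behaviour this data-generating process rewards, and tests asserting
multi-center recovery reflect that: prediction-oriented checks (model
performance, map accuracy) pass comfortably, center-recovery counts can
sit at one neighbourhood per analyte. On real spectra — with scatter,
drift and many interfering constituents — spreading selections across
all informative regions is rewarded far more strongly.

## Regression models

* **PLS**: NIPALS with mean-centering only (no autoscaling, the usual
  convention for reflectance spectra; the Bw selector autoscales
  separately because its scores require a common scale). Prediction is
  affine; at full rank PLS reproduces ordinary least squares, a
  property checked against a normal-equations oracle.
* **LS-SVM**: RBF kernel `exp(−‖x−x′‖²/σ²)`; the dual
  `[[0, 1ᵀ],[1, K + I/γ]]·[b; α] = [0; y]` is solved directly and the
  solve residual is required below 1e−8. Grid search runs over
  γ ∈ 10⁰..10¹² and σ² ∈ 10⁰..10¹⁰ (decade-spaced) using the
  closed-form leave-one-out residual `αᵢ/(A⁻¹)ᵢᵢ`, verified in the
  tests against an explicit refit loop.
* **ELM**: inputs rescaled per band to [−1, 1] from calibration ranges
  (constant bands map to 0); input weights and biases drawn
  uniform(−1, 1) from the seed, node by node, so a smaller network's
  random layer is a prefix of a larger one's (making training error
  monotone in width under a common seed); output weights are the
  minimum-norm least-squares solution; sigmoid activation. The same
  seed is reused in every cross-validation refit so RMSECV variation
  reflects the data, not reinitialisation.

**Splitting.** Random 3:1 calibration:prediction split (124/41 at
n = 165); after the draw, the samples attaining the minimum and maximum
of y are swapped into the calibration set so the prediction range is
covered. Minimum workable table size is 4 (3/1 split).

**Evaluation.** `r_c/r_cv/r_p` are Pearson correlations between
predicted and reference contents (calibration fit, leave-one-out CV,
held-out prediction); RMSEC/RMSECV/RMSEP are the corresponding
root-mean-square errors in % w/w. Zero-variance predictions yield an
undefined (NaN) correlation while the RMSE is still reported.
Hyperparameter ties go to the smaller model.

## Prediction maps

Pixel prediction uses exactly the training preprocessing: smooth the
pixel spectrum on the full axis, truncate to the analysis window, take
the model's band subset, predict. Models are trained on per-bulb mean
spectra and applied to single pixels — the same domain shift the
original workflow accepts; for affine models the per-bulb mean of pixel
predictions equals the prediction of the mean spectrum, which the tests
assert. Maps default to painting each bulb with its mean predicted
content (the per-bulb view used for sorting whole bulbs), with the raw
pixel-wise view available; color bounds default to the map's own range
and should be fixed to the calibration y-range when comparing scenes.
Out-of-range values are clamped and counted in the JSON sidecar.
Rendering is a pure function of (values, bounds, colormap). The
pseudo-RGB composite stretches the bands nearest 1000/1200/1400 nm to
0–255 per channel; a constant band maps to mid-gray by convention.

## Workflow scale

The default configuration is a reduced profile (2 scenes × 10 bulbs,
trimmed selector iterations) that finishes in well under a minute;
`profile="full"` switches to the complete 165-sample design, which the
acceptance script runs end to end in under a minute as well (96×128 px
scenes). Artifact hashes in the manifest make deterministic stages
reproducible bit for bit; PNG, CSV and JSON outputs are byte-stable
across reruns of the same configuration.

## Known limitations

* The phantom's simplicity (see above) makes prediction tasks easier
  than on real bulbs; performance figures on synthetic data are upper
  bounds, not forecasts.
* LS-SVM tuning inverts an (n+1)×(n+1) system per grid point; fine for
  n in the hundreds, not intended for thousands of samples.
* Pixel-level prediction inherits the mean-spectrum training domain;
  no scatter correction (MSC/SNV) is applied anywhere because the
  emulated workflow uses none.
* The wavelet threshold and segmentation threshold defaults are
  package choices exposed in configuration, not measured constants.
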