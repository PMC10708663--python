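# Methods

## Problem setting

A line-scan VIS/NIR hyperspectral camera images plates of dried plant
segments (six per row, five per column, on a bright Teflon-like background).
Each batch contributes one plate image of 128 spectral bands between 380 and
1064 nm (5.38 nm sampling; the 10 nm instrument resolution is carried as
metadata only — the data grid uses the sampling interval). Reference values
for five quality attributes — four marker metabolites and moisture, all mass
fractions — come from wet-lab assays. The task is multivariate calibration:
predict the five attributes of a new batch from its image alone.

## Radiometric model

Raw counts are converted to relative reflectance with white/dark reference
frames, `R = (I − D)/(W − D)`. The instrument convention names the
procedure but not the formula; this ratio form is the universal choice. The
denominator is floored at 1e-6 and the output clipped to [0, 1.5] so
specular pixels cannot produce unbounded values. Absorbance is
`A = log10(1/max(R, 1e-4))`; the floor avoids infinities at dead pixels.
Both floors only ever act on degenerate pixels, far outside the working range
of tissue reflectance (~0.02–0.9 here).

## Segmentation

Plant tissue contrasts most strongly against the bright plate in the NIR, so
the mask thresholds the band nearest 850 nm with Otsu's method (a fixed
threshold can be supplied), takes the dark class as foreground, applies one
3×3 binary opening (erosion with a closed border so a frame-filling
foreground survives), drops components under 50 px, and labels the rest
row-major. The default pipeline averages all foreground pixels of a plate
into one spectrum per batch — the calibration targets are per-batch values —
with a per-segment mode available.

## Sample-set partitioning and metrics

Kennard–Stone picks the calibration set by max–min Euclidean distance on the
mean spectra: seed with the farthest pair, then repeatedly add the sample
farthest from the selected set, until `floor(n · 4/5)` samples are chosen.
All ties break to the lowest index, making the split deterministic; at
n = 187 this yields the 149/38 split used throughout.

Metrics per analyte: `RMSE = sqrt(mean((ĉ − c)²))` on the calibration set
(RMSEC), pooled out-of-fold predictions (RMSECV, seeded 5-fold on the
calibration set), and the test set (RMSEP); the coefficient of determination
`R² = 1 − Σ(ĉ − c)² / Σ(c − c̄)²` with `c̄` the mean of the *measured*
values (a printed variant with predicted-value deviations in the denominator
circulates; the measured-value form is the standard definition and matches
the accompanying variable description); `RPD = sd(calibration references,
n−1)/RMSEP` with the usual interpretation bands (<1.5 limited, 1.5–2.0
coarse discrimination, 2.0–2.5 approximate, 2.5–3.0 good, >3 excellent); and
`RER = (Ymax − Ymin)/RMSEP` using the calibration-set extrema — recomputing
the published RER values from the published ranges and RMSEPs confirms that
convention. RMSE is non-negative by construction; published tables
occasionally print negative RMSEP/RER rows, which are arithmetic artifacts a
correct implementation cannot (and should not) reproduce.

## Wavelength selection

The three selectors share one PLS engine (NIPALS via scikit-learn) so
coefficient conventions agree.

* **CARS**: N = 50 Monte-Carlo runs by default, 80% row sampling, variables
  ranked by |PLS coefficient|; the retained fraction follows the enforced
  exponential schedule `r_i = a·e^{−k·i}` with `r_1 = 1`, `r_N = 2/p`
  (so `k = ln(p/2)/(N−1)`, `a = e^k`), followed by adaptive reweighted
  (coefficient-proportional) sampling among the survivors, floored at two
  variables; the subset with minimal 5-fold RMSECV wins.
* **SPA**: forward selection by maximal column norm after projection onto the
  orthogonal complement of the selected columns; when targets are supplied
  the chain prefix with minimal cross-validated RMSE is kept.
* **UVE**: p uniform noise columns (amplitude 1e-10 of the data scale) are
  appended; leave-one-out PLS coefficient stability `c_j = mean(b_j)/sd(b_j)`
  is computed and real variables with `|c_j|` at or below the largest noise
  stability are eliminated (zero-sd coefficients count as eliminated).

## Baseline regressors

PLSR (latent-variable count cappable and selectable by 5-fold CV over 1–15),
ε-SVR with RBF kernel (one model per analyte on z-scored targets; optional
seeded grid search over log-spaced C, γ, ε), and an RBF network (seeded
k-means centers; width = mean distance to the two nearest other centers;
ridge-regularized least-squares output weights). All three expose the same
fit/predict contract as the deep model, so evaluation is model-agnostic.

## The SE-ResNet regressor

Input: a per-sample reflectance view of the plate with spectral bands as
channels, transformed to absorbance — the Beer–Lambert log transform makes
the concentration–signal relation nearly linear, which measurably improves
the weakest analyte. The full-fidelity profile is the bottleneck-residual
family consistent with stage counts (3, 4, 23, 3) and a 2048-wide head
(1×1 reduce, 3×3, 1×1 expand; stage channels 256/512/1024/2048; SE reduction
16). The printed pooling padding of 3 for a 3×3 window would make border
outputs pure padding; the implementation defaults to padding 1 and leaves the
printed value selectable.

Squeeze-and-excitation per block: channel-wise global average → dense
bottleneck (reduction r) → ReLU → dense → sigmoid → channel rescaling.
Pinning all excitation weights to 1 turns the network into a plain residual
network (ablation switch, covered by a test).

Training (all artifact choices; no protocol is published): MSE on z-scored
targets, Adam at 2e-3 with cosine decay to 1/50th, batch 32, 400 epochs,
random horizontal/vertical plate flips (the layout carries no orientation),
Polyak weight averaging (decay 0.998) with batch-norm statistics re-estimated
under the averaged weights, and flip-averaged prediction. Inputs are
ZCA-whitened across the spectral channels on the training pixels (eigenvalue
shrinkage 1e-4 relative to the largest): per-band scaling leaves the weakest
analyte's discriminating spectral direction ~50× smaller than the dominant
ones and the stem compression loses it; whitening equalizes the signal
directions while the shrinkage keeps pure-noise directions damped. For the
headline study a 4-member ensemble is used whose members differ in seed and
alternate mixup strength (α = 0 and α = 1); mixup's convex sample mixing is
consistent with the generator's near-linearity in absorbance, and mixing
regularized with unregularized members decorrelates their errors where a
plain seed ensemble saturates.

The numpy substrate (`hsicalib.nn`) implements conv2d (im2col/col2im),
batch norm, max pooling, SE modules, dense layers and Adam with exact manual
backward passes (verified against numerical differentiation in float64).
Everything is float32, single-threaded-deterministic, and seeded through
`numpy.random.Generator`.

## Synthetic data generator

The generator reproduces the *statistical structure* of the study, not the
spectroscopy of the real analytes (whose signatures are not published):

* Concentrations: truncated multivariate normal with the published
  calibration-set means and min/max bounds per analyte, and correlation 0.64
  between cryptotanshinone and tanshinone IIA. The marginal sd is 0.35× the
  distance from the mean to the nearest bound — truncation then clips only
  ~2.9σ tails, so rejection is rare and the embedded correlation survives
  (realized sample coefficients at n = 2000 stay within ±0.05 across seeds,
  with a small (~0.01) truncation attenuation).
* Endmembers: five absorptivity curves, 2–4 Gaussian peaks each, centers in
  450–1000 nm, widths 20–60 nm, fixed by a seed decoupled from the sampling
  seed. Peak amplitudes scale inversely with the analyte's mean so each
  contributes a comparable (~0.25) absorbance at its mean — otherwise the
  trace constituents would be spectroscopically invisible and no method could
  recover them.
* Forward optics: tissue absorbance `A(λ) = Σ_k c_k ε_k(λ) · (1 + f) + 0.15`
  with `f` a smooth zero-mean spatial field (sd 0.03, ~10 px scale) standing
  in for illumination/scatter non-uniformity; `R = 10^(−A)`; plate background
  R = 0.92; raw counts `D + R(W − D)` plus Gaussian noise of sd
  0.01·(W − D) (i.e. 0.01 in reflectance units). White/dark frames are
  smooth per-band curves. An optional multiplicative scattering term (off by
  default) curves the reflectance–concentration relation.
* Geometry: the 6×5 disc grid. The default plate is 100×120 px (radius 8,
  20 px cells) so a 187-sample dataset renders in ~20 s; the instrument-scale
  703×800 frame is a parameter choice away. Network inputs are the whole
  plate block-averaged to 8×8 — a full-plate view lets the spatial field
  average out exactly as it does in the plate-mean spectrum, and coarser
  pixels carry proportionally less detector noise with no information loss
  for a per-batch regression target.

What passing tests show — and do not show. The generator is linear in
absorbance by construction (PLSR on noiseless spectra must reach R² ≥ 0.999;
a failure indicts the pipeline, not the data). Real plate data are
non-bilinear in reflectance, carry instrument drift, moisture-dependent
scatter and analyte signatures that overlap differently; desk-scale success
here validates the implementation and the workflow, not field performance.

## Study-scale check

The headline simulation trains the reduced-depth profile — stage counts
(1, 1, 2, 1), channels (64, 128, 192, 256), SE reduction 4, head 64→5, 8×8
input — on a 187-sample synthetic dataset at default noise, split 149/38 by
Kennard–Stone, and requires test-set Rp² ≥ 0.93 for every analyte. The
full-fidelity (3, 4, 23, 3)/2048 profile is constructed and shape-checked in
the suite but not trained there; training a ResNet-101-scale model is not a
desk-scale exercise.

## Numerical choices and degenerate inputs

* Ties (Kennard–Stone candidates, CARS coefficient ranking, SPA column
  norms) break to the lowest index, so every procedure is deterministic.
* Standardization uses the sample (n−1) standard deviation; zero-variance
  columns get a floored scale and a warning rather than an error.
* PLS component requests beyond the usable rank are capped with a warning.
* RBF widths are floored at 1e-8 for duplicate centers.
* Batch-norm epsilon 1e-5; reflectance/absorbance floors as above.
* Empty masks warn and return zero segments; empty ROI selections raise.

## Known limitations

* The ENVI reader supports the BSQ interleave this package writes, not the
  full dialect zoo (BIL/BIP, offsets, bad-band lists).
* Model persistence is by reproducible re-fit (config hash + seed), not
  serialized weights.
* The SVR grid search is deliberately small; serious tuning would widen it.
* Synthetic endmembers claim structural, not spectroscopic, fidelity; no
  conclusion about real *S. miltiorrhiza* spectra follows from them.
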