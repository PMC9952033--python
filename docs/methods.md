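# Methods

## Noise model and preprocessing

The observation model is additive white Gaussian noise, `a = a₀ + n` with
`n ~ N(0, σ²)` i.i.d. per pixel and σ in intensity units (the working scale
is [0, 255]).  Noise is added in floating point without clipping; values are
only quantized and clamped at image export.  The median prefilter uses the
full (2r+1)² square neighborhood including the center, with edge replication
at borders so output size equals input size; the default radius is 1 and the
radius is exposed as a flag since no single window size is canonical.
Min–max normalization maps the observed [min, max] to a target range,
default [0, 255]; it is undefined (and rejected) on constant images.

## The two-iteration non-local Bayes denoiser

**Parameters.**  Everything derives from σ: patch side e₁ is 3/5/7 with
breakpoints at σ = 20 and 50, e₂ is 3/5/7 with breakpoints at 50 and 70;
group size N = 3e²; search-window half-width λ = ⌈N/2⌉ (the rule N/2 yields
half-integers for odd N, rounded up); distance threshold τ₀ = 16e₂²,
independent of σ.  Note that at, say, σ = 20 the expected mean-squared
distance between two noisy copies of the same patch is ≈ 2σ² = 800, well
above τ₀ = 144, so the threshold rarely passes and the nearest-N fallback
(below) dominates grouping; this is the rule as specified and the fallback
makes it well behaved.

**Grouping.**  For each reference patch on a stride grid (default stride 1;
larger strides trade accuracy for speed and are capped at the patch side so
reference patches alone still tile every pixel), all patches whose anchors
lie in the window of half-width λ are candidates.  Distances are mean
per-pixel squared differences; candidates under τ₀ are retained and the N
nearest kept, falling back to the N nearest overall when fewer pass.  Ties
break by (row, col) anchor order; the reference is always forced into the
group.  In iteration 2 distances are computed on the iteration-1 (basic)
image.

**Shrinkage.**  Group statistics use the sample mean and the (n−1)-divisor
covariance, symmetrized.  Iteration 1 applies `P̂ = P̄ + F(P − P̄)` with
`F = C[C + σ²I]⁻¹` by default; a `classic` variant `F = (C − σ²I)₊C⁻¹`
(eigenvalue clamp at zero, the form implied by the clean-covariance relation
`Cₙ = C₀ + σ²I`) is available as a flag, since the two published forms of
the first-pass filter disagree and neither is asserted correct here.
Iteration 2 uses `P̂ = P̄₁ + C₁[C₁ + σ²I]⁻¹(Pₙ − P̄ₙ)` with mean/covariance
from basic patches and the innovation from noisy patches.  The filter is
applied in the eigenbasis of C (a symmetric eigendecomposition, never an
explicit inverse); eigenvalues are floored at `1e-8·trace(C)/e²` first.
Both variants give filter eigenvalues in [0, 1], so shrinkage contracts
toward the group mean.  A degenerate covariance (zero trace with σ = 0)
falls back to emitting the group mean.

**Flat-region shortcut** (default on): when the pooled sample standard
deviation of the group's noisy values is ≤ σ the group is treated as
homogeneous and every member receives the group mean — standard flat-area
handling that prevents noise-fitting in the uniform lung field.

**Aggregation.**  Every member receives one estimate per group it joins;
each pixel is the unweighted mean of all patch estimates covering it.
Coverage counts are returned for diagnostics.

**Degenerate σ.**  Parameter selection requires σ > 0; the denoiser itself
accepts σ = 0 and uses the σ → 0⁺ parameter limit (e₁ = e₂ = 3), in which
the filter is exactly the identity — a useful analytic check.

**Same σ in both iterations.**  No residual-noise re-estimation is performed
for the second pass; the original σ is reused, as no re-estimation rule is
specified for this pipeline.

## Feature bank

Features are computed on an image restricted to a binary ROI mask (≥ 16
pixels; the largest 8-connected component is used).  Segmentation is out of
scope: masks come from the caller or from the ground-truth phantom support;
an Otsu-threshold fallback exists for convenience but is not used in tests.

*Texture.*  Intensities in the ROI bounding box are quantized to 32 levels
over the ROI min–max; a symmetric co-occurrence matrix is accumulated per
offset {(0,1),(1,0),(1,1),(1,−1)} over pixel pairs that are both inside the
mask, normalized per offset and averaged.  Contrast, correlation (0 by
convention at zero variance), homogeneity, variance and entropy (base 2) are
standard.  "Spectral" and "spatial" are interpretations fixed here: the
fraction of ROI power-spectrum energy outside the lowest radial-frequency
quartile, and the lag-1 normalized spatial autocorrelation of masked
intensities.

*Shape.*  Area is the foreground count; perimeter is the weighted
boundary-step estimator; circularity = 4πA/P², irregularity its reciprocal,
roundness = 4A/(π·major_axis²) from second-order central moments.

*Intensity.*  Sum, mean, population variance, excess kurtosis, skewness,
median (midpoint for even counts); zero-variance ROIs report skewness and
kurtosis 0.

*Geometry.*  Eccentricity from second-order moments; compactness = P²/A; a
radial distance signature sampled by marching 360 uniform rays from the
centroid in half-pixel steps and keeping the farthest in-mask sample, giving
radial mean/std and roughness = std/mean; and a local area integral
invariant: the mean over boundary pixels of the fraction of a radius-5 disk
(radius configurable) lying inside the mask — 0.5 on a straight edge, lower
at spike tips, higher in concavities.  Because a spiculated boundary mixes
tips and concave valleys its *mean* occupancy need not drop below the disk
value; the discriminative spiculation signal is carried primarily by
roughness, which the tests quantify.

The full vector concatenates texture (7), shape (5), intensity (6) and
geometry (6) — 24 features in a fixed documented order.

## Classifier and protocol

Gaussian naive Bayes: priors are class frequencies; per-class per-feature
means and variances are maximum-likelihood moments, variances floored at
1e-9 times the largest pooled feature variance.  Prediction is MAP in
log-space with max-subtraction; exact ties resolve to malignant so a tie
never misses a cancer.  Evaluation uses a stratified seeded split with
⌊count·0.8⌋ of each class in training, and reports accuracy, specificity
TN/(FP+TN) and sensitivity TP/(FN+TP), positive class malignant.  The
classifier is intentionally simple — features, not the decision rule, carry
the discrimination.

## Synthetic phantoms: what they emulate and what they do not

Phantoms emulate the geometry and first-order statistics that the pipeline
consumes: a smooth background field (Gaussian-filtered white noise rescaled
to [40, 80], correlation length 8 px), a brighter nodule (+60 by default)
with a soft Gaussian radial intensity profile, and exact ground-truth masks.
Benign nodules are disks (radius ~ U(6, 14)); malignant nodules are
star-shaped with cosine-modulated radius `r(θ) = R(1 + A·cos kθ)`,
k ~ U{5..12}, A ~ U(0.3, 0.7) — a simple spiculation model with analytic
radial-signature ground truth.  The default composition is 8218/15000
malignant, and noise is the σ of the observation model.

They deliberately do *not* model: 3-D anatomy, vessels and ribs,
partial-volume and reconstruction artifacts, scanner noise correlation,
segmentation error (masks are exact supports; a dilation-noise option exists
for robustness experiments), or overlapping structures.  Passing tests
therefore demonstrate correctness of the algorithms and the expected
behavior on images with these statistics — not clinical performance.  In
particular the benchmark classification scores are near-perfect because
shape features on exact masks separate the two synthetic morphologies almost
deterministically; on clinical data with imperfect segmentations the same
pipeline would score lower.

## Problem sizes and numerical choices

The standard benchmark runs 200 phantoms of 128 px at σ = 20 with denoiser
stride 4 (capped to the patch side), chosen as the package's default
benchmark configuration; denoising-gain measurements use stride 2 and 5
seeds.  Tolerances: covariance eigenvalue floor 1e-8·trace/e²; variance
floor 1e-9·max pooled variance; GLCM quantization 32 levels; 360 radial
rays at 0.5 px steps; integral-invariant disk radius 5 px.  All randomness
flows through seeded `numpy` generators; identical seeds give bit-identical
images, splits and artifacts.

## Known limitations

- Grouping cost grows quadratically with the search window; large σ (e = 7,
  λ = 74) on big images is slow at stride 1.
- τ₀ as specified is σ-independent, so at realistic σ grouping is
  effectively nearest-N (see above).
- The radial signature requires the centroid inside the region
  (star-shaped masks); highly concave masks raise a geometric-degeneracy
  error rather than returning misleading values.
- Only single-frame 2-D grayscale inputs are supported (PNG/TIFF 8/16-bit,
  DICOM read-only).
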