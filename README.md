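# lungnlb

Early lung-cancer image analysis in 2-D: patch-based denoising of noisy CT
slices, nodule feature extraction, and benign/malignant classification.  The
package is aimed at researchers prototyping nodule-characterization pipelines
who need every stage — preprocessing, restoration, features, classifier,
scoring — testable on synthetic ground truth before touching clinical data.

## What it computes

**Non-local Bayes denoising (two iterations).**  A noisy image is modeled as
`a = a₀ + n` with `n ~ N(0, σ²)` i.i.d. per pixel.  Every e×e patch `P` is
treated as a sample from a Gaussian over its group of similar patches inside
a local search window; with group mean `P̄` and covariance `C` the patch is
shrunk by a Wiener-type filter

```
P̂ = P̄ + C [C + σ²I]⁻¹ (P − P̄)
```

run twice: the first pass filters noisy statistics, the second re-groups and
re-estimates `P̄₁, C₁` on the first pass's output (the "oracle" image) while
keeping the noisy innovation `Pₙ − P̄ₙ`.  All parameters derive from σ alone:
patch sides e₁ ∈ {3,5,7} (breakpoints at σ = 20, 50) and e₂ ∈ {3,5,7}
(breakpoints at 50, 70), group sizes N = 3e², search half-width ⌈N/2⌉, and
grouping threshold τ₀ = 16e₂².  A separate minimum-mean-square-error patch
estimator (Gaussian-weighted candidate average) is also provided.

**Preprocessing.**  Square-window median filtering (edge-replicated),
min–max normalization `I* = a_new + (b_new − a_new)(I − a)/(b − a)`, seeded
Gaussian noise injection, and PSNR scoring.

**Features.**  A 24-descriptor bank per nodule ROI: masked-GLCM texture
(contrast, correlation, homogeneity, variance, entropy) plus spectral and
spatial statistics; shape (area, perimeter, circularity, roundness,
irregularity); intensity moments; and geometry built on the radial distance
signature r(θ) — eccentricity, compactness, roughness = std(r)/mean(r), and
the boundary disk-occupancy integral invariant.

**Classification.**  Gaussian naive Bayes with MAP decision (ties go to
malignant), stratified seeded 80/20 split, and accuracy / specificity /
sensitivity from the confusion matrix with malignant as the positive class.

**Synthetic phantoms.**  Lung-field backgrounds carrying disk-shaped benign
or cosine-spiculated malignant nodules, `r(θ) = R(1 + A·cos kθ)`, with exact
ground-truth masks and a configurable class composition (default 8218/15000
malignant).

## Worked example

```
$ python examples/01_denoise_phantom.py
sigma=20 -> patch sides e1=3, e2=3, group sizes N1=27, N2=27, threshold tau0=144
PSNR noisy  :  22.11 dB
PSNR basic  :  28.63 dB   (after iteration 1)
PSNR final  :  33.45 dB   (after the oracle iteration)
gain        :  11.34 dB
```

The phantom's clean image is known, so PSNR is exact: iteration 1 already
removes most noise (+6.5 dB) and the oracle iteration adds almost 5 dB more.
`examples/02_nodule_features.py` contrasts a smooth and a spiculated nodule
(roughness 0.03 vs 0.38 — the separation the classifier exploits), and
`examples/03_classification_benchmark.py` runs the full
simulate → denoise → extract → train → evaluate loop on 60 phantoms.

There is also a thin CLI mirroring the library:

```
lungnlb simulate --n 20 --sigma 20 --seed 1 --out phantoms/
lungnlb denoise  --input phantoms/phantom-0000.png --sigma 20 --output out.png
lungnlb extract  --manifest phantoms/manifest.csv --out features.csv
lungnlb evaluate --features features.csv --seed 1 --out metrics.json
lungnlb benchmark --n 200 --sigma 20 --seed 7 --out report.json
```

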