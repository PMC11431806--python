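# Methods

## The measurement model

The package quantifies nuclear pleomorphism by decomposing the Nottingham
score-band descriptions into three per-nucleus elements and aggregating
them with a conditional weighted harmonic mean.

**Size.** `EPSize = (Ar − k)/k` measures relative area excess over the
benign reference `k`, the mean pixel area of benign epithelial nuclei
(default 849 px, obtainable from a user's own benign sample via
`estimate_k`).  The piecewise rule `ESize` maps the Nottingham bands:
areas below 1.5×k (EPSize < 0.5, including nuclei smaller than benign)
give 0, the 1.5–2× band passes EPSize through unchanged, and ≥ 2×
saturates at 1.  `k` is a pixel area and therefore magnification-bound:
it must be calibrated at the resolution of the images being scored.

**Shape.** `EShape = 1 − 4π·Ar/Peri²`, the complement of the
isoperimetric quotient: 0 for a circle, → 1 for elongated or bizarre
outlines.  The perimeter estimator matters: a naive pixel-edge count
gives a digital circle an isoperimetric quotient of ~0.79 (EShape ≈ 0.21),
contradicting the intended circle-maps-to-0 behavior.  We use the
Crofton 4-direction estimator (`skimage.measure.perimeter_crofton`),
under which digital disks score within ~1% of 1 (and the small overshoot
above 1 is clamped, so disks score exactly 0).  A 10×10 square measures
36.8117 px, frozen as a regression value.

**Appearance.** `EAppearance = Hol/Ar`, the enclosed hollow fraction,
proxies vesicular chromatin and prominent nucleoli.  A hollow pixel is a
low-hematoxylin pixel inside the nucleus whose 4-connected non-chromatin
component touches neither the outside of the nucleus nor the image
border — pale pixels on the rim are not hollows.  Chromatin vs
non-chromatin is decided by Otsu's threshold on the hematoxylin
concentrations within that nucleus (a constant-intensity nucleus is
treated as all chromatin).  Nuclei use 8-connectivity and holes
4-connectivity, the standard complementary pairing.

**Aggregation.** `HM = τ / Σ wᵢ/Eᵢ` over the included elements.  When
`ESize = 0` its reciprocal would be infinite, so the size term is dropped
and τ becomes the sum of the remaining weights (2 at the default unit
weights); otherwise τ is the sum of all weights (3).  This generalization
keeps the fixed-point property — equal elements return themselves — for
any positive weights.  If shape or appearance is exactly 0 the score is 0
(the continuous limit of the harmonic mean).  The harmonic mean is
dominated by its smallest element, so a nucleus must be jointly large,
irregular and hollow-rich to score high.

## Stain unmixing

Tiles are converted to optical density (`OD = −log10(I/i0)`, i0 = 255,
intensities floored at 1 so black pixels stay finite), where Beer–Lambert
absorption makes stain contributions linear.  The two stain directions
are estimated from the data: SVD of the foreground OD pixels (any channel
above 0.15) gives a 2-plane, and the 1st/99th percentiles of the in-plane
angle distribution define the two stains; the one closer in cosine to the
canonical hematoxylin direction (0.65, 0.70, 0.29) is labelled H.  On
tiles overwhelmingly dominated by one stain (a single nucleus on an
eosin background) the percentile angles collapse into the majority
cluster; the estimator then falls back to the extreme angles.
Concentrations are recovered by pseudo-inverse projection with negatives
clamped to 0.

## Evaluation protocol

Scores 1–3 are classified with an RBF-kernel SVM under stratified
fivefold cross-validation; features are standardized inside each fold
(statistics fit on training folds only).  SVM hyperparameters are the
conventional defaults C = 1 and gamma = 1/(n_features·Var), recorded in
the config.  Metrics are per-class one-vs-rest Accuracy, Recall,
Specificity, Precision and F1, computed both from pooled out-of-fold
predictions and as per-fold means; "overall" is the unweighted macro
average over the three classes (note macro one-vs-rest accuracy has a
chance level of ~5/9 on balanced 3-class data because it credits true
negatives; macro recall is the balanced accuracy with chance 1/3).
Undefined ratios (0/0) are reported as 0 and flagged.  The ablation grid
re-runs the same protocol per feature subset: each element alone, each
pair, and HM.

## The synthetic generator

Clinical slides are not distributable, so validation runs on generated
nuclei that emulate the score-band descriptions:

- **Boundary:** star-convex radial Fourier series
  `r(θ) = r0 (1 + s·Σ aₘ cos(mθ+φₘ))`, harmonics m = 2…10 with 1/m
  amplitude decay.  Irregularity is specified directly as a target EShape
  band per score — 1: (0, 0.12), 2: (0.15, 0.35), 3: (0.38, 0.60) — and
  the amplitude `s` is solved by bisection on the continuous curve's
  isoperimetric quotient (radius kept ≥ 0.25·r0 to stay star-convex,
  which caps reachable EShape near 0.6).  Rasterized EShape tracks the
  continuous target within ~0.02 up to ~0.5.
- **Area:** a multiplier of k drawn per score from the Nottingham bands
  (1: 0.8–1.5, 2: 1.5–2.0, 3: 2.0–3.5) and enforced *exactly* on the
  raster by adding/trimming boundary pixels ranked by their radial
  residual, so the ESize band semantics hold without rasterization noise.
- **Hollows:** an exact pixel count (fraction bands 1: 0–0.1, 2: 0.1–0.3,
  3: 0.3–0.6 of the area) planted as unions of small disks inside the
  twice-eroded interior, so no hollow can touch the boundary; the last
  disk is truncated in raster order to land on the exact count.
- **Rendering:** Beer–Lambert with the canonical H&E basis — hematoxylin
  0.9 in chromatin, 0.03 in hollows; eosin 0.25 outside the nucleus,
  0.05 inside — quantized to 8-bit.

Everything is driven by one `numpy` Generator, so datasets are
bit-reproducible from (specs, seed).

What the generator does **not** emulate: texture inside chromatin,
touching/overlapping nuclei, segmentation errors, stain variability
between slides, scanner noise, and the diffuse (non-disk-shaped)
chromatin clearing of real vesicular nuclei.  Consequences: measured
features recover the planted ground truth essentially exactly, per-score
feature distributions have clean gaps that real data would not show, and
the classification benchmark (HM-feature SVM accuracy ≥ 0.9 on 200
nuclei/score) demonstrates internal consistency of the pipeline — that
the measurement preserves the generative score structure — not clinical
performance.  The ablation ordering (HM above every single element) does
mirror the qualitative finding that the aggregate beats its parts, since
single-element boundaries carry uniform density while HM boundaries
require all elements to be extreme simultaneously.

## Numerical and design notes

- Reference worked examples: the nine published component triplets
  reproduce their reported HM values to within one unit in the fourth
  decimal — the precision at which the inputs themselves are printed.
  One row (EPSize 0.5034) computes to 0.375953 vs a reported 0.3759,
  a half-ulp rounding effect of the printed inputs; tests assert
  agreement at 1e-4 accordingly.
- The printed size column of those examples is the raw ratio EPSize, not
  ESize: two rows (0.3993, 0.0863) lie outside ESize's codomain, and only
  applying the size rule to them before aggregation reproduces the
  reported HM values.  Both size-excluded rows go through the τ = 2
  branch.
- Label masks: multi-fragment labels keep the largest 8-connected
  fragment with a warning (segmentation artifacts should not abort a
  batch); float-typed or multi-channel masks are rejected.
- Expert mask correction is supported as an optional directory of
  corrected masks that overrides the originals by filename stem.
- Every CSV written by the pipeline begins with a comment line embedding
  the configuration hash and seed; reruns at a fixed seed are
  byte-identical.
- Experiment scale: the bundled experiment and tests use 200 nuclei per
  score (the benchmark), with smaller sizes (4–25/score) in unit tests
  and examples; generation plus measurement of the 600-nucleus benchmark
  takes well under a minute on one CPU.

## Known limitations

- `k` transfers across magnifications only if rescaled; the package
  stores optional microns-per-pixel metadata but does not auto-convert.
- The hollow-pixel definition (Otsu + enclosure) is this package's
  operationalization; other reasonable thresholding rules would shift
  EAppearance on real images.
- EShape is resolution-sensitive for very small nuclei (< ~100 px), where
  any discrete perimeter estimate is coarse.
- The HM → discrete score mapping is deliberately left to a classifier;
  no fixed thresholds are provided.
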