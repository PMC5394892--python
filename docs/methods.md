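# Methods

`esocad` implements a classical computer-aided diagnosis pipeline for
grayscale esophageal radiographs: isolate a lesion window, summarize it as a
37-dimensional feature vector drawn from three complementary domains
(co-occurrence texture, wavelet frequency, binary-pattern complexity),
reduce the vector by wrapper selection or principal components, and classify
in two binary stages (normal vs. abnormal, then fungating vs. ulcerative)
with cross-validated error bars. This note records the model choices, the
defaults and why they were chosen, and what the synthetic benchmark does and
does not establish.

## Preprocessing

Raw esophagrams are dominated by background; the pipeline crops a fixed
region of interest — by default 140 rows × 240 columns, supplied per image
since lesion placement varies — then median-filters and histogram-equalizes
the window.

* **Median kernel**: 3×3 by default (the smallest standard denoising
  window); configurable. Borders are reflect-padded so the filter does not
  darken the frame, which would otherwise bias co-occurrence counts near
  edges.
* **Equalization** is the plain global CDF remap
  `v → round((L−1)·cdf(v))` with an inclusive CDF. It is monotone, so
  gray-level ordering is preserved, and a constant image passes through
  unchanged. Adaptive variants (CLAHE) are deliberately out of scope.

## Texture features (16)

The gray-level co-occurrence matrix `P(i, j | d, θ)` is accumulated at
distance `d = 1` for θ ∈ {0°, 45°, 90°, 135°} with the (row, col)
displacement convention 0°→(0,+d), 45°→(−d,+d), 90°→(−d,0), 135°→(−d,−d).
Matrices are symmetrized (both pair orderings counted) and normalized to a
probability distribution, since the downstream statistics — energy and
homogeneity in particular — assume one. Four Haralick statistics are read
off each matrix:

    contrast    = Σ (i−j)² P(i,j)
    correlation = (Σ ij P(i,j) − μxμy) / (σxσy)
    energy      = Σ P(i,j)²
    homogeneity = Σ P(i,j) / (1 + |i−j|)

with correlation defined as 0 for a degenerate (constant) image.
Intensities are first uniformly re-binned to **L = 32** levels: full 256-bin
matrices on a 140×240 window are sparse and noisy, and 32 is standard
Haralick practice. `stat × angle` gives the 16-element block, stat-major
order, columns named `contrast_45` etc.

## Frequency features (20)

A 4-level separable 2-D DWT is applied, recursing on the approximation band
only. The finest-level (level-1) details are discarded as noise; the
retained subbands are the deepest approximation A4 plus the H/V/D details of
levels 2–4. The block is the mean and variance of each retained subband
(10 subbands × 2 = 20 values).

* **Basis**: Haar by default — the simplest orthogonal basis, making the
  hand-worked 2×2 expansions and the Parseval check exact. Configurable via
  any PyWavelets name.
* **Boundary mode**: periodization, so the transform stays exactly
  orthogonal on dyadic sizes (total coefficient energy = image energy within
  1e-8 relative). On non-dyadic sizes the odd-length levels introduce a
  small (~0.1%) padding effect, identical across images of one cohort and
  therefore harmless to classification.
* **Variance** is the population formula (divide by n): these are
  descriptive features, not estimators, and the fixed convention keeps
  values bit-reproducible.
* **Mean** of signed detail bands is the plain arithmetic mean, not the
  mean absolute value; detail means carry orientation information near
  zero, and the variance terms carry the energy.

## Complexity feature (1)

Kolmogorov complexity is uncomputable; the computable proxy is the
Lempel–Ziv production count under the Kaspar–Schuster parse: scan the binary
sequence left to right, grow the current word while it can be copied from
the history (a copy may start before the word and run into it), and count a
production each time an inserted symbol closes a word. The count is
normalized by `n / log₂ n` — the asymptotic count for a random sequence — so
the feature is comparable across image sizes and ≈1 for incompressible
input.

The image-level scalar: binarize the image (global-mean threshold by
default, Otsu available; a constant image maps to all zeros by convention),
take the normalized complexity of each row, binarize the resulting
row-complexity vector at its median (ties map to 1 — deterministic and
scale-free), and return the normalized complexity of that sequence. The
row-then-rows construction makes the feature sensitive to *row-to-row
irregularity* of within-row pattern complexity, not merely to average pixel
disorder — a property the synthetic ulcerative archetype is built around
(see below).

## Feature selection

**Sequential forward selection (SFS)** is a wrapper: starting from the empty
set, each step adds the single feature minimizing the criterion — the mean
misclassification rate (equivalently the MSE of one-hot class predictions)
of the downstream classifier under internal stratified 5-fold CV on the
training partition. The search stops when no addition strictly improves the
criterion, or at a preset size (`fixed_k`); ties break toward the lowest
column index so the greedy trace is reproducible. Inside the wrapper the
SVM runs at fixed mid-grid hyperparameters (C=1, γ=1/p) — a nested grid
search per candidate subset would multiply cost by ~140× for no change in
ranking at these sample sizes; the final per-fold model after selection is
still tuned.

**PCA** standardizes features to zero mean / unit variance, eigendecomposes
the (correlation) matrix, and retains the minimal leading components whose
cumulative explained variance reaches the threshold (default **0.9**). Each
eigenvector's dominant loading is made positive so serialized models are
stable. Zero-variance columns are dropped with a warning.

By default selection is fitted **inside each outer CV fold** on the training
partition only, so no validation information leaks into the reduced
subspace. `global_selection=True` reproduces the common (leaky) practice of
selecting once on the whole table before cross-validation; it exists for
comparability, not as the recommended protocol.

## Classification and evaluation

* **SVM** — RBF kernel on standardized features. C and γ are tuned per
  training fold by stratified 5-fold grid search over C ∈ {0.1, 1, 10, 100}
  and γ ∈ {2⁻⁴ … 2²} unless fixed in the spec; generalization is sensitive
  to both and no universal values exist.
* **KNN** — majority vote among the K Euclidean-nearest standardized
  training points, K = 15 by default and odd by contract (a binary vote
  cannot tie). The ROC score is the positive-class neighbor fraction.
  `knn_k_sweep` evaluates odd K from 1 to 21 so the best K can be located
  empirically per dataset.
* **Protocol** — stage 1 classifies all samples normal vs. abnormal;
  stage 2 classifies the abnormal subset fungating vs. ulcerative. Each
  stage runs stratified 10-fold CV (90%/10% splits) with a fixed shuffle
  seed. Per fold: selection (if any) → train → validate. Reported per
  metric: fold-wise values, their mean, and the 95% Student-t half-width
  over folds. AUC is the per-fold trapezoidal ROC area averaged over folds
  (the pooled-score AUC is also emitted for reference). Accuracy, precision
  and recall are percentages from the fold confusion matrix; precision of a
  never-predicted class is reported as 0 and flagged rather than silently
  dropped.

Everything downstream of a fixed config and seed is deterministic; the
report embeds the config hash.

## Synthetic cohort

No suitable public esophagram collection with fungating/ulcerative labels
exists, so the benchmark cohort is generated:

* **normal** — smooth shading: white noise blurred at σ=18 px, rescaled to
  mean 120 ± 35 intensity units.
* **fungating** — shading plus a 45°-oriented sinusoidal ridge pattern
  (period 6–10 px) inside a lobulated 3-lobe mass; raises directional GLCM
  contrast and mid-level wavelet detail variance.
* **ulcerative** — shading plus ±1 speckle over row-wise scattered
  segments (each row independently carries a segment with probability 0.5,
  random position and extent). The scattering across rows is essential:
  contiguous crater blobs would make the per-row complexity sequence smooth
  and *lower* the image complexity feature; row-scattering makes both the
  within-row patterns and the row-complexity sequence incompressible, which
  is exactly what the feature measures.

Defaults: 100 images per class (a balanced three-class study of 300
images), 140 × 240 px, separation δ = 1.0, pixel noise σ = 8. δ scales the
structure amplitude (30·δ intensity units); at δ = 0 the three classes are
drawn from the identical background distribution, giving an exact null for
permutation and chance-AUC checks.

The generator emulates the *feature-space geometry* of the classification
problem — each feature family is decision-relevant for at least one class
boundary — not radiographic physics: there is no barium column, no
projection geometry, no scanner characteristic. Passing benchmarks
therefore demonstrate that the pipeline recovers planted, well-separated
class structure; they say nothing about clinical discrimination on real
esophagrams.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run the full grid at 30 images
per class, δ = 2.0, noise σ = 5 (clearly separated classes), where both
classifiers exceed 95% mean CV accuracy on both stages; the δ = 0 null sits
at chance AUC; SFS recovery is measured on 20 replicates of an 80-sample,
10-feature table with two decisive (+5σ) signal features. These sizes keep
a full run in minutes on one core while leaving every statistical contract
testable.

## Known limitations

* The complexity bridge (median-binarization of the row-complexity vector)
  is one deterministic choice among several defensible ones; the raw
  production counts are retained in debug paths for sensitivity work.
* Homogeneity uses `1 + |i−j|`; correlation of a constant image is defined
  as 0. Both are conventions, stated so values are comparable across
  implementations.
* Wrapper SFS is greedy: with weakly informative features it can admit a
  noise feature that happens to repair the last few internal-CV errors.
  This is inherent to the method, visible in the recovery benchmark when
  the planted effect is reduced.
* 16-bit inputs are linearly rescaled to 8-bit on read; DICOM is not
  ingested.
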