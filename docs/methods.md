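# Methods

## Overview

`mammoseg` segments bright masses in 2-D grayscale images by seeded region
growing, selects the seeds automatically with a fuzzy-c-means/genetic-
algorithm (FCM-GA) hybrid, offers a Gaussian-mixture (GMM-EM) segmenter
with optional hidden-Markov-random-field (HMRF) refinement for comparison,
and classifies segmented regions as benign, malignant or normal from
co-occurrence texture features with a probabilistic neural network (PNN).
Because no clinical data ship with the package, a synthetic phantom
generator with exact ground truth drives all tests and experiments.

## Region growing

A region is a connected pixel set grown breadth-first from a seed. Its
count N, mean μ and sample standard deviation σ (N−1 denominator) are
updated recursively as each pixel is accepted:

    μ_N = ((N−1) μ_{N−1} + I_N) / N
    σ_N² = ((N−2) σ_{N−1}² + (N/(N−1)) (I_N − μ_N)²) / (N−1)

which reproduces the batch statistics exactly (verified to 1e-9). Two
similarity criteria, both with *strict* inequalities:

* **std band**: μ − Xσ < I < μ + Xσ with X = 3, the band containing
  ~99.7% of Gaussian samples — the default;
* **threshold**: μ − X < I < μ + X with X in gray levels (no default; the
  CLI requires it explicitly in threshold mode).

The region starts with σ = 0, which makes the std band empty; we therefore
bootstrap with the threshold rule until `bootstrap_min` (9) pixels are
accepted and floor σ at `sigma_floor` (1 gray level) afterwards. The
frontier is FIFO with neighbors enqueued N, S, W, E, NW, NE, SW, SE
(8-connectivity by default); a rejected pixel may be re-tested when the
region reaches it from another accepted neighbor, since the band may have
widened. On piecewise-constant images the threshold criterion reduces to
exact connected-component extraction (verified exhaustively on all 2^16
binary 4×4 images).

## FCM-GA seed selection

FCM minimizes J_q = Σ_i Σ_j u_ij^q (x_j − c_i)² subject to Σ_i u_ij = 1,
with fuzzifier q = 2 and K = 10 clusters by default. Membership and center
updates are the standard alternating formulas; memberships are computed
from min-distance-scaled ratios so nearly coincident centers cannot
overflow. Because intensity-only clustering depends on the data only
through value counts, images are clustered through their 256-bin histogram
(exact, and ~250× faster than per-pixel evaluation).

The GA searches over center vectors only (memberships are implied by the
centers): population 100, mutation rate 0.2, blend crossover 0.8,
tournament size 2, elitism 1, per-gene Gaussian mutation with SD 10 gray
levels, 50 generations. Fitness defaults to J_q evaluated at the
chromosome's centers; a tri-level segmentation-disagreement cost
(gray/white/black layer indicator differences against a tercile
quantization of the filtered image) is available as an alternative but is
much more expensive, since each evaluation grows a full partition.

The tumor seed is the pixel with maximal membership in the cluster whose
center intensity is highest (masses are hyperintense); membership ties
break to the pixel nearest the center in intensity, then to the smallest
(row, col). The pipeline grows from up to 5 such candidates spaced ≥5
pixels apart and keeps the largest mask within the area bounds below; if
*every* candidate stalls below the minimum area (the bootstrapped band can
trap a too-homogeneous start), the candidates are regrown once with the
threshold criterion at X = 30 gray levels (half the expected mass
contrast). Masks outside [32 px, 15% of the image] are reported as "no
tumor" (empty), which is also how normal images are recognized.

## Adaptive median filter

The classical two-level algorithm with a growing window (3 → 7, odd):
level A grows the window until the window median is not an extreme value;
level B replaces the pixel only if the pixel itself is an extreme value.
Borders are reflect-padded. The filter removes ≥99% of 10% salt-and-pepper
noise on flat images exactly, is the identity on clean constant images, and
never invents intensities (every output value occurs in some input window).

## GMM-EM and HMRF

Intensities follow f(x) = Σ p_i N(x | μ_i, σ_i) with k = 2 components by
default, initialized by Lloyd k-means (empty clusters reseeded to the
farthest pixel) and fitted by at most 100 EM iterations (stop at
|Δ log L| < 1e-8). The default **full** E-step uses weights and the 1/σ
normalizer (log-sum-exp stabilized) and the M-step re-estimates means,
variances (floored at 1e-3) and weights; log-likelihood is then
monotonically non-decreasing. A simplified **unweighted** mode uses
exponent-only responsibilities and updates the means only. Hard
segmentation takes the per-pixel posterior argmax (ties to the lower
component index).

HMRF refinement minimizes Σ_s [(y_s − μ_{x_s})²/(2σ²_{x_s}) + log σ_{x_s}]
+ β Σ_pairs 1[x_s ≠ x_t] by raster-order ICM sweeps (β = 1,
4-neighborhood, 5 sweeps), alternating with per-label parameter
re-estimation (3 rounds); a label with no pixels keeps its previous
parameters. Each single-site update is the exact conditional minimizer, so
the energy never increases within a sweep.

## Texture features and PNN

The ROI (segmented mass, or for normal images the brightest region of at
least 32 px from a full region-growing partition) is quantized to 16
levels over its own masked intensity range. Co-occurrence matrices count
pixel pairs with *both* endpoints inside the mask for the four unit
offsets (0,1), (1,0), (1,1), (1,−1), symmetrically accumulated and
normalized. Five scalar features — contrast, correlation, energy,
homogeneity, entropy (log base 2) — are averaged over the four offsets,
which makes the signature invariant under 90° ROI rotations.

The PNN stores all standardized training vectors (zero-variance features
dropped with a warning) and scores a query by class-averaged Gaussian
kernels, S_c = (1/n_c) Σ exp(−‖q − p‖²/2σ²), normalized to posteriors via
log-sum-exp. σ defaults to 0.5 in standardized units; a leave-one-out grid
search is available. As σ → 0 the classifier reduces to 1-nearest-neighbor
(tested against a brute-force oracle). Class averaging keeps unbalanced
training sets from dominating; multiclass output is native, and binary
metrics are computed one-vs-rest with "malignant" as the default positive
class.

## Metrics

Jaccard index |A∩B|/|A∪B| (defined as 1 when both masks are empty, so a
correct "no tumor" answer scores 1) with distance 1 − index; RMS mask
error √(disagreeing fraction); sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), accuracy (TP+TN)/total, and fall-out
FP/(FP+TN) = 1 − specificity. Any 0/0 rate is reported as NaN with a
warning so batch benchmarks never abort. The ROC sweeps thresholds over
the unique scores (±∞ endpoints); its trapezoid AUC equals the normalized
Mann–Whitney statistic with ties counted one half (tested exactly).

## Synthetic phantoms

Each phantom is 256×256 uint8 (size is configurable up to screening-scale
1024×1024): background 15, a half-ellipse breast at 110 with smooth
fibroglandular texture (SD 3, correlation length 8 px), an optional
pectoral wedge at 145 in the top corner, and zero or one mass at +60
contrast with a radial falloff to 60% at the margin. Benign masses are
disks with smooth correlated speckle (SD 2); malignant masses are
spiculated star polygons (8 spikes by default) whose heterogeneous
interior is modeled as punctate bright foci — microcalcification-like
specks at 25% density with amplitude chosen so the interior SD equals the
requested texture SD (12 by default). Gaussian pixel noise (SD 5) and
optional salt-and-pepper impulses complete the image; the truth mask is
the exact analytic mass support. Datasets are generated in fixed class
order (normal, benign, malignant) with per-item child seeds, jittered
centers and radii (±25%), and are bit-reproducible.

The punctate texture model serves two purposes: the adaptive median filter
removes the foci before segmentation (so the std-band grower sees a smooth
interior), while the raw image keeps a strong co-occurrence contrast
signal that separates malignant from benign interiors on essentially every
seeded pair. What the phantoms do **not** emulate: anatomic tissue
superposition, scanner characteristic curves, spiculations radiating
*outside* the mass support, low-contrast or isodense masses, and pectoral
overlap with the mass. Passing tests therefore demonstrate algorithmic
correctness and the expected qualitative ordering of methods, not clinical
performance; headline numbers on real screening data cannot be reproduced
without those datasets.

## Problem sizes and numerical choices

The standard experiment suite is 3 × 20 phantoms at 256×256 — large enough
that every stage (filtering, GA seeding, growing, feature extraction,
leave-one-out classification) runs in minutes on one CPU while the
qualitative comparisons stay stable across seeds. FCM/EM tolerances are
1e-5 and 1e-8 on objective/log-likelihood changes; FCM membership columns
normalize to 1 within 1e-9; EM monotonicity is asserted with 1e-7 slack;
GA history is non-increasing by elitism. Ties everywhere break
deterministically (raster order, lower index, first listed class) so runs
with equal seeds are bit-identical.

## Known limitations

* The std-band criterion assumes the mass interior is markedly more
  homogeneous than its contrast step; interiors with SD comparable to the
  contrast leak or stall by construction (the threshold fallback mitigates
  stalls only).
* The brightest-cluster seed heuristic fails for hypointense masses.
* GMM with two components merges mass and breast tissue when the
  background/tissue split dominates the histogram; on the phantoms the
  area bound then reports "no tumor", which matches its role as the weaker
  comparison method.
* ICM is a greedy energy minimizer; it refines labels but cannot escape
  poor GMM fits.
* The 60-image classification experiment separates phantom classes
  perfectly at σ = 0.5; that reflects the phantom design, not expected
  clinical accuracy.
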