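# Methods

This note documents the models and procedures implemented in `mammosub`,
the parameter choices that matter, what the synthetic phantom does and
does not emulate, and the package's known limitations.

## Pipeline overview

A temporal pair (recent + prior view of the same breast and projection)
flows through preprocessing → non-rigid registration → subtraction →
candidate detection → feature extraction → two-round classification. A
`--recent-only` arm skips registration and subtraction and detects
directly in the preprocessed recent image; it is the comparison arm that
quantifies what the temporal information buys.

## Preprocessing

* **Normalisation**: min–max rescale to [0, 1]; constant images map to
  zeros. Idempotent by construction.
* **Breast segmentation**: threshold at `fg_threshold` (default 0.05),
  morphological closing (disc r = 3), a cleared 4-px frame margin (drops
  edge labels/artifacts), largest 8-connected component, holes filled.
  The mask must be a single connected component with positive area.
* **Gamma correction**: `out = in^γ`, default γ = 2.0 — suppresses the dim
  background and stretches the bright range where microcalcifications
  live. The exponent is a config key (`preprocess.gamma`); 2.0 is this
  package's default since the referenced technique does not fix one.

Both images of a pair are processed with identical parameters, and pixels
outside the breast mask are zeroed so registration forces and contrast
statistics are confined to tissue.

## Demons registration

Classic Thirion Demons with backward (pull) warping: the displacement
increment at each pixel is

    u = −(m∘φ − f) ∇f / (|∇f|² + (m∘φ − f)²)

with `f` the fixed (recent) image and `m∘φ` the warped moving (prior)
image. Updates are capped at 2 px, smoothed with a fluid kernel
(σ_fluid = 1), added to the field, and the field is smoothed with a
diffusion kernel each iteration. The solver runs coarse-to-fine over a
×4/×2/×1 pyramid, keeps the best-so-far field per level (so the mean
squared difference never ends above its starting value at any level), and
stops early when the metric has not improved relatively by 1e-4 for 10
iterations.

Defaults that deviate from a naive textbook setting, and why:

* **σ_diffusion = 4.0, 80 iterations/level.** On phantom benchmarks with
  realistic noise, σ = 2 lets the field fit noise (endpoint error worsens)
  while σ = 4 suppresses it without losing the smooth true deformation;
  80 iterations with the 10-iteration stop window lets coarse levels
  converge. Both remain config keys.
* **Symmetric forces with σ = 1 pre-smoothing.** The driving gradient is
  the average of the fixed and warped-moving gradients computed on lightly
  smoothed images; measurably more stable on noisy pairs.
* **Intensity harmonisation before registration.** Per-image min–max
  normalisation leaves a small gain mismatch between rounds, and
  acquisitions drift; intensity differences the demon forces cannot
  explain by motion are otherwise absorbed into large spurious flows
  (endpoint error worse than not registering at all, reproducible with
  independent Demons implementations). The moving image is therefore
  corrected by a low-pass gain ratio (σ = 32 px, ratio clipped to
  [0.5, 2]) and then exact histogram matching inside the breast mask.
  This is the same practice ITK recommends for demons-family methods.
* **Masked damping.** The accumulated field is multiplied each iteration
  by a blurred breast mask, forcing displacements to ~0 where there is no
  intensity information to constrain them.

On ten default phantoms (512×416, 6-px peak deformation, 1% noise, 2%
drift) the solver reduces the mean endpoint error against the generator's
true field by ≈ 71% relative to the zero field (≈ 81% on noise-free
pairs). For reference, SimpleITK's classic/fast-symmetric/diffeomorphic
demons filters reach 42–64% on the same preprocessed pairs, so the
shipped solver is at the practical ceiling of this algorithm family under
these conditions.

## Subtraction and removal accounting

`diff = max(recent − warped prior, 0)` inside the breast mask, zero
outside. Negative differences are clipped: new findings are brighter than
their local background, and darkening is not a detection signal here.
Background suppression is summarised by the **contrast ratio** (max/mean
over mask pixels — computed breast-only, since a zero background would
arbitrarily deflate the mean) and the **intensity reduction**
`100·(1 − mean(diff)/mean(recent))`.

A microcalcification counts as *removed* when its residual peak in the
difference image, within an 11×11 window around its annotated centre,
falls below half its contrast in the recent image. Contrast is the window
peak above the window median (a local-background estimate): comparing the
residual to the absolute intensity instead would make "removal" depend on
how bright the tissue under the spot happens to be. Threshold (0.5) and
window half-width (5 px at phantom scale) are config keys.

## Detection

Range filter (local max − min, window 3, replicated borders) →
binarisation at a global threshold → morphological cleaning (closing with
disc r = 1 bridges hairline gaps; components under 4 px are dropped,
judged on their pre-closing support so closing cannot inflate specks past
the cut) → 8-connected labelling. Defaults are stated at phantom scale
(512×416) and scale linearly with image width for full-resolution data.

The binarisation threshold is not a constant of the method: it is
optimised on a labelled development set by maximising `tp − fp` through
the full detect-and-match path (ties toward the higher threshold). The
phantom study optimises it per arm over the grid {0.05 … 0.4}.

Candidate-to-annotation matching is optimal one-to-one assignment
(Hungarian, with a prohibitive cost on ineligible pairs): a pair is
eligible when the point lies inside the candidate mask or within 8 px of
its centroid; the matching maximises eligible pairs and, among those,
minimises total centre distance. A greedy nearest-first rule was
considered and rejected — it is provably non-optimal on dense instances,
while the assignment solution is deterministic and exactly matches
exhaustive enumeration everywhere.

## Features (96)

* **Shape (12)**, from the candidate's binary mask via `regionprops`:
  area, perimeter, eccentricity, solidity, extent, major/minor axis
  lengths, aspect ratio, equivalent diameter, circularity `4πA/P²`,
  convex area, orientation.
* **First-order intensity (12)**, over mask pixels: mean, std, min, max,
  median, skewness, kurtosis, energy (Σx²), histogram entropy (32 bins),
  range, 10th and 90th percentiles. Skewness/kurtosis are defined as 0 on
  (numerically) constant regions.
* **GLCM texture (72)**: the patch is the bounding box dilated by 2 px,
  grown with surrounding image context to at least 32×32 so every offset
  fits (edge-replicated only at image borders — zero-padding would
  manufacture artificial edges); quantised to 32 grey levels.
  Co-occurrence matrices are accumulated at angles {0°, 45°, 90°, 135°}
  and offsets {5, 15, 25} px, normalised to sum 1, **not** symmetrised.
  Twelve properties per matrix (contrast, correlation, energy Σp²,
  homogeneity, dissimilarity, entropy, maximum probability, sum average,
  sum variance about the sum mean, sum entropy, difference variance,
  difference entropy), summarised as mean and standard deviation across
  the four angles, separately per offset: 12 × 3 × 2 = 72. The
  correlation of a degenerate (zero-variance) matrix is defined as 1.

The 24 non-GLCM feature identities and the 12-property set are this
package's fixed, versioned schema (`FEATURE_NAMES`), engineered so the
GLCM block is exactly 72 of the 96; anyone comparing against other
implementations should treat feature identities as approximate.

Note one subtlety the test suite encodes: a bright disc on a uniform
background does *not* give zero angular spread of GLCM properties,
because diagonal offsets span √2 more distance than axial ones; the
zero-texture limit (all std-type GLCM features exactly 0) holds for a
constant patch.

## Feature selection and classification

Selection is a Welch two-sample t-test screen per feature (keep
p < 0.05; if nothing survives, the smallest p-values are kept so the
selected set is never empty), followed by permutation-importance ranking
from a random-forest surrogate; the top 20 survivors are used. Selection
runs once per classification round on the full table — mirroring a single
published per-round feature set — while standardisation is strictly
per-fold on training patients only.

Eight classifiers: 9-nearest neighbours (Euclidean on standardised
features), decision tree, random forest (100 trees), MLP (one hidden
layer of 64, ≤400 iterations), AdaBoost (50), bagging (10), gradient
boosting (100), and a soft-voting ensemble of the first seven. A
deep-network variant is not included: the classical eight are the
mandatory set, and no deep-learning backend is part of this package's
dependency footprint.

Cross-validation is patient-grouped: leave-one-patient-out, or a
seed-shuffled partition of patients into k near-equal folds. The plan
constructor enforces that no patient appears on both sides of any split.
Folds whose training side lacks a class are skipped with a warning. Out-
of-fold scores are pooled; the operating cutoff is the crossing point of
the positive and negative score distributions (minimise |FP − FN|, ties
by FP + FN then the lower threshold). AUC is the trapezoidal ROC area
(equal to the Mann–Whitney probability with ties counted half). Variants
are compared with a single pre-specified two-sided Fisher exact test on
correct/incorrect counts.

Round 2 (benign vs suspicious) consumes the ground-truth true
microcalcifications by default, so its denominators equal the annotated
counts; a flag restricts it to round-1 survivors at the best round-1
classifier's cutoff.

## The synthetic phantom

Defaults define the desk-scale study conditions: 512×416 frames (1/8 of a
4096×3328 full-field digital mammogram), half-elliptical breast against a
dark (0.02) background, smooth multi-scale blob texture (Gaussian-filtered
noise at σ = 4/8/16/32, mapped to ≈[0.15, 0.55]) standing in for
fibroglandular tissue.

* **Old benign spots** (default 6): soft-edged discs, radius 2–4 px,
  contrast 0.30–0.35, present in both rounds, scattered with ≥80 px
  spacing (2× the suspicious-cluster radius; wider spacings do not fit the
  frame).
* **New spots**, recent round only: benign (2) as above; suspicious (5)
  at 0.6× radius with randomly perturbed-ellipse outlines (random axis
  ratio 0.45–0.8 plus radial harmonics), clustered inside a disc of
  radius 10× the maximum benign radius — encoding the
  morphology/distribution cues without claiming clinical realism.
* **Static clutter** (default 40 specks, radius 0.8–1.6 px, contrast
  0.08–0.35, both rounds): stands in for the microcalcification-mimicking
  fine structure that makes single-image detection false-positive-prone.
  Its contrast range deliberately overlaps the true spots' — in real data
  mimickers are not separable by brightness; what distinguishes them is
  temporal persistence, which is exactly what subtraction exploits.
* **Inter-round change**: the prior is the recent image minus the new
  findings, pushed through the numerical inverse (fixed-point iteration)
  of a smooth random field (Gaussian-filtered noise, σ = 16 px, peak
  normalised to 6 px), then given a ±2% linear multiplicative drift and
  1% additive Gaussian noise (independent noise also on the recent
  image). Rendering through the inverse makes the pair exactly consistent
  with the stored true field, so registration can be scored against it;
  with deformation, noise and drift all zero the prior equals the recent
  image minus exactly the new spots, which several tests rely on.

Everything is reproducible from the spec's seed.

**What the phantom does not emulate.** Breast-density classes, pectoral
muscle, curvilinear fibres and ducts, vendor LUTs, quantum noise
statistics, and — importantly — feature-level realism of the mimicking
clutter: the clutter specks are morphologically simple, so a classifier
separates them from true spots more easily than in clinical data. In the
phantom studies the recent-only arm can therefore reach *higher*
classification accuracy than the subtracted arm even though it needs an
order of magnitude more false-positive candidates at equal detection
sensitivity; the detection-stage advantage is the phantom-level claim
this package can support, while the classification-stage advantage
requires clinical pairs. Passing tests demonstrate pipeline correctness
and the temporal-subtraction mechanism, not clinical performance.

## Problem sizes

The shipped studies use 512×416 phantoms, 10 seeds for the imaging
pipeline, 40-patient cohorts (3–6 samples each) for the classifier
harness, 20 seeds for the chance-level check, and grids of 8 thresholds —
sizes chosen so the whole suite and the reproduction script each run in
minutes on a single CPU while keeping every statistic stable across
seeds.

## Known limitations

* The Demons endpoint-error reduction plateaus at ≈71% under the default
  noise/drift conditions (≈81% noise-free); independent implementations
  do no better, so residual sub-pixel error should be expected on real
  pairs as well.
* Feature selection on the full table before cross-validation introduces
  a mild optimism in round-level accuracies (patient-grouped CV still
  prevents sample-level leakage); per-fold selection would be the
  stricter design at ~20× the cost.
* The full-resolution (4096×3328) path is untested against clinical data
  in this repository; detection defaults scale linearly with image width,
  which is a heuristic.
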