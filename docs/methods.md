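# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `dermao`. Every empirical number quoted here
is computed by the test suite or by `scripts/acceptance.py`.

## The Aquila Optimizer

`dermao.ao` implements the population-based Aquila Optimizer for
box-constrained minimization. Four position-update strategies model the
eagle's hunting repertoire (high soar, contour flight, low flight,
walk-and-grab); the README lists the update equations. Design points:

- **Phase switch.** Iterations `t = 1..T`; exploration strategies are
  used while `t ≤ 2T/3` (inclusive), exploitation afterwards. Within a
  phase the expanded/narrowed variant is a fair coin per candidate per
  iteration. Starting at `t = 1` keeps the quality function
  `QF(t) = t^((2·rand−1)/(1−T)²)` defined everywhere (`0` raised to a
  negative power is not).
- **Lévy flights.** Mantegna construction: `step = s·u/|v|^(1/β)` with
  `u ~ N(0, σ²)`, `v ~ N(0, 1)` per dimension and
  `σ(β) = [Γ(1+β)·sin(πβ/2) / (Γ((1+β)/2)·β·2^((β−1)/2))]^(1/β)`.
  Defaults `β = 1.5`, `s = 0.01` (the conventional choices); both are
  config knobs. `σ(1) = 1` and `σ(2) = 0` analytically, which the tests
  assert.
- **Stochastic companion `X_R`.** The narrowed-exploration update
  perturbs around a randomly drawn *population member*, which
  recombines population structure rather than restarting from a fresh
  uniform point.
- **Spiral base radius.** `r₃` is drawn uniformly from the integers
  `1..20` once per update; the angular rate is `ω = 0.005`.
- **Exploitation coefficients.** `α = δ = 0.1`, the upper end of their
  nominal `(0, 0.1]` range; configurable.
- **Greedy acceptance.** A proposal replaces its candidate only when
  the objective improves, which guarantees the non-increasing
  best-fitness history that the tests assert per iteration. Proposals
  are clipped to the box (clipping, not reflection, so the boundary
  behavior is a stated contract). Non-finite objective values reject
  the proposal with a warning.
- **Determinism.** One `numpy.random.Generator` threads through every
  draw; a fixed seed reproduces runs bit-for-bit. The broadcast scalar
  in the bare `− rand` term of expanded exploitation, and the scalar
  (not per-dimension) `rand` multiplying the spiral offsets, are
  deliberate, documented readings of ambiguous conventions; both are
  pinned by unit tests.

On the 5-dimensional sphere benchmark (box `[−10, 10]^5`, `N = 30`,
`T = 500`) the optimizer reaches ~1e−9, far below the 1e−2 bar the
acceptance suite sets.

## Wrapper feature selection

A feature subset is a binary mask over `D` columns (1 = selected, so
the mask's popcount is the subset size that the objective penalizes).
The optimizer works on the continuous relaxation `[0, 1]^D`:

- **Bridge.** Static threshold 0.5; an all-zero binarization is rescued
  by forcing the largest component (lowest index on ties), because the
  objective is undefined for empty subsets.
- **Objective.** `F = μ·E + (1 − μ)·|mask|/D` with `μ = 0.99`. `E` is
  the stratified k-fold (default 5) misclassification rate of
  5-nearest-neighbours on the selected columns. Folds are frozen per
  run from the seed, making `F` a pure function of the mask; results
  are memoized by mask bits, and tests verify that caching never
  changes the returned selection.
- **Reporting.** `SelectionResult` carries the mask, its fitness and CV
  error, and the reduction percentage
  `100·(before − after)/before`, rounded half-up to two decimals
  (1024→256 = 75.00%, 1024→300 = 70.70%).

## Deep-feature extractor

`dermao.features.SmallCNN` is a compact, self-contained convnet in
numpy: 3×3 same-padding convolutions (im2col), optional per-channel
batch normalization, ReLU, 2×2 max-pooling per block, global average
pooling, a dense penultimate layer whose activations are the extracted
features, and a 2-way softmax head. Training minimizes cross-entropy
with Adam (default, `lr = 1e−3`) or momentum SGD; a stratified 20%
holdout supplies the per-epoch validation-loss trace. Backpropagation
is verified against numeric directional derivatives in the tests, and
inference is deterministic.

Defaults mirror a production-scale extractor in shape (three conv
blocks of 16/32/64 filters, 1024-wide penultimate layer, 224×224
input); the tests and acceptance runs use reduced sizes (32×32 input,
8/16/32 filters, 64-wide features) so the full pipeline trains in
seconds on one CPU. Those sizes are this package's desk-scale choices;
any external backbone can be substituted upstream by supplying its
feature table as CSV.

Preprocessing resizes to the target resolution and normalizes to
`[0, 1]` (exact `pixel/255` when no resize is needed) or to per-channel
z-scores. Augmentation applies a seeded rotation/scale-jitter/flip
chain; identity parameters return the input unchanged and flips are
exact involutions.

## Synthetic data

Two generators make every stage testable with known ground truth.

**Feature tables.** Benign rows are `N(0, σ²)` in all columns;
malignant rows add a shift of `effect_size · σ` in `k` informative
columns drawn without replacement, so `effect_size` is exactly Cohen's
d per informative feature. Defaults (400 samples, 50 features, 8
informative, d = 1.5, balanced classes) define the standard recovery
fixture. Under a zero effect the generator is calibrated: pooled over
200 seeds, ≥95% of per-column t statistics stay below the α = 0.01
critical value, and single-feature AUC averages 0.5 ± 0.05.

**Lesion images.** A filled ellipse with a sinusoidal radial
perturbation, composited on a textured skin background, with a binary
ground-truth mask. Malignant lesions receive extra eccentricity
(`asymmetry_delta = 0.25`), border perturbation (relative amplitude
0.12 from three random harmonics), and a darker color shift
(−0.10, −0.08, −0.02 RGB); Gaussian blur (σ = 1 px) and 1% speckle
emulate acquisition artifacts. These defaults are a deliberately
legible cartoon of the ABCD dermoscopy criteria (asymmetry, border,
color, diameter): strong enough that a small convnet separates the
classes, weak enough that untrained pixels do not trivially do so.
With perturbation, blur and speckle off, the benign mask is an exact
rasterized ellipse (area within 1% of πab), which anchors the geometry
tests. The generator does **not** emulate hair, rulers, gel bubbles,
varied illumination, or the full diversity of real dermoscopy; passing
tests demonstrate the pipeline's mechanics and internal consistency,
not clinical performance.

## Pipeline and ablation

`run_pipeline` executes simulate → (train/extract | load) → select →
classify (5-NN on the selected columns) → evaluate on a stratified
held-out split (default 25%). `run_ablation` evaluates the identical
split twice — all features vs the selected subset — so metric deltas
are attributable to selection alone; the split hash is embedded in the
report. Reports (metrics/confusion/selection JSON, ROC CSV, config
snapshot with content hash, plain-text summary) are byte-identical
across reruns of the same config and seed. Replicate runs over a seed
list report per-seed metrics; mean ± sd across seeds is the package's
descriptive variability measure.

## Problem sizes

Test and acceptance runs use: sphere `N = 30, T = 500`; selection
budgets of `N = 12..20` populations and `T = 20..120` iterations;
recovery fixtures of 400×50; the exhaustive-oracle fixture 150×10 with
two informative columns at d = 1.0 (moderate class overlap keeps the
optimal fitness error-dominated, ≈0.2, so a relative fitness comparison
is meaningful — with near-separable classes the optimum collapses to
the size penalty and any relative tolerance degenerates into requiring
the exact mask); ablation tables of 300×100 with 8 informative; and
end-to-end runs of 100 images per class at 64×64 generated, 32×32
trained. These sizes are the package's single-CPU defaults.

## Known limitations

Two limits of threshold-bridged AO selection are measured and
documented by the acceptance suite (the corresponding assertions fail,
deliberately, at the strict bars they state):

1. **Coverage of mask space.** On the thresholded unit box several
   update terms exceed the box width by an order of magnitude (spiral
   offsets scale with `r₃ ≤ 20`; expanded exploitation subtracts a
   uniform scalar from positions in `[0, 1]`), so after clipping many
   proposals saturate at the box corners. At `D = 10` the search
   visits only ~200 of the 1023 possible masks no matter how long it
   runs. Against exhaustive enumeration — whose minimum is an extreme
   order statistic over all 1023 fold-coupled error estimates — the
   optimizer's best fitness lands a median ≈9–14% (relative) above the
   enumeration optimum, short of the 5% bar.

2. **Recovery vs the objective's own optimum.** At the standard
   recovery fixture (d = 1.5, 8 of 50 informative, n = 400) the
   k-NN error is nearly flat in 0–20 extra noise columns, while the
   parsimony pressure is only `(1 − μ)/D = 2×10⁻⁴` per column — an
   order of magnitude below the fitness change from a single CV
   misclassification. An independent simulated-annealing probe of the
   same objective converges to masks of 20–28 features with
   Jaccard ≈ 0.3 against the planted set — *better fitness, worse
   recovery* than the planted mask itself. Median Jaccard ≥ 0.5 is
   therefore not a property of optimizing this objective at these
   conditions (nor at μ = 0.9, nor with repeated CV); the suite keeps
   the strict assertion as documentation. Recovery of decisive
   features is reliable: a label-identical column is selected in
   ~100% of runs, and the with/without-selection ablation improves
   median accuracy while always using fewer features.

Other limitations: binary classification only (a three-class mode is a
config option, not a tested path); no lesion segmentation (masks are
generator ground truth only); box constraints only in the optimizer;
the convnet is CPU-oriented and desk-scale, not a production backbone.
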