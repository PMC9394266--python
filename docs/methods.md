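# Methods

## Model

The classifier is a fully connected feed-forward network with one hidden
layer: `n_input` inputs (derived from the encoded design matrix, never
configured by hand), 30 hidden units with ReLU activation, and a single
sigmoid output interpreted as the probability of the positive class
(disease present). All weights and biases are packed into one flat real
vector in a fixed order — input→hidden weights row-major, hidden biases,
hidden→output weights, output biases — so that `decode(encode(·)) `is an
exact bijection. For the Cleveland schema under one-hot encoding the
design matrix has 25 columns (5 continuous + 3 binary passthrough + 17
one-hot indicator columns from cp/restecg/slope/ca/thal), giving
25·30 + 30 + 30·1 + 1 = 811 parameters. Under integer encoding the
design is 13 columns (421 parameters).

Training minimizes the mean squared error between the 0/1 labels and the
output probabilities over the training rows. MSE of probabilities (not
thresholded labels) keeps the objective smooth in the parameters and
bounded in [0, 1]. Classification uses threshold 0.5 with ties going to
the positive class; the same `score ≥ t` rule drives the ROC sweep so
curve and classifier agree at every threshold.

## Optimizer

Global-best (star topology) PSO. Defaults: swarm size 100, 50
iterations, inertia `w = 0.9`, cognitive `c1 = 0.5`, social `c2 = 0.3`,
stopping when the global best fitness reaches `error_limit` (default
1e-3, configurable; with the MSE objective this corresponds to
essentially perfect training predictions). Initial positions are uniform
in (−1, 1) per dimension and initial velocities uniform in (−0.1, 0.1);
both ranges are configurable. No velocity clamp or position bounds by
default — network weights are genuinely unbounded — though an optional
symmetric clamp is exposed.

Two readings of the stochastic coefficients are supported, because the
conventional description of the update rule makes `r1, r2` random on
[0, 1) while fixed values `r1 = 0.4`, `r2 = 0.5` are also in circulation
for this configuration. `r_mode="random"` (default) draws both fresh per
dimension, per particle, per update — coarser draw granularity biases
search along the diagonal of the space — and `r_mode="fixed"` uses the
constants, making an entire run a deterministic function of the
initialization seed. One RNG stream per run, seeded explicitly, consumed
in a documented order (positions, then velocities, then per-iteration
r-draws in particle order), so results are bit-reproducible across
processes.

Within an iteration particles update in index order: velocity, position,
evaluation, personal best, then the global best immediately (an
asynchronous update — later particles in the same sweep see the improved
global best). The stopping test checks the global best, and a non-finite
fitness during search is treated as +∞ (it can never become a best);
non-finite fitness at initialization is an error instead, since it
usually means a broken objective.

## Preprocessing

Order: mean imputation → categorical encoding → (optional split) →
feature scaling. Every statistic is fitted on a caller-chosen row set and
reused verbatim elsewhere; the cross-validation harness hands the
training folds only, so no held-out information leaks into imputation
means or scaling parameters. Imputed categorical cells carry a fractional
column mean; the one-hot encoder snaps these to the nearest admissible
level (a genuine integer code outside the schema is still an error).

Standardization uses the population SD (divide by n); the `ddof`
parameter switches to sample SD. Min–max scaling maps the fitted min/max
to 0/1. One-hot and binary columns are exempt from scaling by default so
indicators stay 0/1; `scale_all` overrides. Zero-variance columns raise
an error in strict mode and pass through unscaled in lenient mode (the
trainer uses lenient, since a constant synthetic column should not abort
a fit).

Splits: `train_test_split` takes round(n·fraction) training rows,
stratified by default (the minority class is small enough to protect);
k-fold CV shuffles once with the given seed and deals folds of size
⌊n/k⌋ or ⌈n/k⌉, each fold testing exactly once. Fold metrics are
averaged unweighted, as fold sizes differ by at most one.

Degenerate-metric conventions: precision with no predicted positives is
0 (with a warning); recall with no actual positives is an error — an
evaluation set without positives cannot assess a disease classifier; F1
is 0 when precision + recall = 0.

## Synthetic data generator

The generator emulates the *shape* of the Cleveland table, not its joint
distribution: continuous features are class-conditional Gaussians with
base means/SDs loosely matched to the real ranges (age 54±9, restbp
131±17, chol 246±52, thalach 150±23, oldpeak 1.0±1.1; thalach shifts
down with disease, the others up), and discrete features draw from base
level probabilities tilted in log-odds along a centered level-risk score.
A single `effect_size` knob controls both: each continuous feature's
class means differ by `effect_size` within-class SDs (split ±half around
the base mean) and discrete logits are tilted by ±`effect_size`/2.
Defaults are the study conditions: 303 rows, prevalence 0.46
(near-balanced, matching the real class ratio), `effect_size` 1.0
(difficulty comparable to the real task), and missing rate 0.01 applied
MCAR to `ca` and `thal` only — the two columns that actually contain
nulls in the real file (≈6 cells out of 606). `oldpeak` is clipped at 0,
which slightly distorts its lower tail.

What passing tests on this generator do **not** show: the real data's
correlation structure between features, non-Gaussian marginals, and
informative missingness are all absent, so pipeline correctness and
learnability are demonstrated, but real-data performance numbers are not.

## Problem sizes and empirical behaviour

The shipped benchmarks use deliberately small problems — sphere in 5
dimensions (swarm 50, 200 iterations), XOR with a 2-4-1 network (swarm
100, ≤100 iterations), and 300-row synthetic tables under 5-fold CV with
the default 100×50 swarm — chosen so the full suite and the acceptance
script each run in seconds while still exercising the 811-dimensional
Cleveland-scale search space in the CV benchmarks.

On XOR, roughly one seed in ten converges to the well-known local
optimum of the 2-4-1 MSE surface (training MSE 0.125, outputs
[0.5, 1, 0.5, 0]) within the 100-iteration budget; an independent
synchronous-update PSO transcription shows the same rate at identical
settings, so this is a property of the landscape and budget, not of the
implementation. The remaining seeds reach MSE < 1e-3 in 10–25
iterations.

## Serialization

Models serialize to a single self-describing JSON document (schema,
topology, flat parameter vector, imputation means, encoder mode, scaler
statistics, training history, optimizer configuration). Floats use
Python's shortest round-trip repr, so save → load → save is
byte-identical and loaded models predict bit-for-bit identically.
Malformed or version-mismatched files fail loudly with no partial model.

## Known limitations

* Single hidden layer only; no backpropagation trainer in the core (the
  optional `benchmark` CLI command delegates a BP-trained MLP and nine
  other baselines to scikit-learn for comparison).
* Star topology only; no inertia schedules, constriction factor, or
  neighborhood variants.
* The generator's MCAR missingness and independent features understate
  real-data difficulty at a given `effect_size`.
* AUC is computed by trapezoid over the empirical ROC; for heavy ties it
  equals the pairwise concordance estimator, but confidence intervals
  are out of scope.
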