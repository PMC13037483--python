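# Methods

This note documents the models implemented in `qsrr`, the defaults they
ship with, what the synthetic benchmark does and does not emulate, and the
numerical choices that make the pipeline deterministic.

## Problem setting

A QSRR model regresses gas-chromatographic retention time (RT, minutes) on
molecular descriptors. The packaged calibration set contains 75 basic
narcotic/hazardous drugs measured on a non-polar HP-5 column, with RT
spanning 0.96–2.16 min and a fixed 60/15 train/test partition. Descriptor
pools computed by cheminformatics software are typically wide (hundreds to
thousands of columns) and strongly collinear, while only a handful of
descriptors carry retention-relevant signal — hence the pipeline order:
pre-treatment → wrapper selection → regression → validation.

## Descriptor pre-treatment

Three filters run in sequence, then autoscaling:

1. **Constant columns** — zero range (max − min = 0) over all rows. The
   range is used rather than a variance threshold so a column of repeated
   identical values is recognized exactly regardless of floating-point
   accumulation in the mean.
2. **Near-constant columns** — modal value frequency ≥ 95%
   (`near_constant_fraction = 0.95`). "Near-constant" has no universal
   definition; the modal-frequency rule is a common chemometrics
   convention and is exactly testable.
3. **Correlated pairs** — scanning pairs in column order, whenever
   |Pearson r| > 0.90 (`r_threshold`) one member is dropped. The survivor
   is the column with the larger |correlation to the response|
   (`response_aware=True`; falls back to keeping the earlier column).
   Keeping the more predictive member preserves signal while making the
   outcome deterministic.

When the table carries partition labels, all correlations (pair and
response) are computed on training rows only, so held-out compounds never
influence the filter. The filter is idempotent: a second pass removes
nothing.

Autoscaling is the usual z-score with training-row mean and sd (n−1
denominator, stated so tests can assert exact values); held-out rows are
always transformed with training statistics. Zero-sd columns raise an
error directing the user to pre-treat first.

## Genetic-algorithm descriptor selection

Chromosomes are binary inclusion masks over the K pretreated descriptors.
Defaults: population 30, single-point crossover with probability 0.5,
per-gene mutation rate 0.01, at most 1000 generations, early stop when the
best fitness improves by less than 0.001 for 100 consecutive generations,
and 20 independent runs aggregated into per-descriptor selection
frequencies.

Fitness unifies "maximize Q²" and "minimize RMSECV" (monotone transforms
of each other under fixed folds) as

    fitness(mask) = Q²_cv − α · k/K,      α = 0.05 by default,

where Q²_cv = 1 − PRESS/TSS from an inner 5-fold CV of the configured
estimator (PLS with 4 latent variables by default, or kernel PLS) on the
masked columns, with per-fold autoscaling. The penalty proportional to the
selected-descriptor fraction favors parsimonious masks. A mask on which
the estimator fails scores −∞ and is culled by selection.

Choices where the design was genuinely open, fixed as follows:

- **Parent selection**: tournament of size 2 — standard and
  parameter-free.
- **Elitism 1**, which makes the per-run best-fitness trace monotone (an
  invariant the test suite asserts).
- **Initial inclusion probability 0.1** per bit: a sparse start mirroring
  the parsimony objective; configurable.
- **Stall rule**: absolute improvement < 0.001, not a significance test.
- **Inner CV**: 5-fold; leave-one-out is available by setting
  `inner_cv = n`.
- The **fold assignment is fixed per run** (seeded from the run seed) so
  fitness values are comparable within a run and can be memoized per mask;
  the consensus step re-evaluates each run-best mask under a fresh fold
  seed to avoid favoring masks tuned to one fold split.

Consensus: selection frequency = fraction of runs whose best mask includes
the descriptor; the final mask is the run-best mask with the highest
re-evaluated CV fitness, ties broken by higher mean member frequency, then
by fewer descriptors.

## PLS and kernel PLS

PLS uses the NIPALS formulation for a single response: weights
w ∝ Xᵀy, scores t = Xw, deflation X ← X − t pᵀ, with regression
coefficients `W(PᵀW)⁻¹q`. Successive scores are mutually orthogonal, and
with full latent rank the fit coincides with ordinary least squares (the
test suite checks this against the normal equations). `n_lv = 0` is
allowed and yields the training-mean model. The default latent-variable
count is 4 for PLS and 3 for kernel PLS; no automatic LV selection is
performed.

Kernel PLS builds the Gram matrix K with the Gaussian kernel
`exp(−d²/(2σ²))` (σ is the width; the σ-vs-2σ² convention is absorbed by
the width search), double-centers it (feature-space centering), extracts
components by the iterative dual algorithm with deflation
`K ← (I − ttᵀ)K(I − ttᵀ)`, and predicts via the dual coefficient vector
`α = U(TᵀKU)⁻¹Tᵀy` with test kernel rows centered by the stored training
row means and grand mean. Component iteration is capped at 500 with a
1e-10 score-change tolerance (it converges in one step for a univariate
response; the cap exists for generality and determinism). With the linear
kernel the predictions coincide with NIPALS PLS — the package's
cross-check that centering and extraction are correct. Whether to center
the kernel at all was an open choice; double-centering is the canonical
formulation and is what the linear-kernel equivalence validates.

σ is chosen by k-fold CV over a grid of multipliers
(0.25, 0.5, 1, 2, 4) of the median pairwise Euclidean distance of the
autoscaled training descriptors, ties toward the smaller σ.

## Levenberg–Marquardt MLP

A single-hidden-layer perceptron d–h–1 with tanh hidden units and a linear
output; a 7–4–1 network has 4·8 + 5 = 37 weights, deliberately small
relative to ~60 training compounds. Inputs and the response are z-scored
with training statistics; weights initialize U(−0.5, 0.5) from a seeded
generator.

Each epoch solves `(JᵀJ + λI)Δw = Jᵀe` on the full training batch with an
analytic Jacobian (validated against central finite differences to 1e-6).
A step is accepted only if the training SSE decreases — accepted steps can
therefore never increase the loss — whereupon λ is multiplied by 0.1;
otherwise λ is multiplied by 10 and the solve retried (up to 30 times;
λ > 1e10 ends training as a converged stall, not an error). The damping
starts at λ₀ = 0.01. (A "learning rate" is sometimes quoted for LM
training; LM has none, so 0.01 is interpreted as the initial damping — the
only self-consistent reading.)

Early stopping: validation RMSE is recorded each epoch; training stops
after 10 epochs without improvement (`patience`) or at `max_epochs = 150`
(hard cap 200, the architecture-scan limit), and the weights at the best
validation RMSE are returned. Hidden-unit counts 2–10 are scanned with a
reduced number of restarts (≥ 3), picking the argmin of median validation
RMSE with ties toward fewer neurons; the final model is trained with 15
independent restarts and the lowest-validation-RMSE network is kept, with
a per-restart mean ± sd table.

Sensitivity analysis perturbs each standardized input multiplicatively by
±5% and ±10% with the others fixed and reports the mean |Δ predicted RT|
(minutes) over rows and model realizations, ranked by the mean across
perturbations. Because perturbations are multiplicative in scaled space, a
standardized value of exactly zero contributes zero change — documented
behavior, not a bug.

The ANN uses a seeded, RT-stratified 70/15/15 train/validation/test split:
rows are sorted by response, cut into consecutive strata of ~7, and
allocated within strata by cumulative (largest-remainder) rounding so the
global 70/15/15 counts are exact while all parts of the RT range appear in
every subset.

## Validation

- Metrics: MSE = SS_res/n, RMSE = √MSE, R² = 1 − SS_res/SS_tot,
  Adj R² = 1 − (1 − R²)(n−1)/(n−p−1) with p = number of input descriptors
  (not latent variables; configurable), SE = sample sd of residuals (n−1),
  Pearson r. Residuals are e = y_exp − y_pred. Adj R² is reported as NaN
  with a warning when n ≤ p + 1; zero response variance is an error.
- Leave-group-out CV: rows are shuffled (seeded) into ⌈n/7⌉ contiguous
  groups (`group_size = 7`, inside the conventional 5–10 range); each
  group is predicted by a model refit — scaler included — on the rest.
  Q² = 1 − PRESS/TSS, RMSECV = √(PRESS/n). Grouping is random only;
  similarity-based grouping would need structures, which the package does
  not handle.
- y-scrambling: permuting the response must collapse Q² to ≤ 0; the test
  suite runs 20 permutations as a chance-correlation guard.

## Synthetic benchmark

`SyntheticSpec` defaults describe the regime the pipeline targets: n = 75
compounds, K = 200 descriptors in equicorrelated blocks of 5 (within-block
r = 0.9 via the shared-factor construction x = √ρ·z_block + √(1−ρ)·ε,
which hits the target correlation exactly in expectation with no
covariance factorization), k_true = 7 informative descriptors placed one
per block (so the |r| > 0.90 filter cannot delete the whole truth set), 3
constant and 3 near-constant nuisance columns appended last, and a
response mapped affinely into 0.9–2.2 min before adding Gaussian noise
with sd 0.03 min (a measurement-repeatability scale chosen by the package;
roughly 2–3% of the RT span). Surfaces: linear (y = Xβ) or nonlinear
(Σβ_j tanh(x_j) plus one pairwise interaction among true columns).

What the generator does *not* emulate: real descriptor distributions
(counts, heavy tails, block structure tied to descriptor families),
descriptor-descriptor correlations across blocks, or chromatographic
physics. Passing the recovery tests therefore shows the machinery is
correct under the assumed statistical structure — not that any particular
descriptor set predicts RT for new chemistry.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from one master seed by hashing (BLAKE2b of
`master:stage:index`, reduced below 2³¹), so independent stages have
independent streams and whole runs are bit-reproducible (the manifest
records artifact checksums to prove it). Tests and the acceptance script
run scaled-down experiments chosen to exercise every code path at
desk-scale: GA recovery at K = 50 / 20 runs × 100 generations, exhaustive
GA verification at K = 10, ANN stability at 5–15 restarts. These sizes are
the package's own benchmark choices.

## Known limitations

- The 75-compound table ships with only three physicochemical columns
  (MW, XlogP3, HBD); a full descriptor matrix must be supplied by the user
  as CSV, so the packaged data alone cannot reproduce a full
  descriptor-selection study on real drugs.
- SE is defined as the sample sd of residuals. Published QSRR tables
  sometimes report SE values that no residual-based definition reproduces
  (e.g. test SE exceeding test RMSE); such values are not comparable with
  this implementation's SE.
- Only the Gaussian and linear kernels are implemented; no polynomial or
  sigmoid kernels, no multi-layer ANN topologies, no Bayesian
  hyperparameter search.
- The applicability domain is not modeled; predictions for chemistry
  unlike the calibration set should be treated with caution.
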