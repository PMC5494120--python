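# Methods

`admorph` implements a staged-diagnosis classification pipeline for
morphometric feature tables: subjects carry regional grey-matter volume
features (mm³) and a diagnostic label in the ordered set NC → MCI → AD
(normal control, mild cognitive impairment, Alzheimer's disease). The
pipeline is PCA feature selection → classifier → stratified
cross-validation with permutation-test significance. This note documents
the models, their assumptions, the tunable parameters, and the numerical
and design choices a maintainer should know about.

## Synthetic cohorts

Real staged-dementia cohorts cannot ship with the package, so the
generator in `admorph.synthetic` emulates the statistical structure such
studies assume. A cohort is drawn as

    x_ij = baseline_mean − stage_i · effect · noise_sd · 1[j affected] + ε_ij

with `stage` ∈ {0 (NC), 1 (MCI), 2 (AD)} and Gaussian noise `ε` of SD
`noise_sd`, optionally equicorrelated across features with coefficient ρ
(implemented as a shared factor for ρ > 0, a Cholesky factor of the
equicorrelation matrix otherwise). Defaults encode the target study
conditions: 70/74/70 subjects, 54 features, and a monotone volume
reduction NC > MCI > AD in the affected features.

Parameters and defaults:

| parameter       | default    | meaning                                             |
|-----------------|------------|-----------------------------------------------------|
| `n_per_class`   | (70,74,70) | subjects per stage                                  |
| `n_features`    | 54         | volume features (ROIs)                              |
| `n_affected`    | 12         | stage-sensitive features (first columns)            |
| `effect`        | 1.0        | atrophy step per stage, in within-class SD units    |
| `noise_sd`      | 500 mm³    | within-class SD (≈10 % coefficient of variation)    |
| `baseline_mean` | 5000 mm³   | stage-0 mean volume (mid-sized ROI)                 |
| `correlation`   | 0.0        | equicorrelation ρ across features                   |

`n_affected = 12`, `noise_sd`, and `baseline_mean` are the package's own
choices of a realistic regime (roughly a fifth of regions affected, 10 %
between-subject variation): no empirical effect sizes are available to
calibrate against, so they are fixed once and documented rather than
tuned. The generator is a pure function of its spec, including the seed.

What the generator does **not** emulate: measurement error of the
segmentation pipeline, site/scanner batch effects, age and sex
covariates, non-Gaussian tails, heterogeneous per-feature variances, and
longitudinal change. Passing tests therefore demonstrate correctness of
the algorithms and protocol under a clean Gaussian staging model, not
expected accuracy on clinical data.

## PCA feature selection

Features are centered, by default scaled to unit variance (regional
volumes span orders of magnitude), and projected onto the top-k right
singular directions. Component signs are fixed by making the
largest-magnitude loading positive, so results are identical across
linear-algebra backends. The component count is either fixed (default
k = 10) or grid-searched over {2, 4, …, 20} by inner stratified CV, with
the PCA refit inside every inner training fold; ties break toward the
smaller k. During outer CV the PCA is always fit on the training fold
only — test rows are never visible to `fit_pca`.

## Kernel logistic regression and the import vector machine

KLR places a softmax over kernel evaluations k(x, r_m) against reference
points r_m, minimizing the convex objective

    Q(w) = −Σ_i log P(y_i | x_i; w) + (λ/2) Σ_c w_cᵀ K_rr w_c

with the Gram matrix as penalty (the RKHS norm; an identity penalty is
selectable), the bias unpenalized, and the last class's weight column
pinned to zero for identifiability (the binary case then reduces to a
sigmoid of a single score). Optimization is damped Newton–Raphson with
backtracking line search — monotone in Q and convergent to gradient
tolerance `tol` (default 1e−6); non-convergence raises an error carrying
the final gradient norm. A tiny spectral jitter (1e−10 relative) keeps
the Hessian solvable when λ = 0 or the Gram matrix is near-singular.

The IVM sparsifies KLR greedily: starting from a bias-only model it adds,
at each step, the training point whose inclusion minimizes Q, and stops
when the relative decrease |Q_t − Q_{t−Δt}|/|Q_t| falls below ε (defaults
ε = 1e−3, Δt = 1), when every point is included, or at `max_import`.
Candidate evaluation uses warm-started bounded Newton updates; exact
per-candidate refits are available behind `exact_greedy` for oracle
tests, and a seeded random candidate subsample (a standard large-n
speedup) can bound the per-step cost without changing any stopping rule.
Because each accepted step refits from a feasible warm start with a
monotone line search, the objective trace is non-increasing.

Classifier-adapter defaults: RBF width γ = 1/(d · Var(X)) (scale
adaptive), λ = 1e−2 fixed, `max_import` = 30, candidate subsample 50 with
one warm Newton update per candidate. λ can instead be selected by inner
3-fold CV via `lambda_grid`; this is off by default because the greedy
fit is the most expensive stage of the pipeline and the fixed value is
adequate across the synthetic regimes exercised here.

## ELM, RELM, and the sparse-representation fallback

The extreme learning machine draws hidden weights and biases i.i.d.
Uniform(−1, 1) from a seed and never trains them; output weights are
closed-form. Plain ELM uses the minimum-norm least-squares solution
β = H⁺T on one-hot targets; the regularized ELM solves the ridge system
β = (I/C + HᵀH)⁻¹HᵀT via a symmetric positive-definite factorization
(contract-identical to the explicit inverse, numerically safer). C → ∞
recovers plain ELM on full-column-rank H; C → 0 shrinks β to zero.

Adapter defaults: hidden width L = 1000 capped at 10·n_train, ridge
C = 1, training-fold standardization of inputs (so Uniform(−1,1) weights
operate on O(1) activations regardless of feature units). The default
activation is **relu**: with sigmoid or tanh features the one-hot
least-squares output layer exhibits the classic middle-class masking of
three collinear class means (the MCI stage is systematically swallowed
by its neighbours, costing ~15 accuracy points on strongly separated
cohorts), while piecewise-linear random features break the masking.
Sigmoid and tanh remain selectable.

The hybrid predictor addresses test samples the ELM is unsure about. A
rule of the form "use the ELM when the test point is correctly
classified" is not operational at test time (labels are unknown), so the
gate is a reliability score: the margin between the top two output
scores. Rows with margin ≥ `threshold` keep the ELM label; the rest are
re-classified by sparse representation over the retained training
dictionary — the sample is greedily sparse-coded (orthogonal matching
pursuit, ≤ `n_nonzero` = 10 atoms) on the ℓ2-normalized training rows,
and assigned to the class whose atoms' partial reconstruction leaves the
smallest ℓ2 residual. `threshold` = 0 reproduces pure ELM/RELM exactly
and is the default; the registered `relm-hybrid` spec uses 0.2 on the
one-hot score scale. The gate-plus-pursuit construction is a documented
interpretation: reliability measures and sparse solvers vary across the
sparse-representation classification literature, and this package fixes
one deterministic choice.

## SVM baseline

The maximum-margin baseline delegates to scikit-learn's SVC (linear or
RBF kernel, default C = 1, γ = 'scale'), wrapped one-versus-all for
multiclass and preceded by training-fold standardization — the solver's
convergence deteriorates badly on raw mm³-scale features, and the affine
rescaling leaves the decision contract intact.

## Evaluation protocol

Metrics follow the binary definitions ACC = (TP+TN)/total,
SEN = TP/(TP+FN), SPE = TN/(TN+FP), with the first class of the declared
order as positive; zero-denominator ratios are NaN with a warning.
Multiclass matrices are reduced one-versus-all and macro-averaged
(unweighted; NaN-aware), with accuracy = trace/total.

Three stratified protocols: repeated 70/30 splits (default 100 repeats),
10-fold CV (default 10 repeats), and leave-one-out (repetition re-seeds
stochastic classifiers; for LOO the NaN-aware per-fold mean of
sensitivity equals the pooled sensitivity, so aggregates stay
meaningful). Everything fit — standardization, PCA, component count,
classifier — sees only the training fold. All seeds fan out from one
master seed through `SeedSequence` spawn keys; the whole pipeline is a
pure function of (config, seed) and reports are byte-reproducible.

A historical note on the 70/30 protocol: the source experimental setup
describes a "70/30" split whose train/test counts (111 + 30 out of 141,
with 140 subjects in the two classes) are mutually inconsistent; this
package implements exact proportional stratified 70/30 splits instead.

The permutation test re-runs the identical CV protocol on label-permuted
cohorts and reports the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + B), which is never exactly zero and
is invariant to monotone rescaling of the accuracy statistic.

## Verification problem sizes

The acceptance checks (`tests/test_acceptance.py`,
`scripts/acceptance.py`) use these problem sizes, chosen as the smallest
scales at which each property is meaningfully exercised:

- solver-vs-oracle comparisons: 20 random KLR instances (n ≤ 30, d ≤ 5,
  K ≤ 3), 50 random ELM/RELM systems, 20 six-point greedy-selection toys;
- effect recovery: 20 seeded cohorts at the full study size (214 × 54),
  one stratified 70/30 split each, PCA k = 10, all six classifiers, at
  effect = 3 (every classifier ≥ 90 %) and effect = 0 (within ±7 points
  of the 33.3 % chance level);
- permutation calibration: 50 runs × 200 permutations on 60-subject null
  cohorts under the repeated-split protocol (2 repeats), linear SVM
  without PCA, Kolmogorov–Smirnov uniformity at α = 0.01.

## Known limitations

- The Gaussian equicorrelated generator is deliberately simple; none of
  the robustness claims extend to heavy-tailed or batch-confounded data.
- Greedy IVM candidate scoring with bounded warm Newton updates can, in
  principle, pick a different point than exact refitting would; the exact
  mode exists and the oracle tests pin the exact path.
- The sparse fallback uses greedy pursuit, not ℓ1 minimization; on highly
  coherent dictionaries the two can disagree.
- LOO per-fold sensitivity/specificity are individually degenerate
  (single-subject folds); only their NaN-aware aggregates are
  interpretable.
- `missing="impute-mean"` imputes with whole-file column means at load
  time; for strictly leak-free evaluation, impute within training folds
  upstream or reject missing data (the default).
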