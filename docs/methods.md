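# Methods

## Scope and notation

`pensvm` fits linear classifiers f(x) = w·x + b on binary labels y ∈ {−1, +1}
by minimizing

    A(b, w) = (1/n) Σᵢ [1 − yᵢ f(xᵢ)]₊ + pen(w).

The hinge-loss term is divided by n so that one λ range is comparable across
sample sizes; the intercept b is never penalized. The plain soft-margin SVM is
kept in its primal cost form ½‖w‖² + C Σᵢ ξᵢ (the two forms coincide up to the
reparameterization λ₂ ↔ 1/(2nC) of the ridge weight); it serves as the
no-selection reference and as the start point of the iterative solvers.

Predicted labels are sign(f(x)) with the tie sign(0) := +1, so predictions are
deterministic. Labels of any two-level input coding are mapped to −1/+1 by
sorted level order (first level → −1) and the mapping is recorded. Features
are not rescaled by default — none of these penalties is scale invariant, so
rescaling changes the estimator; an explicit `standardize` helper is provided
for callers whose features live on incomparable scales.

## Penalties

* ridge: λ₂‖w‖₂² (cost form C in the plain SVM) — shrinks, never selects.
* lasso: λ₁‖w‖₁ — selects, but at most n+1 nonzero parameters and typically
  one feature per correlated group.
* SCAD(|w|; λ₁, a): quadratic spline with knots λ₁ and aλ₁ — identical to L1
  below the first knot, constant (a+1)λ₁²/2 above the second, so large
  coefficients are not biased downward. The shape parameter defaults to
  a = 3.7, the standard choice to which the fit is insensitive.
* elastic net: λ₁‖w‖₁ + λ₂‖w‖₂² — selection beyond the n bound plus the
  grouping effect (correlated features enter together).
* elastic SCAD: SCAD + λ₂‖w‖₂² — SCAD's sparsity with ridge's tolerance of
  non-sparse signal. With λ₂ = 0 it is definitionally SCAD, and the code paths
  coincide exactly (likewise elastic net at λ₂ = 0 is exactly the L1 program).

## Solvers

**L2 (ridge).** Solved in the dual by libsvm (through scikit-learn's `SVC`
with a linear kernel, tolerance 10⁻⁶). The Lagrange multipliers, support set
and the reconstruction w = Σ_{i∈S} αᵢ yᵢ xᵢ are exposed in the fit metadata.

**L1.** The objective is piecewise linear, so the minimization is written as
an exact linear program (split coefficients w = u − v, free intercept, hinge
slacks) and solved by HiGHS. Coefficients below the removal threshold 10⁻⁴
are zeroed afterwards.

**SCAD / elastic SCAD (and elastic net) — local quadratic approximation.**
Starting from the L2 SVM solution at C = 1 (an override is available), each
iteration majorizes both terms of A at the current iterate (b₀, w₀):

* hinge: [m]₊ = (|m| + m)/2 with m = 1 − y f(x); |m| ≤ m²/(2c) + c/2 for any
  c > 0, with equality at c = |m|. Sample i therefore contributes
  sᵢ(1 − yᵢf)² + (1 − yᵢf)/2 + const with weight sᵢ = 1/(4·max(|m₀ᵢ|, δ_h)).
  This majorant is global and matches the hinge's value and gradient at the
  expansion point wherever |m₀ᵢ| > δ_h.
* penalty: pen(|wⱼ|) ≤ pen(|w₀ⱼ|) + qⱼ(wⱼ² − w₀ⱼ²) with
  qⱼ = pen′(|w₀ⱼ|)/(2·max(|w₀ⱼ|, δ_p)) + λ₂, the standard quadratic majorant
  of a penalty concave in w² (SCAD and L1 both are).

Minimizing the resulting quadratic is one weighted least-squares solve over
(b, w_active): with X̃ = [1, X_active], W = diag(sᵢ) and P = diag(0, qⱼ),

    (X̃ᵀWX̃ + nP) c = X̃ᵀWz,    zᵢ = yᵢ(1 + 1/(4sᵢ)),

where the targets z fold the linear half of the hinge majorant into the
regression. After each solve, coefficients with |wⱼ| < 10⁻⁴ are removed
permanently (they re-enter only on a fresh fit); the iteration stops when
max(|Δb|, ‖Δw‖∞) < 10⁻⁴ or after 200 iterations, and non-convergence is
reported in the model metadata rather than raised. If every feature is
removed, the intercept-only model with the mean-hinge-minimizing intercept
(the majority rule, b = ±1) is returned.

Numerical safeguards, each of which was forced by observed behaviour:

* δ_p = 10⁻⁸ floors the penalty-weight denominator (shrinking-but-not-removed
  coefficients would otherwise blow up qⱼ). Distinct from the 10⁻⁴ removal
  threshold.
* δ_h = 10⁻⁴ floors the margin residual in the hinge weights. The L2 start
  point places its support vectors exactly on the margin (|m₀| = 0); with a
  much smaller floor their weights are so large that the first step is pinned
  to the start point and the solver stalls. Flooring keeps the quadratic a
  global majorant (the bound holds for every c > 0) at the price of an
  O(δ_h) value offset for on-margin samples.
* A backtracking step halving guards descent: the quadratic model shares the
  objective's gradient at the expansion point, so its minimizer defines a
  descent direction, and the accepted step never increases A. In practice the
  full step is almost always accepted; the safeguard makes the objective trace
  provably non-increasing between removals (removals can cause bounded jumps).
* A numerically singular system (possible when λ₂ = 0 and SCAD's flat region
  zeroes some qⱼ) receives a 10⁻⁸ diagonal jitter on the coefficient block;
  jitter use is recorded in the metadata.

**Elastic net.** The objective is convex, so the same majorize-minimize
iteration converges to the global minimum; it is run at a tighter tolerance
(10⁻⁶, 300 iterations, in-loop pruning only below 10⁻⁶) and the final 10⁻⁴
zeroing threshold is applied as in the L1 program. A quadratic-programming
formulation would be the natural alternative, but no QP solver is available
in the dependency set, and the MM route reproduces an independent convex
solve of the same objective to ~10⁻⁶ relative in the test suite. λ₂ = 0
delegates to the exact L1 linear program.

**RFE baseline.** Features are ranked by |wⱼ| of an L2 fit on the full
training data; subset sizes visit p and then the powers of two below p down
to 1 (so the conventional 2^k candidate sizes appear, e.g. 256 for p = 4919),
and the stratified-CV error of an L2 SVM restricted to each retained set
selects the winning size. Ties in |wⱼ| break by feature index.

## Tuning-parameter search

All searches operate on the log₂ scale over a default box [2⁻¹⁰, 2¹⁰] per
dimension: one dimension for ridge (C) and lasso/SCAD (λ₁), two for the
elastic families (λ₁, λ₂). The fold split (stratified k-fold; k = 5 by
default in simulation workflows, k = 10 for real-data workflows) is fixed
once per search so every candidate is scored on identical folds, and the L2
start point of the iterative solvers is precomputed per fold.

The interval search fits a Gaussian-process surrogate (squared-exponential
kernel with likelihood-fitted length scale on the unit-box-rescaled inputs,
noise-free interpolation with 10⁻⁶ jitter) to all visited points, starting
from a Latin-hypercube design of 10 points per dimension, and evaluates the
point maximizing the expected improvement EI = (best − μ)Φ(u) + σφ(u),
u = (best − μ)/σ (zero wherever σ = 0), located by local search from the best
of 100 random candidates. It stops when the best observed value has not
improved for ten consecutive proposals, when max EI < 10⁻⁹ (the "convergence"
branch of the stopping rule, which the source method leaves unquantified), or
at a proposal budget. Exact ties in CV error resolve toward larger λ₁, then
larger λ₂ — prefer the sparser, then smoother model. A fixed-grid search
(every point evaluated, same tie-break) is provided for comparison.

## Performance measures

Discrete classifiers are summarized by the confusion counts with +1 as the
positive class: misclassification rate, sensitivity, specificity, the Youden
index (sensitivity + specificity − 1) and the discrete-classifier
AUC = (sensitivity + specificity)/2 = (Youden + 1)/2, the area under the
one-point ROC polygon. A rate whose denominator is empty (e.g. sensitivity
with no positives in the fold) is reported as missing, never silently zero,
and aggregation skips missing values. Internally all rates are proportions;
percent formatting happens only in the reporting layer.

## Synthetic-data generator

The generator emulates a preprocessed two-class expression study:

* X ~ N(0, Σ) with Σ block-diagonal: five "clumps" of five features with
  unit variance and pairwise correlation ρ = 0.8 (co-regulated genes),
  identity elsewhere. Sampling uses the per-block Cholesky factor, so the
  covariance is exact.
* β has r nonzero entries of magnitude 0.5 with alternating signs (balanced
  positive/negative; an odd r leaves one extra positive). The first feature
  of each block is its relevant lead; the remaining r − 5 relevant features
  sit on independent coordinates directly after the block region. The truth
  partition (relevant / correlated-redundant / independent-irrelevant) is
  index-explicit for unambiguous selection-frequency accounting.
* labels: P(yᵢ = +1) = 1/(1 + exp(−(β₀ + xᵢ·β))) with β₀ = 0; yᵢ = +1 iff a
  Uniform(0,1) draw falls below that probability.

μ = 0 and the magnitude 0.5 are documented defaults of the generator — the
magnitude is a free parameter with no canonical value, and `bayes_error`
reports the irreducible error it implies (≈ 0.26 at r = 10, magnitude 0.5:
a deliberately hard, low-signal regime). What the generator does **not**
emulate: heavy-tailed or skewed expression values, feature-dependent noise,
batch effects, and long-range correlation beyond the five blocks. Passing
tests therefore demonstrate correct behaviour under a clean multivariate-
normal/logistic mechanism, not robustness to real microarray artifacts.

The comparative study (`run_study`) per run draws fresh train/test sets,
tunes every method on the training set by interval search under stratified
k-fold CV, fits at the tuned parameters and evaluates on the test set; run i
uses seed s + 10007·i (prime stride) so the streams are decorrelated but
reproducible. Summaries report mean ± sd of test error and Youden index,
median and IQR of model size, and selection frequencies per truth group;
methods failing in more than 20% of runs are flagged.

At the reduced benchmark scale used in the test suite (p = 200, r = 10,
n_train = n_test = 200, 10 runs — sized to keep a full five-method study
inside a routine test run), the qualitative sparsity ordering of the methods
reproduces clearly, while error-rate differences between methods are small
relative to their run-to-run spread in this low-signal regime; the study
summary carries the standard deviations needed to judge that spread.

## Degenerate inputs and edge cases

* Single-class data refuses to fit; CV refuses folds larger than the smaller
  class.
* A CV fold whose solver fails is skipped if at least k−1 folds succeed,
  otherwise the error propagates; failures are counted in the result.
* Degenerate search bounds (low = high) evaluate the single admissible point.
* Model files store coefficients with round-tripping decimal `repr`, so
  reloaded models reproduce decision values bit-identically; non-finite
  coefficients are rejected on read.

## Known limitations

* The SCAD families solve a non-convex problem: the LQA iteration finds a
  local minimum in the basin of the L2 start point (verified in tests against
  a derivative-free polish of the same basin), not a certified global one.
* The elastic-net MM iteration approaches coefficients of exactly zero only
  in the limit; the 10⁻⁴ threshold supplies the final sparsity, so
  coefficients genuinely between 10⁻⁶ and 10⁻⁴ can be pruned slightly
  aggressively.
* Tuning minimizes the CV misclassification rate, which is piecewise constant
  in the parameters; wide plateaus make the selected λ seed-dependent even
  though the search itself is deterministic per seed. The larger-λ tie-break
  resolves only exact ties.
* CV error estimated on the same data used for tuning is optimistically
  biased; the simulation study therefore evaluates on independent test data,
  and nested CV for real-data error reporting is out of scope.
* Binary classification with a linear kernel only.
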