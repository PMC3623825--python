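# Methods

## Model and estimator

Let X be a p-variate Gaussian vector with invertible covariance Σ and
precision Ω = Σ⁻¹. The partial correlation between variables i and j given
the rest is ρ_ij = −ω_ij/√(ω_ii ω_jj), and ρ_ij = 0 iff i and j are
conditionally independent. An independence graph G declares which ρ_ij may
be nonzero.

The estimator combines two classical facts: (1) the coefficient of X_j in
the regression of X_i on all other variables satisfies
ρ_ij = sign(β_ij)·√(β_ij β_ji); and (2) setting β_ij = β_ji = 0 for a
non-edge is the same as deleting X_j from X_i's regression. So each variable
is regressed on its *graph neighbors only* (data mean-centered per column,
intercept discarded) and, for each edge,

    ρ̂_ij = sign(β̂_ij) · √(β̂_ij β̂_ji),

while non-edges are written as literal zeros. Removing a covariate changes
every other coefficient in that regression, which is how the graph
information propagates into the retained entries. With the complete graph
and OLS the procedure reproduces the unconstrained estimator
−ω̂_ij/√(ω̂_ii ω̂_jj) from the inverse sample covariance exactly (verified to
1e−8 in the tests; machine precision in practice).

Two situations the square-root form leaves open are resolved as follows and
logged when they occur:

- **Discordant signs** (β̂_ij β̂_ji < 0): the square root is undefined; the
  entry is set to 0. Discordant signs arise when the two neighborhood
  regressions disagree about a weak association, which is itself evidence of
  no reliable partial correlation. (With the complete graph and OLS this
  cannot happen — both coefficients are the same precision entry up to
  positive scaling.)
- **|ρ̂| > 1** (possible with regularized engines): clipped to ±1 so the
  output remains a valid correlation-like matrix.

Unordered pairs are processed once, in the column order of the data matrix,
so the output is symmetric by construction.

## Regression engines

When a node's neighborhood is not small relative to n, OLS is replaced by a
regularized regression. All engines share the contract (centered response,
centered covariates) → coefficient vector; hyperparameters are selected by
seeded K-fold cross-validation (default K = 10; fold assignment is a seeded
shuffle, so everything is reproducible).

- **ols** — least squares; requires fewer than n−1 neighbors (one degree of
  freedom is spent on centering). A node with too many neighbors is a hard
  error naming the node, never a silent pseudo-inverse.
- **ridge_cv** — grid of 25 penalties, logarithmic over 1e−4…1e4. CV is
  computed from one SVD per training fold, from which the entire penalty
  path is evaluated in O(grid) extra time; the selected-penalty solution
  matches scikit-learn's `Ridge` to 1e−8 (tested). This implementation
  choice keeps the per-node cost low enough for the iterative and stability
  experiments, which call the estimator thousands of times.
- **ridge_analytic** — the CV-free Hoerl–Kennard–Baldwin plug-in
  λ = q·s²/‖β̂‖² with β̂ the (minimum-norm) least-squares solution and
  s² = RSS/(n − rank); floored at λ_min = 1e−8 when the fit is perfect.
  Used in the stability experiments, where removing CV noise from penalty
  selection markedly stabilizes the inferred networks. A single-neighbor
  node falls back to simple regression (the plug-in needs q ≥ 2).
- **pls** — scikit-learn PLS regression; component count chosen by CV over
  1…min(q, n_train−1, 15).
- **lasso / adalasso** — scikit-learn `LassoCV` on internally standardized
  columns, coefficients back-transformed. The adaptive variant uses Zou's
  weights 1/|β̂_init| (γ = 1) with the ridge-CV fit as initializer,
  implemented by rescaling the kept columns; covariates with a zero initial
  coefficient carry infinite weight and are dropped.

## Iterative graph inference

Inputs: a dataset, a threshold t ∈ (0,1), an initial graph G₀ (default: the
complete-graph estimate thresholded — equivalently the regression-based
full-GGM estimators of the ridge.net/pls.net family). Each iteration
estimates the pcor matrix under the current graph and thresholds it
(edge iff |ρ̂| > t, strictly; strictness makes the empty graph a clean fixed
point and preserves monotone nesting across thresholds). Stopping:

- **converged** — the new graph equals the graph it was estimated under;
- **cycle_detected** — the new graph equals some earlier graph. Oscillation
  is possible in principle because CV re-randomizes each iteration; the full
  visited set is tracked, and the sparsest recorded graph of the cycle is
  reported as the result. This policy is an engineering choice; such cycles
  were not observed in the shipped experiments.
- **max_iter** — hard cap, default 50 (empirical convergence takes ~3–12
  iterations at the scales used here).

CV folds are re-seeded deterministically per iteration (base seed + a fixed
multiple of the iteration index), so traces are exactly reproducible while
folds still differ across iterations. Each iteration's pcor matrix satisfies
the previous graph's zero constraints exactly — an invariant the tests check
on every trace.

## Simulation generator

The generator defines the study conditions for all shipped experiments:

1. Draw a graph: Erdős–Rényi G(p, π) for (typically) non-decomposable
   structures, or Barabási–Albert preferential attachment (m = 1 gives a
   tree, hence a chordal/decomposable graph).
2. Fill the upper-triangular adjacency entries with uniform weights from
   [0.1, 1.0], each with a random sign (±1 with probability ½). Random signs
   avoid a systematically signed pcor matrix; both bounds and the sign flag
   are exposed.
3. Form Ω = (I+W)ᵀ(I+W). As a Gram matrix of the invertible unit-triangular
   factor I+W it is strictly positive definite, sparse, and introduces
   *fill-in*: pairs of nodes sharing a lower-indexed neighbor acquire an
   edge. The realized graph G̃ — read off the nonzero pattern of Ω with
   tolerance 1e−12 — is therefore a supergraph of the drawn graph, and G̃,
   not the drawn graph, is the ground truth attached to the model. For
   m = 1 trees the fill-in connects siblings into family cliques, and the
   realized graph remains chordal (asserted, not assumed, wherever the
   decomposable scenarios rely on it).
4. Normalize Ω to the partial correlation matrix ρ_ij = −ω_ij/√(ω_ii ω_jj);
   positive-definiteness guarantees |ρ_ij| < 1.
5. Sample N(0, Ω⁻¹) through the Cholesky factor of Ω (solve Lᵀx = z), never
   forming the inverse.

What this emulates — and does not. The generator produces exactly-sparse,
well-conditioned Gaussian data with moderate partial correlations, which is
the regime where the zero-constraint machinery can be validated against
known truth. Real omics data add heavy tails, shared technical covariates,
and block-correlated noise; passing tests here demonstrate correctness of
the estimators under the model's own assumptions, not robustness to those
violations.

## Baselines

- **Shrinkage pcor** — columns standardized, Ledoit–Wolf shrinkage toward
  the (identity) target with analytic intensity, inverted, transformed to
  pcor. Graph-ignorant by design: it serves as the reference upper bound on
  MSE that prior-knowledge methods should beat.
- **IPF covariance selection** — cyclic iterative proportional fitting over
  the edge set plus singleton cliques: for clique a,
  K_aa += (S_aa)⁻¹ − ((K⁻¹)_aa)⁻¹. Pairwise (edge) cliques converge to the
  same constrained MLE as maximal-clique IPF and keep the code simple.
  Non-edge precision entries stay exactly zero throughout. Convergence =
  largest block update in a sweep < tol (default 1e−8); non-convergence
  after max_sweeps (default 5000) is flagged, not raised. The complete graph
  is returned directly (no constraints ⇒ MLE = S). On trees the result
  matches the closed-form decomposable MLE (Σ over edge-block inverses minus
  degree corrections) to 1e−6 — a dual-route check in the tests.

## Evaluation statistics

- **MSE** — mean squared difference over the p(p−1)/2 upper-triangle pairs;
  the unit diagonal is excluded so the statistic is scale-free in p.
- **PPV / sensitivity** — TP/(TP+FP) and TP/(TP+FN) over unordered pairs.
  0/0 (e.g. an empty estimated graph) is reported as `None` and excluded
  from averages — never silently coerced to 0 or 1.
- **Fleiss' κ** — items = unordered pairs, raters = networks, categories =
  {edge, non-edge}; computed via statsmodels and verified to 1e−12 against a
  from-definition brute force. When every rater puts every item in one
  category the chance term is 1 and κ is returned as 1 (perfect agreement).
- **Stability protocol** — samples are shuffled with a seeded permutation
  and cut into contiguous near-equal groups (remainder spread over the
  leading groups; whether the original study's split was random or ordered
  is unknown, seeded-random is this package's choice); one network is
  inferred per leave-one-group-out subset and κ is computed over the group
  count (default 10).

## Experiment scales and defaults

The shipped experiment scenarios use p ∈ {50, 100}, n ∈ {40, 100, 200},
ER edge probability 0.1 (p = 50) or 0.04 (p = 100), BA attachment m = 1,
thresholds {0.05, 0.1, 0.15, 0.2}, 10 replicates, and weight interval
[0.1, 1.0] — sizes chosen so a full comparison runs in minutes on one CPU
while preserving the qualitative contrasts of interest: constrained
estimation beats shrinkage when p > n on non-decomposable graphs; iterative
inference raises PPV at every threshold with a sensitivity deficit well
under 0.1; and iterative inference raises Fleiss' κ (observed ≈ 0.63 → 0.71
with the analytic ridge engine). Stability improvements are only meaningful
when the baseline is itself reasonably stable; no improvement is claimed
when the baseline κ falls below 0.3.

## Known limitations

- The residual-correlation formulation of partial correlation is not
  implemented as an estimation route; the regression-coefficient identity is
  used throughout.
- Threshold selection is out of scope: thresholds are inputs, swept by the
  experiment driver.
- The IPF implementation recomputes K⁻¹ per block update (O(p³) each);
  fine at the p ≤ 100 scales here, but a rank-2 update scheme would be
  needed for much larger p.
- Marginal-variance estimation is limited to the precision-scale
  reconstruction Ω_ii = 1/v_i, Ω_ij = −ρ_ij√(Ω_ii Ω_jj) from user-supplied
  partial variances.
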