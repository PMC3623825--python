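# pcorsel

Partial correlation selection for Gaussian graphical models (GGMs):
estimation of a partial correlation matrix **under the constraint that a
given set of entries is exactly zero**, and iterative inference of the
independence graph itself.

## The problem

In systems biology and related fields, networks of interacting variables
(genes, proteins, measured physical properties) are modeled as GGMs: for a
Gaussian vector X = (X₁, …, X_p) with precision matrix Ω = Σ⁻¹, the partial
correlation between variables i and j given all others is

    ρ_ij = −ω_ij / √(ω_ii ω_jj),

and ρ_ij = 0 exactly when X_i ⟂ X_j given the rest. An undirected
*independence graph* G encodes which partial correlations may be nonzero.
Typical omics data have far fewer samples n than variables p, so both
estimating ρ under a known graph and estimating G itself require
regularization.

## What the package does

**Graph-constrained estimation** (`pacose`). Using the classical
regression identity ρ_ij = sign(β̂_ij)·√(β̂_ij β̂_ji), each variable is
regressed on its graph *neighbors only*; non-edges become exact zeros in the
result. Regression engines: OLS, ridge (K-fold CV or the analytic
Hoerl–Kennard–Baldwin penalty λ = q·s²/‖β̂‖²), PLS, lasso and adaptive
lasso, so neighborhoods larger than n are handled. Unlike closed-form
covariance selection, this works for **non-decomposable** graphs — the
common case for biological networks.

**Iterative graph inference** (`ipacose`). Start from any estimated graph
(by default the thresholded unconstrained estimate), re-estimate the partial
correlations under it, re-threshold, and repeat until the graph stops
changing. Re-estimated coefficients tend to shrink below the threshold, so
the procedure prunes false positive edges — raising the positive predictive
value with little loss of sensitivity — and makes the inferred network more
stable under data perturbation.

**Baselines and scoring** — the precision→pcor transform, a Ledoit–Wolf
identity-target shrinkage estimator (graph-ignorant reference), iterative
proportional fitting (IPF) for the constrained covariance MLE, MSE /
PPV / sensitivity scoring, and a leave-one-group-out stability protocol
scored with Fleiss' κ.

**Simulation ground truth** (`simdata`) — Erdős–Rényi or Barabási–Albert
graphs, sparse positive-definite precision matrices Ω = (I+W)ᵀ(I+W) with
uniform random weights, and seeded multivariate Gaussian sampling.

## Worked example

```python
import pcorsel as pc

graph = pc.random_graph(p=30, model="erdos_renyi", density_or_attach=0.1, seed=1)
model = pc.build_precision_model(graph, seed=1)          # ground-truth pcor matrix
data  = pc.sample_gaussian(model, n=60, seed=2)          # n = 60 << p(p-1)/2 pairs

engine = pc.RegressionEngine("ridge_cv", seed=3)
constrained = pc.pacose(data, model.graph, engine)       # knows the true graph
shrunk, intensity = pc.shrinkage_pcor(data)              # graph-ignorant baseline

truth = pc.PartialCorrelationMatrix(model.pcor, model.graph.node_labels)
print(pc.pcor_mse(constrained, truth), pc.pcor_mse(shrunk, truth))
```

prints (see `examples/01_constrained_estimation.py`):

```
MSE constrained (true graph): 0.00181
MSE shrinkage (no graph):     0.00980  (intensity 0.37)
```

Knowing which coefficients are zero concentrates the 60 samples on the 91
realized edges, cutting the MSE about fivefold versus the unconstrained
baseline. For graph inference (`examples/02_iterative_graph_inference.py`,
p=40, n=100, threshold 0.1):

```
 one-shot: PPV 0.561, sensitivity 0.541
iterative: PPV 0.785, sensitivity 0.490
```

The iterative procedure prunes 66 edges over 11 iterations; most of them are
false positives, so PPV rises sharply while sensitivity barely drops. The
other example scripts cover IPF covariance selection on decomposable graphs
(`03`) and the Fleiss-κ stability protocol (`04`).

A `pcorsel` command-line tool wraps the same functions
(`pcorsel simulate | pacose | ipacose | covsel | evaluate | evaluate-graph |
stability | experiment`); run `pcorsel --help` for details.

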