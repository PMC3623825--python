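"""Estimate a partial correlation matrix under a known independence graph.

Simulates a sparse ground-truth model, estimates the partial correlation
matrix with the graph-constrained regression estimator (true graph given),
and compares the error against the graph-ignorant shrinkage baseline.
"""

import logging

import pcorsel as pc

# discordant-sign warnings are routine in bulk runs; keep the output clean
logging.getLogger("pcorsel").setLevel(logging.ERROR)

# ground truth: sparse random graph -> SPD precision matrix -> Gaussian data
graph = pc.random_graph(p=30, model="erdos_renyi", density_or_attach=0.1, seed=1)
model = pc.build_precision_model(graph, seed=1)
data = pc.sample_gaussian(model, n=60, seed=2)  # fewer samples than p(p-1)/2 pairs
truth = pc.PartialCorrelationMatrix(model.pcor, model.graph.node_labels)

# graph-constrained estimate (ridge engine: neighborhoods can exceed n)
engine = pc.RegressionEngine("ridge_cv", seed=3)
constrained = pc.pacose(data, model.graph, engine)

# unconstrained shrinkage baseline ignores the graph entirely
shrunk, intensity = pc.shrinkage_pcor(data)

print(f"variables: {model.graph.p}, realized edges: {model.graph.edge_count}, samples: {data.n}")
print(f"MSE constrained (true graph): {pc.pcor_mse(constrained, truth):.5f}")
print(f"MSE shrinkage (no graph):     {pc.pcor_mse(shrunk, truth):.5f}  (intensity {intensity:.2f})")
# the constrained estimator should be several-fold more accurate: knowing
# which coefficients are zero concentrates the n=60 samples on the few
# nonzero ones, while the shrinkage baseline spreads them over every pair
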