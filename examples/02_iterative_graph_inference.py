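"""Infer an independence graph by iterative re-estimation and thresholding.

Starting from the thresholded unconstrained estimate (the one-shot baseline),
the iterative procedure re-estimates the partial correlations under the
current graph and re-thresholds until the graph stabilizes, pruning false
positive edges.
"""

import logging

import pcorsel as pc

# discordant-sign warnings are routine in bulk runs; keep the output clean
logging.getLogger("pcorsel").setLevel(logging.ERROR)

graph = pc.random_graph(p=40, model="erdos_renyi", density_or_attach=0.1, seed=5)
model = pc.build_precision_model(graph, seed=5)
data = pc.sample_gaussian(model, n=100, seed=6)

engine = pc.RegressionEngine("ridge_cv", seed=7)
threshold = 0.1

initial = pc.initial_graph_from_data(data, engine, threshold)
trace = pc.ipacose(data, initial, threshold, engine, max_iter=50)

print(f"true graph: {model.graph.edge_count} edges")
print(f"one-shot thresholding: {initial.edge_count} edges")
print(f"iterations: {len(trace.iterations)} ({trace.stop_reason}); "
      f"edge counts {[r.graph.edge_count for r in trace.iterations]}")

for name, g in (("one-shot", initial), ("iterative", trace.final_graph)):
    ppv, sens = pc.ppv_sensitivity(pc.graph_confusion(g, model.graph))
    print(f"{name:>9}: PPV {ppv:.3f}, sensitivity {sens:.3f}")
# the iterative graph is sparser: its PPV (fraction of reported edges that
# are real) rises while sensitivity (fraction of real edges found) barely drops
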