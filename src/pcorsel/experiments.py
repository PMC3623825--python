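"""Scripted simulation experiments comparing estimators and inference methods.

One experiment draws ``replicates`` ground-truth models and datasets and, for
each, scores (a) matrix estimation — PACOSE under the true graph vs. the
unconstrained shrinkage baseline, plus IPF when the realized graph is
decomposable and n > p — by MSE, and (b) graph inference — the iterative
procedure vs. its non-iterative counterpart — by PPV and sensitivity at each
threshold. Results come back as a tidy table with every seed recorded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, evaluation, ipacose, simdata
from .engines import RegressionEngine
from .graph import IndependenceGraph
from .pacose import PartialCorrelationMatrix, pacose


@dataclass(frozen=True)
class ExperimentConfig:
    scenario: str = "default"
    p: int = 50
    n: int = 100
    graph_model: str = "erdos_renyi"  # or "barabasi"
    graph_param: float = 0.1  # ER edge probability or BA attachment count
    weight_low: float = 0.1
    weight_high: float = 1.0
    engine: str = "ridge_cv"
    cv_folds: int = 10
    thresholds: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2)
    replicates: int = 10
    base_seed: int = 0
    max_iter: int = 50
    run_ipf: bool = True

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(not 0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")


def _replicate_rows(config: ExperimentConfig, rep: int) -> list[dict]:
    seed = (config.base_seed + 1000003 * rep) % (2**31)
    graph0 = simdata.random_graph(config.p, config.graph_model, config.graph_param, seed)
    model = simdata.build_precision_model(graph0, config.weight_low, config.weight_high, seed)
    data = simdata.sample_gaussian(model, config.n, seed + 1)
    truth = PartialCorrelationMatrix(values=model.pcor, variable_labels=model.graph.node_labels)
    engine = RegressionEngine(name=config.engine, cv_folds=config.cv_folds, seed=seed)
    rows: list[dict] = []
    base = {"scenario": config.scenario, "replicate": rep, "seed": seed}

    # (a) matrix estimation with the true graph known
    est = pacose(data, model.graph, engine)
    rows.append(base | {"metric": "mse", "method": f"pacose_{config.engine}", "threshold": None,
                        "value": evaluation.pcor_mse(est, truth)})
    shrunk, _ = baselines.shrinkage_pcor(data)
    rows.append(base | {"metric": "mse", "method": "shrinkage", "threshold": None,
                        "value": evaluation.pcor_mse(shrunk, truth)})
    if config.run_ipf and config.n > config.p and simdata.is_decomposable(model.graph):
        S = np.cov(data.values, rowvar=False)
        ipf = baselines.ipf_covariance_selection(S, model.graph)
        ipf_pcor = baselines.precision_to_pcor(ipf.precision, model.graph.node_labels)
        rows.append(base | {"metric": "mse", "method": "ipf", "threshold": None,
                            "value": evaluation.pcor_mse(ipf_pcor, truth)})

    # (b) graph inference: one-shot thresholding vs the iterative procedure
    complete = IndependenceGraph.complete(data.variable_labels)
    full_pcor = pacose(data, complete, engine)
    for t in config.thresholds:
        init = ipacose.threshold_graph(full_pcor, t)
        for method, graph in (
            ("noniterative", init),
            ("ipacose", ipacose.ipacose(data, init, t, engine, config.max_iter).final_graph),
        ):
            conf = evaluation.graph_confusion(graph, model.graph)
            ppv, sens = evaluation.ppv_sensitivity(conf)
            rows.append(base | {"metric": "ppv", "method": method, "threshold": t, "value": ppv})
            rows.append(base | {"metric": "sensitivity", "method": method, "threshold": t, "value": sens})
            rows.append(base | {"metric": "edges", "method": method, "threshold": t,
                                "value": float(graph.edge_count)})
    return rows


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run all replicates; optionally write results.tsv and summary.json."""
    rows: list[dict] = []
    errors: list[dict] = []
    for rep in range(config.replicates):
        try:
            rows.extend(_replicate_rows(config, rep))
        except Exception as exc:  # record and continue: partial failures must not kill the run
            errors.append({"replicate": rep, "error": str(exc)})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.tsv", sep="\t", index=False)
        summary = {
            "config": asdict(config),
            "errors": errors,
            "medians": _summaries(table),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return table


def _summaries(table: pd.DataFrame) -> dict:
    if table.empty:
        return {}
    out: dict = {}
    mse = table[table.metric == "mse"]
    if not mse.empty:
        out["mse_median"] = mse.groupby("method").value.median().to_dict()
    for metric in ("ppv", "sensitivity"):
        sub = table[(table.metric == metric) & table.value.notna()]
        if not sub.empty:
            out[f"{metric}_mean"] = {
                f"{m}@{t}": float(v)
                for (m, t), v in sub.groupby(["method", "threshold"]).value.mean().items()
            }
    return out
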