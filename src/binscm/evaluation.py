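"""Graph-vs-truth scoring, the frequent-pattern baseline and the benchmark runner.

Two scoring tasks:

* **directed** — edge-level precision/recall/F1 of the inferred directed
  edges against the ground-truth directed edges.
* **transitive** — the same counting after replacing both edge sets by
  their reachability closures, so that a mediated relation (X causes Z
  through Y) counts as correct.

Undirected inferred edges ("dependency without causal relation") carry no
direction claim and are excluded from both tasks.

The frequent-pattern baseline keeps every pair whose aligned joint support
clears a threshold and whose odd difference tests nonzero, then orients by
comparing the two conditional confidences directly — no confounding check,
which is what makes it strong on the transitive task and weak on the
directed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data import BinaryDataset, bootstrap_resample, derive_seeds, nondegenerate_columns
from .estimators import align_pair
from .inference import (
    CausalGraph,
    EdgeRecord,
    _Moments,
    infer_causal_graph,
    test_nonzero,
)
from .simulator import benchmark_model, benchmark_true_edges, simulate_bscm, transitive_closure

__all__ = [
    "GraphScore",
    "compare_graphs",
    "score_graph",
    "frequent_pattern_baseline",
    "run_benchmark_suite",
]


@dataclass(frozen=True)
class GraphScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    task: str

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "task": self.task,
        }


def _score(tp: int, fp: int, fn: int, task: str) -> GraphScore:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return GraphScore(tp=tp, fp=fp, fn=fn, precision=precision,
                      recall=recall, f1=f1, task=task)


def compare_graphs(
    inferred: Iterable[tuple[int, int]],
    truth: Iterable[tuple[int, int]],
    task: str = "directed",
) -> GraphScore:
    """Precision/recall/F1 of ordered edge sets on one of the two tasks."""
    inferred = set(inferred)
    truth = set(truth)
    if task == "transitive":
        inferred = transitive_closure(inferred)
        truth = transitive_closure(truth)
    elif task != "directed":
        raise ValueError(f"unknown task {task!r}")
    tp = len(inferred & truth)
    return _score(tp, len(inferred - truth), len(truth - inferred), task)


def score_graph(graph: CausalGraph, truth: Iterable[tuple[int, int]],
                task: str = "directed") -> GraphScore:
    """Score a :class:`CausalGraph`'s directed edges against the truth."""
    return compare_graphs(graph.directed_edges(), truth, task)


def frequent_pattern_baseline(
    ds: BinaryDataset,
    min_support: float = 0.05,
    alpha: float = 0.05,
    q: int = 100,
    seed: int = 0,
) -> CausalGraph:
    """Support/confidence causal mining without a confounding check.

    A pair enters when its aligned joint support is at least ``min_support``
    and the bootstrap odd-difference test rejects; the edge points from the
    variable whose active state better predicts the other, i.e. towards the
    larger conditional confidence.  An exact confidence tie stays undirected.
    """
    ens = bootstrap_resample(ds, q=q, seed=seed)
    mom = _Moments(ens)
    graph = CausalGraph(names=ds.names)
    cols = nondegenerate_columns(ds)
    n = ds.n
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            i, j = cols[a], cols[b]
            pair = align_pair(ds, i, j)
            xi = ds.values[:, i]
            xj = ds.values[:, j] if not pair.flipped_j else 1 - ds.values[:, j]
            support = float(np.count_nonzero(xi & xj)) / n
            if support < min_support:
                continue
            odd = test_nonzero(mom.cov_samples(i, j), "two-sided", alpha,
                               method="percentile")
            if not odd.reject:
                continue
            dir_s, _, _, _ = mom.dir_samples(pair)
            edge = EdgeRecord(i=i, j=j, status="undirected",
                              flipped_j=pair.flipped_j, dep=None, odd=odd)
            mean_dir = float(dir_s.mean()) if dir_s.size else 0.0
            if mean_dir > 0:
                edge.status, edge.direction = "directed", (i, j)
            elif mean_dir < 0:
                edge.status, edge.direction = "directed", (j, i)
            graph.edges.append(edge)
    graph.edges.sort(key=lambda e: (e.i, e.j))
    return graph


def run_benchmark_suite(
    p_grid: Iterable[float] = (0.5, 0.3, 0.1, 0.05),
    n_grid: Iterable[int] = (500,),
    reps: int = 10,
    q: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    min_support: float = 0.05,
) -> pd.DataFrame:
    """Simulate, infer and score across a (p, n) grid.

    For every cell and replication, one benchmark dataset is drawn and both
    the proposed method and the frequent-pattern baseline are scored on both
    tasks against the six-edge ground truth.  Long-format result: one row
    per (method, task, p, n, rep).
    """
    p_grid = list(p_grid)
    n_grid = list(n_grid)
    truth = benchmark_true_edges()
    cells = [(p, n) for p in p_grid for n in n_grid]
    seeds = derive_seeds(seed, 2 * len(cells) * reps)
    rows = []
    s = 0
    for p, n in cells:
        for rep in range(reps):
            data_seed, boot_seed = seeds[s], seeds[s + 1]
            s += 2
            ds = simulate_bscm(benchmark_model(p), n, seed=data_seed)
            proposed = infer_causal_graph(ds, q=q, alpha=alpha,
                                          seed=boot_seed).graph
            baseline = frequent_pattern_baseline(
                ds, min_support=min_support, alpha=alpha, q=q, seed=boot_seed
            )
            for method, graph in (("proposed", proposed),
                                  ("frequent_pattern", baseline)):
                for task in ("directed", "transitive"):
                    sc = score_graph(graph, truth, task)
                    rows.append({
                        "method": method, "task": task, "p": p, "n": n,
                        "rep": rep, "precision": sc.precision,
                        "recall": sc.recall, "f1": sc.f1,
                    })
    return pd.DataFrame(rows)
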