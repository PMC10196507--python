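"""Boolean structural-causal-model data generator with exact marginals.

Each variable is the logical OR of its parents and an independent Bernoulli(p)
noise term, drawn fresh per row and per variable:

    X_k = X_{pa_1} v ... v X_{pa_m} v N_k,   P(N_k = 1) = p.

The 10-variable benchmark wires X1 <- X2 v X3, X4 <- X2 v X5 and
X6 <- X1 v X4; the other seven variables are pure noise.  OR gates make the
implication "parent active => child active" hold deterministically in every
simulated row, and ancestral enumeration over the noise terms yields exact
marginal probabilities for testing.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .data import BinaryDataset

__all__ = [
    "BSCMModel",
    "benchmark_model",
    "benchmark_true_edges",
    "simulate_bscm",
    "exact_marginal",
    "transitive_closure",
    "load_model",
    "save_model",
]


@dataclass(frozen=True)
class BSCMModel:
    """An OR-gate Boolean SCM: per-variable parent lists plus noise rate p."""

    names: tuple[str, ...]
    parents: tuple[tuple[int, ...], ...]
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"noise probability p must be in (0,1), got {self.p}")
        d = len(self.names)
        if len(self.parents) != d:
            raise ValueError("one parent list per variable is required")
        for k, pa in enumerate(self.parents):
            for u in pa:
                if not 0 <= u < d or u == k:
                    raise ValueError(f"invalid parent {u} for variable {k}")
        g = nx.DiGraph(self.edges())
        g.add_nodes_from(range(d))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent relation must be acyclic")

    @property
    def d(self) -> int:
        return len(self.names)

    def edges(self) -> set[tuple[int, int]]:
        """Ground-truth directed edges (parent, child)."""
        return {(u, k) for k, pa in enumerate(self.parents) for u in pa}

    def topological_order(self) -> list[int]:
        g = nx.DiGraph(self.edges())
        g.add_nodes_from(range(self.d))
        return list(nx.topological_sort(g))

    def ancestors(self, k: int) -> set[int]:
        """Ancestral set of variable k, including k itself."""
        g = nx.DiGraph(self.edges())
        g.add_nodes_from(range(self.d))
        return nx.ancestors(g, k) | {k}


def benchmark_model(p: float) -> BSCMModel:
    """The 10-indicator benchmark: X1<-X2vX3, X4<-X2vX5, X6<-X1vX4.

    Seven of the ten variables are parentless noise.  Indices are 0-based
    internally; names keep the 1-based convention (X1..X10).
    """
    names = tuple(f"X{k}" for k in range(1, 11))
    parents: list[tuple[int, ...]] = [()] * 10
    parents[0] = (1, 2)   # X1 <- X2, X3
    parents[3] = (1, 4)   # X4 <- X2, X5
    parents[5] = (0, 3)   # X6 <- X1, X4
    return BSCMModel(names=names, parents=tuple(parents), p=p)


def benchmark_true_edges() -> set[tuple[int, int]]:
    """The six directed ground-truth edges of the benchmark (0-based)."""
    return {(1, 0), (2, 0), (1, 3), (4, 3), (0, 5), (3, 5)}


def simulate_bscm(model: BSCMModel, n: int, seed: int = 0) -> BinaryDataset:
    """Sample n rows: i.i.d. noise, then OR of parents in topological order."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    noise = (rng.random((n, model.d)) < model.p)
    X = np.zeros((n, model.d), dtype=np.int8)
    for k in model.topological_order():
        col = noise[:, k]
        for u in model.parents[k]:
            col = col | (X[:, u] == 1)
        X[:, k] = col
    return BinaryDataset(X, model.names)


def exact_marginal(model: BSCMModel, k: int, max_noise: int = 20) -> float:
    """Exact P(X_k = 1) by enumeration over the ancestral noise assignment.

    Enumerates the 2^m joint noise configurations of the m ancestral
    variables of k (including k itself) and sums the probabilities of those
    where the OR recursion turns X_k on.  Usable as an independent oracle
    for models with at most ``max_noise`` ancestral noise terms.
    """
    anc = sorted(model.ancestors(k))
    if len(anc) > max_noise:
        raise ValueError(
            f"{len(anc)} ancestral noise terms exceed the enumeration "
            f"limit of {max_noise}"
        )
    order = [v for v in model.topological_order() if v in set(anc)]
    total = 0.0
    for bits in itertools.product((0, 1), repeat=len(anc)):
        noise = dict(zip(anc, bits))
        weight = 1.0
        for b in bits:
            weight *= model.p if b else (1.0 - model.p)
        value: dict[int, int] = {}
        for v in order:
            on = noise[v]
            for u in model.parents[v]:
                on = on or value[u]
            value[v] = int(on)
        if value[k]:
            total += weight
    return total


def transitive_closure(edges: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Reachability closure of a directed edge set (superset, idempotent)."""
    g = nx.DiGraph(edges)
    return set(nx.transitive_closure(g).edges())


# --------------------------------------------------------------------------
# model spec files: JSON {"names": [...], "parents": {name: [names]}, "p": x}
# --------------------------------------------------------------------------

def save_model(model: BSCMModel, path: str | Path) -> None:
    spec = {
        "names": list(model.names),
        "parents": {
            model.names[k]: [model.names[u] for u in pa]
            for k, pa in enumerate(model.parents)
            if pa
        },
        "p": model.p,
    }
    Path(path).write_text(json.dumps(spec, indent=1))


def load_model(path: str | Path) -> BSCMModel:
    spec = json.loads(Path(path).read_text())
    names = tuple(str(n) for n in spec["names"])
    index = {n: k for k, n in enumerate(names)}
    parents: list[tuple[int, ...]] = [()] * len(names)
    for child, pas in spec.get("parents", {}).items():
        parents[index[child]] = tuple(index[u] for u in pas)
    return BSCMModel(names=names, parents=tuple(parents), p=float(spec["p"]))
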