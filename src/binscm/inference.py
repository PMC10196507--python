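"""Bootstrap estimation statistics and the causal-graph inference algorithm.

The pipeline turns a binary dataset into an annotated causal graph in four
composed phases:

1. ``bootstrap_resample`` (in :mod:`binscm.data`) — q with-replacement
   replicates of the rows.
2. ``infer_association_graph`` — for every usable pair, bootstrap sampling
   distributions of the dependency degree and the signed odd difference;
   a pair becomes a candidate edge when both statistics test nonzero.
3. ``confounding_filter`` — a candidate (i, j) is dropped when some third
   variable Z renders the pair conditionally independent in every
   informative stratum of Z.
4. ``orient_edges`` — the bootstrap causal-direction statistic decides
   i -> j, j -> i, or (when its CI straddles zero) an undirected edge,
   "dependency without causal relation".

Two decision rules back :func:`test_nonzero`:

* ``"rank-zero"`` (used for the nonnegative dependency statistics): a
  Mann-Whitney rank test of the bootstrap sample against an equal-length
  all-zero reference, with tie correction and normal approximation.  Since
  the statistic is an absolute value, this effectively asks whether any
  nonzero dependency mass is present at all; it returns p = 1 only when the
  samples are (almost) exactly zero.  Under a deterministic OR-gate data
  model, conditioning on a separating variable makes strata degenerate and
  the conditional dependency *exactly* zero in every replicate — which is
  precisely the signature the confounding filter keys on.
* ``"percentile"`` (used for the signed odd-difference and
  causal-direction statistics): the percentile-bootstrap p-value, i.e. the
  (doubled, for two-sided) fraction of bootstrap mass on the null side of
  zero.  Rejection at level alpha coincides with the 100(1-alpha)%
  percentile CI excluding zero, the estimation-statistics reading, and
  holds the false-positive rate of the association step near alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .data import (
    BinaryDataset,
    BootstrapEnsemble,
    bootstrap_resample,
    nondegenerate_columns,
    validate_dataset,
)
from .estimators import Cells, PairAssignment, align_pair, cov_from_cells, pair_cells
from .exceptions import DegenerateColumnError, UnstableStatisticError

__all__ = [
    "StatDecision",
    "EdgeRecord",
    "CausalGraph",
    "InferenceResult",
    "bootstrap_distribution",
    "percentile_ci",
    "test_nonzero",
    "infer_association_graph",
    "confounding_filter",
    "orient_edges",
    "infer_causal_graph",
]


# --------------------------------------------------------------------------
# decision containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StatDecision:
    """A bootstrap sampling distribution with its CI and test decision."""

    samples: np.ndarray
    mean: float
    ci: tuple[float, float]
    p_value: float
    reject: bool
    alternative: str  # "greater" | "two-sided"
    method: str = "percentile"
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "mean": float(self.mean),
            "ci": [float(self.ci[0]), float(self.ci[1])],
            "p": float(self.p_value),
            "reject": bool(self.reject),
            "alternative": self.alternative,
            "n_skipped": int(self.n_skipped),
        }


@dataclass
class EdgeRecord:
    """One examined variable pair with all its bootstrap decisions."""

    i: int
    j: int
    status: str  # "undirected" | "directed"
    flipped_j: bool
    dep: StatDecision | None
    odd: StatDecision | None
    dir: StatDecision | None = None
    direction: tuple[int, int] | None = None  # (cause, effect) when directed
    effect_given_cause: dict | None = None  # {"mean": .., "ci": [lo, hi]}

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)

    def to_dict(self, names: Sequence[str]) -> dict:
        out = {
            "i": self.i,
            "j": self.j,
            "names": [names[self.i], names[self.j]],
            "flipped_j": bool(self.flipped_j),
            "status": self.status,
            "dep": self.dep.to_dict() if self.dep else None,
            "odd": self.odd.to_dict() if self.odd else None,
            "dir": self.dir.to_dict() if self.dir else None,
            "direction": (
                [names[self.direction[0]], names[self.direction[1]]]
                if self.direction
                else None
            ),
            "effect_given_cause": self.effect_given_cause,
        }
        return out


@dataclass
class CausalGraph:
    """Vertex labels plus annotated directed/undirected edges."""

    names: tuple[str, ...]
    edges: list[EdgeRecord] = field(default_factory=list)

    def directed_edges(self) -> set[tuple[int, int]]:
        """Ordered (cause, effect) pairs for the directed edges."""
        return {
            e.direction for e in self.edges if e.status == "directed" and e.direction
        }

    def undirected_pairs(self) -> set[frozenset]:
        return {
            frozenset(e.pair) for e in self.edges if e.status == "undirected"
        }

    @property
    def adjacency(self) -> np.ndarray:
        """0/1 matrix, row = source.  Undirected edges marked symmetrically."""
        d = len(self.names)
        adj = np.zeros((d, d), dtype=np.int8)
        for e in self.edges:
            if e.status == "directed" and e.direction is not None:
                adj[e.direction[0], e.direction[1]] = 1
            else:
                adj[e.i, e.j] = 1
                adj[e.j, e.i] = 1
        return adj


# --------------------------------------------------------------------------
# bootstrap statistics
# --------------------------------------------------------------------------

_STATS = ("dependency", "odd_diff", "causal_dir")


def _replicate_value(
    X: np.ndarray, stat: str, i: int, j: int, flipped_j: bool,
    cond: tuple[int, int] | None,
) -> float | None:
    """Evaluate one statistic on one replicate matrix; None = skip."""
    if cond is not None:
        mask = X[:, cond[0]] == cond[1]
        if not mask.any():
            return None
        X = X[mask]
    n = X.shape[0]
    xi = X[:, i]
    xj = X[:, j]
    n11 = int(np.count_nonzero(xi & xj))
    si = int(xi.sum())
    sj = int(xj.sum())
    cells = Cells(n11, si - n11, sj - n11, n - si - sj + n11)
    if stat == "odd_diff":
        return cov_from_cells(cells)
    if flipped_j:
        cells = cells.flip_j()
    if stat == "dependency":
        return abs(cov_from_cells(cells))
    if stat == "causal_dir":
        si_a = cells.n11 + cells.n10
        sj_a = cells.n11 + cells.n01
        if si_a == 0 or sj_a == 0:
            return None
        return cells.n11 / si_a - cells.n11 / sj_a
    raise ValueError(f"unknown statistic {stat!r}; expected one of {_STATS}")


def bootstrap_distribution(
    ens: BootstrapEnsemble,
    stat: str,
    i: int,
    j: int,
    flipped_j: bool = False,
    cond: tuple[int, int] | None = None,
) -> list[float]:
    """One statistic value per replicate, in replicate order.

    Replicates on which the statistic is undefined (empty conditioning
    stratum, zero-support conditioning event for the direction statistic)
    are skipped; if more than half are skipped the sampling distribution is
    not trustworthy and an :class:`UnstableStatisticError` is raised.
    """
    values = []
    skipped = 0
    for rep in ens.replicates:
        v = _replicate_value(rep.values, stat, i, j, flipped_j, cond)
        if v is None:
            skipped += 1
        else:
            values.append(v)
    if skipped > ens.q / 2:
        raise UnstableStatisticError(
            f"statistic {stat!r} undefined on {skipped}/{ens.q} replicates"
        )
    return values


def percentile_ci(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile CI with linear interpolation between order stats."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples for a percentile CI")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [tail, 100.0 - tail], method="linear")
    return (float(lo), float(hi))


def _rank_zero_p(arr: np.ndarray, alternative: str) -> float:
    """Mann-Whitney p of the sample vs an equal-length all-zero reference."""
    if np.all(arr == 0.0):
        return 1.0
    res = sps.mannwhitneyu(
        arr, np.zeros_like(arr), alternative=alternative, method="asymptotic"
    )
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _percentile_p(arr: np.ndarray, alternative: str) -> float:
    """Sign-consistency bootstrap p-value from the strict tail fractions.

    The two-sided p is twice the smaller fraction of bootstrap samples
    strictly beyond zero, so the test rejects exactly when the sampling
    distribution is sign-consistent: essentially all nonzero mass on one
    side.  The atom at exactly zero is not counted against either side —
    statistics built from rare configurations (e.g. the covariance of a
    deterministically implied pair, a scaled count of the few exception
    rows) are bounded at zero and place genuine mass there without ever
    crossing it, which is one-sided concentration, not null-side tail.  An
    identically-zero distribution gives p = 1 (no dependence, not an
    error), so an exactly degenerate statistic never rejects.  For smooth
    statistics this coincides with the usual percentile-CI-excludes-zero
    decision at level alpha.
    """
    frac_lt = float(np.mean(arr < 0.0))
    frac_gt = float(np.mean(arr > 0.0))
    if frac_lt == 0.0 and frac_gt == 0.0:
        return 1.0
    if alternative == "greater":
        return min(1.0, 1.0 - frac_gt)
    return min(1.0, 2.0 * min(frac_lt, frac_gt))


def test_nonzero(
    samples: Sequence[float],
    alternative: str = "two-sided",
    alpha: float = 0.05,
    method: str = "percentile",
    n_skipped: int = 0,
) -> StatDecision:
    """Nonparametric decision on H0: the statistic's mean is zero.

    ``method="rank-zero"`` is the rank test against a zero reference sample;
    ``method="percentile"`` inverts the percentile bootstrap CI.  Samples
    that are all exactly zero give p = 1 (defined, not an error) under both.
    The reported CI is always the 100(1-alpha)% percentile interval.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 bootstrap samples")
    if method == "rank-zero":
        p = _rank_zero_p(arr, alternative)
    elif method == "percentile":
        p = _percentile_p(arr, alternative)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatDecision(
        samples=arr,
        mean=float(arr.mean()),
        ci=percentile_ci(arr, 1.0 - alpha),
        p_value=p,
        reject=bool(p < alpha),
        alternative=alternative,
        method=method,
        n_skipped=n_skipped,
    )


# --------------------------------------------------------------------------
# vectorized per-replicate moments (the O(d^2 n) workhorse)
# --------------------------------------------------------------------------

class _Moments:
    """Pairwise counts for every replicate, computed once and cached.

    ``S[k]`` holds column sums and ``N11[k]`` the pairwise (1,1) counts of
    replicate k; conditional counts per stratum of a variable Z are built
    lazily the first time the confounding filter asks for that Z.
    """

    def __init__(self, ens: BootstrapEnsemble):
        self.ens = ens
        self.n = ens.n
        mats = [rep.values for rep in ens.replicates]
        self._X = [m.astype(np.int64, copy=False) for m in mats]
        self.S = np.stack([m.sum(axis=0) for m in self._X])
        self.N11 = np.stack([m.T @ m for m in self._X])
        self._cond: dict[int, tuple] = {}

    def cov_samples(self, i: int, j: int) -> np.ndarray:
        """Signed covariance P̂11 − P̂1 P̂·1 of (i, j) across replicates."""
        p11 = self.N11[:, i, j] / self.n
        return p11 - (self.S[:, i] / self.n) * (self.S[:, j] / self.n)

    def cond_counts(self, z: int):
        """Per-stratum (Z=0, Z=1) column sums, pair counts and sizes."""
        if z not in self._cond:
            per_val = []
            for val in (0, 1):
                Ss, Ns, sizes = [], [], []
                for X in self._X:
                    sub = X[X[:, z] == val]
                    sizes.append(sub.shape[0])
                    if sub.shape[0]:
                        Ss.append(sub.sum(axis=0))
                        Ns.append(sub.T @ sub)
                    else:
                        d = X.shape[1]
                        Ss.append(np.zeros(d, dtype=np.int64))
                        Ns.append(np.zeros((d, d), dtype=np.int64))
                per_val.append(
                    (np.stack(Ss), np.stack(Ns), np.asarray(sizes))
                )
            self._cond[z] = tuple(per_val)
        return self._cond[z]

    def cond_cov_samples(self, i: int, j: int, z: int, val: int):
        """Signed conditional covariance of (i, j) in stratum Z=val.

        Returns (samples, n_skipped); replicates with an empty stratum are
        skipped.  The conditional dependency degree is the absolute value.
        """
        S, N, sizes = self.cond_counts(z)[val]
        keep = sizes > 0
        nz = sizes[keep].astype(float)
        p11 = N[keep, i, j] / nz
        cov = p11 - (S[keep, i] / nz) * (S[keep, j] / nz)
        return cov, int((~keep).sum())

    def dir_samples(self, pair: PairAssignment):
        """Aligned causal-direction samples and the two conditionals.

        Returns (dir, p_j_given_i, p_i_given_j, keep_mask); replicates where
        either aligned conditioning event has zero support are dropped.
        """
        i, j = pair.i, pair.j
        n11 = self.N11[:, i, j].astype(float)
        si = self.S[:, i].astype(float)
        sj = self.S[:, j].astype(float)
        if pair.flipped_j:
            n11 = si - n11
            sj = self.n - sj
        keep = (si > 0) & (sj > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pj_i = n11 / si
            pi_j = n11 / sj
        return (pj_i - pi_j)[keep], pj_i[keep], pi_j[keep], keep


# --------------------------------------------------------------------------
# the three phases
# --------------------------------------------------------------------------

def _usable_columns(ds: BinaryDataset) -> list[int]:
    cols = nondegenerate_columns(ds)
    if len(cols) < 2:
        raise DegenerateColumnError(
            "graph inference needs at least 2 non-degenerate columns"
        )
    return cols


def infer_association_graph(
    ens: BootstrapEnsemble,
    alpha: float = 0.05,
    moments: "_Moments | None" = None,
) -> list[EdgeRecord]:
    """Candidate undirected edges: pairs whose dependency and odd-difference
    statistics both test nonzero at level alpha.

    The dependency test is one-sided ("greater", rank-zero method); the odd
    difference is two-sided (percentile method).  Pairs are enumerated over
    the non-degenerate columns in lexicographic order.
    """
    ds = ens.source
    cols = _usable_columns(ds)
    mom = moments if moments is not None else _Moments(ens)
    edges: list[EdgeRecord] = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            i, j = cols[a], cols[b]
            pair = align_pair(ds, i, j)
            cov = mom.cov_samples(i, j)
            dep = test_nonzero(np.abs(cov), "greater", alpha, method="rank-zero")
            odd = test_nonzero(cov, "two-sided", alpha, method="percentile")
            if dep.reject and odd.reject:
                edges.append(
                    EdgeRecord(i=i, j=j, status="undirected",
                               flipped_j=pair.flipped_j, dep=dep, odd=odd)
                )
    return edges


def confounding_filter(
    ens: BootstrapEnsemble,
    candidates: Iterable[EdgeRecord],
    alpha: float = 0.05,
    moments: "_Moments | None" = None,
) -> tuple[list[EdgeRecord], dict[tuple[int, int], list[str]]]:
    """Drop candidates rendered conditionally independent by some Z.

    For each candidate (i, j) and each third non-degenerate variable Z, the
    signed conditional covariance is tested two-sided (percentile method) in
    each stratum Z=0 and Z=1.  A stratum is informative when it is non-empty
    in at least half of the replicates; Z screens the pair off when *no*
    informative stratum rejects — conditional independence given Z means
    independence in each stratum.  Strata made degenerate by a deterministic
    mechanism (one variable constant) have conditional covariance exactly
    zero in every replicate and therefore never reject, which is how chains
    and confounders are recognized.  Returns the surviving records plus a
    map from removed pairs to the list of screening variables.
    """
    ds = ens.source
    cols = _usable_columns(ds)
    mom = moments if moments is not None else _Moments(ens)
    kept: list[EdgeRecord] = []
    removed: dict[tuple[int, int], list[str]] = {}
    for edge in candidates:
        screens: list[str] = []
        for z in cols:
            if z in (edge.i, edge.j):
                continue
            informative = 0
            any_reject = False
            for val in (0, 1):
                samples, skipped = mom.cond_cov_samples(edge.i, edge.j, z, val)
                if samples.size < 2 or skipped > ens.q / 2:
                    continue  # uninformative stratum
                informative += 1
                dec = test_nonzero(samples, "two-sided", alpha,
                                   method="percentile", n_skipped=skipped)
                if dec.reject:
                    any_reject = True
                    break
            if informative > 0 and not any_reject:
                screens.append(ds.names[z])
        if screens:
            removed[edge.pair] = screens
        else:
            kept.append(edge)
    return kept, removed


def orient_edges(
    ens: BootstrapEnsemble,
    edges: Iterable[EdgeRecord],
    alpha: float = 0.05,
    moments: "_Moments | None" = None,
) -> CausalGraph:
    """Run the causal-direction test on each surviving edge.

    Rejection with positive mean orients i -> j, negative mean j -> i;
    failure to reject leaves the edge undirected ("dependency without causal
    relation").  Directed records carry the bootstrap mean and CI of
    P̂(effect = v | cause = v) at the aligned values, the degree of causal
    direction.
    """
    ds = ens.source
    mom = moments if moments is not None else _Moments(ens)
    graph = CausalGraph(names=ds.names)
    for edge in edges:
        pair = PairAssignment(
            i=edge.i, j=edge.j, vi=1,
            vj=0 if edge.flipped_j else 1, flipped_j=edge.flipped_j,
        )
        dir_s, pj_i, pi_j, keep = mom.dir_samples(pair)
        skipped = int((~keep).sum())
        if dir_s.size < 2 or skipped > ens.q / 2:
            edge.status = "undirected"
            graph.edges.append(edge)
            continue
        dec = test_nonzero(dir_s, "two-sided", alpha,
                           method="percentile", n_skipped=skipped)
        edge.dir = dec
        if dec.reject and dec.mean != 0.0:
            if dec.mean > 0:
                edge.direction = (edge.i, edge.j)
                effect = pj_i
            else:
                edge.direction = (edge.j, edge.i)
                effect = pi_j
            edge.status = "directed"
            edge.effect_given_cause = {
                "mean": float(effect.mean()),
                "ci": [float(v) for v in percentile_ci(effect, 1.0 - alpha)],
            }
        else:
            edge.status = "undirected"
        graph.edges.append(edge)
    graph.edges.sort(key=lambda e: (e.i, e.j))
    return graph


# --------------------------------------------------------------------------
# composed pipeline
# --------------------------------------------------------------------------

@dataclass
class InferenceResult:
    """Final graph plus everything the pipeline measured on the way."""

    graph: CausalGraph
    candidates: list[EdgeRecord]
    removed: dict[tuple[int, int], list[str]]
    report: dict

    def directed_edges(self) -> set[tuple[int, int]]:
        return self.graph.directed_edges()


def infer_causal_graph(
    ds: BinaryDataset,
    q: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> InferenceResult:
    """Full pipeline: resample, associate, filter confounding, orient.

    Deterministic for fixed ``(ds, q, alpha, seed)``.  The report lists, per
    examined pair, the dependency/odd/direction decisions with CIs, the
    alignment flip flag and skip counts, pairs sorted lexicographically.
    """
    warnings = validate_dataset(ds)
    ens = bootstrap_resample(ds, q=q, seed=seed)
    mom = _Moments(ens)
    candidates = infer_association_graph(ens, alpha, moments=mom)
    kept, removed = confounding_filter(ens, candidates, alpha, moments=mom)
    graph = orient_edges(ens, kept, alpha, moments=mom)
    report = {
        "n": ds.n,
        "d": ds.d,
        "q": q,
        "alpha": alpha,
        "seed": int(seed),
        "names": list(ds.names),
        "warnings": warnings,
        "pairs": [e.to_dict(ds.names) for e in sorted(
            candidates, key=lambda e: (e.i, e.j))],
        "removed_by_confounding": {
            f"{ds.names[i]}--{ds.names[j]}": zs
            for (i, j), zs in sorted(removed.items())
        },
        "edges": [e.to_dict(ds.names) for e in graph.edges],
    }
    return InferenceResult(graph=graph, candidates=candidates,
                           removed=removed, report=report)


def edge_table(graph: CausalGraph) -> "list[dict]":
    """Rows for the edge-list CSV export."""
    rows = []
    for e in graph.edges:
        if e.status == "directed" and e.direction is not None:
            src, dst = e.direction
        else:
            src, dst = e.i, e.j
        row = {
            "source": graph.names[src],
            "target": graph.names[dst],
            "status": e.status,
            "odd_diff_mean": e.odd.mean if e.odd else "",
            "odd_diff_lo": e.odd.ci[0] if e.odd else "",
            "odd_diff_hi": e.odd.ci[1] if e.odd else "",
            "causal_dir_mean": e.dir.mean if e.dir else "",
            "causal_dir_lo": e.dir.ci[0] if e.dir else "",
            "causal_dir_hi": e.dir.ci[1] if e.dir else "",
        }
        rows.append(row)
    return rows
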