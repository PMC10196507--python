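"""Support/confidence probability estimation and the four pairwise statistics.

All probabilities are estimated by exact integer counting with a single
division at the end, which keeps the algebraic identities (e.g. joint =
conditional x marginal) exact to floating-point rounding.

Statistics on a variable pair (Xi, Xj):

* ``dependency_degree`` — |P̂(Xi, Xj [|Z]) − P̂(Xi [|Z]) P̂(Xj [|Z])|, the
  degree of (conditional) dependency.  For binary variables this absolute
  covariance is the same number for every choice of the target values, so
  evaluating it at the aligned values loses nothing.
* ``odd_ratio`` — (P̂11 P̂00) / (P̂01 P̂10) on the raw values; > 1 means a
  positive association.
* ``odd_diff`` — P̂11 P̂00 − P̂01 P̂10, signed; algebraically identical to
  the covariance P̂11 − P̂1·P̂·1.
* ``causal_dir`` — P̂(Xj=vj | Xi=vi) − P̂(Xi=vi | Xj=vj) at the aligned
  values; a positive value is read as "Xi causes Xj" because a cause's
  active state predicts the effect's active state better than conversely.

Pair alignment complements one variable of a negatively associated pair so
that the (1,1)-type configuration carries the association; the flip is
recorded so association signs can always be reported on the raw coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .data import BinaryDataset
from .exceptions import DegenerateColumnError, UndefinedConditionalError

__all__ = [
    "PairAssignment",
    "ProbabilityEstimate",
    "OddRatio",
    "align_pair",
    "estimate_probability",
    "dependency_degree",
    "odd_ratio",
    "odd_diff",
    "causal_dir",
]


@dataclass(frozen=True)
class PairAssignment:
    """Aligned target values for a variable pair.

    ``vi`` is always 1; ``vj`` is 0 when column j was complemented
    (``flipped_j``), which happens exactly when the raw odd difference of
    (i, j) at values (1, 1) is negative.
    """

    i: int
    j: int
    vi: int
    vj: int
    flipped_j: bool

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a pair needs two distinct columns")


@dataclass(frozen=True)
class ProbabilityEstimate:
    """A support- or confidence-style probability with its exact counts."""

    value: float
    kind: str  # marginal | joint | conditional
    support_count: int
    base_count: int


class OddRatio(NamedTuple):
    value: float
    zero_cells: tuple[str, ...]  # names of the zero 2x2 cells, if any


class Cells(NamedTuple):
    """2x2 contingency counts of a pair at values (1,1)/(1,0)/(0,1)/(0,0)."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def flip_j(self) -> "Cells":
        """Counts after complementing the second variable."""
        return Cells(self.n10, self.n11, self.n00, self.n01)


def pair_cells(ds: BinaryDataset, i: int, j: int) -> Cells:
    """Exact 2x2 counts for columns (i, j)."""
    xi = ds.values[:, i]
    xj = ds.values[:, j]
    n11 = int(np.count_nonzero(xi & xj))
    si = int(xi.sum())
    sj = int(xj.sum())
    return Cells(n11, si - n11, sj - n11, ds.n - si - sj + n11)


def cov_from_cells(c: Cells) -> float:
    """P̂11 P̂00 − P̂01 P̂10 == P̂11 − P̂1·P̂·1, exact up to one division each."""
    n = c.n
    return (c.n11 / n) * (c.n00 / n) - (c.n01 / n) * (c.n10 / n)


def align_pair(ds: BinaryDataset, i: int, j: int) -> PairAssignment:
    """Choose target values so the aligned pair has non-negative odd difference.

    Complements column j (recorded in ``flipped_j``) iff the raw odd
    difference at (1, 1) is negative; a perfectly anti-correlated pair
    therefore becomes perfectly correlated after alignment.
    """
    if i == j:
        raise ValueError("a pair needs two distinct columns")
    for k in (i, j):
        s = int(ds.values[:, k].sum())
        if s == 0 or s == ds.n:
            raise DegenerateColumnError(
                f"column {ds.names[k]!r} is degenerate; alignment undefined"
            )
    flipped = cov_from_cells(pair_cells(ds, i, j)) < 0
    return PairAssignment(i=i, j=j, vi=1, vj=0 if flipped else 1,
                          flipped_j=bool(flipped))


def _match_mask(ds: BinaryDataset, assignment: Iterable[tuple[int, int]]) -> np.ndarray:
    mask = np.ones(ds.n, dtype=bool)
    for idx, val in assignment:
        if val not in (0, 1):
            raise ValueError(f"target value must be 0 or 1, got {val!r}")
        mask &= ds.values[:, idx] == val
    return mask


def estimate_probability(
    ds: BinaryDataset,
    targets: Iterable[tuple[int, int]] = (),
    given: Iterable[tuple[int, int]] = (),
) -> ProbabilityEstimate:
    """Estimate P̂(targets [| given]) by support (or confidence).

    With an empty ``given`` this is the support: the fraction of rows
    matching every (column, value) target.  With conditioning it is the
    confidence: matching rows among the rows satisfying ``given``.  An empty
    target set is the vacuous event with probability 1.
    """
    targets = list(targets)
    given = list(given)
    t_idx = {i for i, _ in targets}
    g_idx = {i for i, _ in given}
    if t_idx & g_idx:
        raise ValueError(f"target and conditioning columns overlap: {sorted(t_idx & g_idx)}")
    if given:
        base_mask = _match_mask(ds, given)
        base = int(base_mask.sum())
        if base == 0:
            names = [(ds.names[i], v) for i, v in given]
            raise UndefinedConditionalError(
                f"no row satisfies the conditioning event {names}"
            )
        support = int((_match_mask(ds, targets) & base_mask).sum())
        kind = "conditional"
    else:
        base = ds.n
        support = int(_match_mask(ds, targets).sum())
        kind = "joint" if len(targets) > 1 else "marginal"
    return ProbabilityEstimate(value=support / base, kind=kind,
                               support_count=support, base_count=base)


def _stratum(ds: BinaryDataset, cond: tuple[int, int] | None) -> BinaryDataset:
    if cond is None:
        return ds
    z, zval = cond
    mask = ds.values[:, z] == zval
    if not mask.any():
        raise UndefinedConditionalError(
            f"conditioning stratum {ds.names[z]!r}={zval} is empty"
        )
    return BinaryDataset(ds.values[mask], ds.names)


def dependency_degree(
    ds: BinaryDataset,
    pair: PairAssignment,
    cond: tuple[int, int] | None = None,
) -> float:
    """Degree of (conditional) dependency of an aligned pair, always >= 0.

    Returns |P̂(Xi=vi, Xj=vj [|Z=z]) − P̂(Xi=vi [|Z=z]) P̂(Xj=vj [|Z=z])|.
    The value is invariant to the choice of target values for binary
    variables, and is bounded above by 0.25.
    """
    if cond is not None and cond[0] in (pair.i, pair.j):
        raise ValueError("conditioning variable must differ from the pair")
    sub = _stratum(ds, cond)
    cells = pair_cells(sub, pair.i, pair.j)
    if pair.flipped_j:
        cells = cells.flip_j()
    return abs(cov_from_cells(cells))


def odd_ratio(ds: BinaryDataset, i: int, j: int) -> OddRatio:
    """Odds ratio (P̂11 P̂00)/(P̂01 P̂10) on the raw (unaligned) values.

    A zero denominator cell yields +inf together with the names of every
    zero cell; no continuity correction is applied, so data sparsity is
    visible rather than masked.
    """
    if i == j:
        raise ValueError("a pair needs two distinct columns")
    c = pair_cells(ds, i, j)
    zero = tuple(name for name, v in
                 zip(("n11", "n10", "n01", "n00"), c) if v == 0)
    if c.n01 == 0 or c.n10 == 0:
        return OddRatio(math.inf, zero)
    n = c.n
    value = ((c.n11 / n) * (c.n00 / n)) / ((c.n01 / n) * (c.n10 / n))
    return OddRatio(value, zero)


def odd_diff(ds: BinaryDataset, i: int, j: int) -> float:
    """Signed odd difference P̂11 P̂00 − P̂01 P̂10 on the raw values."""
    if i == j:
        raise ValueError("a pair needs two distinct columns")
    return cov_from_cells(pair_cells(ds, i, j))


def causal_dir(ds: BinaryDataset, pair: PairAssignment) -> float:
    """P̂(Xj=vj | Xi=vi) − P̂(Xi=vi | Xj=vj) at the aligned values.

    Positive values are read as "Xi causes Xj".  Antisymmetric under
    swapping the pair; when the aligned joint support is positive its sign
    equals the sign of P̂(Xj=vj) − P̂(Xi=vi).
    """
    p_j_given_i = estimate_probability(
        ds, targets=[(pair.j, pair.vj)], given=[(pair.i, pair.vi)]
    )
    p_i_given_j = estimate_probability(
        ds, targets=[(pair.i, pair.vi)], given=[(pair.j, pair.vj)]
    )
    return p_j_given_i.value - p_i_given_j.value
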