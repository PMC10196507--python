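"""Binary dataset container, CSV ingestion, validation and bootstrap resampling.

The whole framework operates on complete n x d matrices of {0,1} values:
rows are individuals or households, columns are binary indicators (for
example the deprivation indicators used to compute a multidimensional
poverty index).  :class:`BinaryDataset` is the single in-memory container
shared by every other module; :func:`bootstrap_resample` produces the
with-replacement replicate ensemble on which all estimation statistics are
computed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import BinaryFormatError

__all__ = [
    "BinaryDataset",
    "BootstrapEnsemble",
    "read_binary_csv",
    "validate_dataset",
    "bootstrap_resample",
    "derive_seeds",
]


@dataclass(frozen=True)
class BinaryDataset:
    """An n x d matrix of {0,1} values with unique column names.

    Parameters
    ----------
    values
        Integer matrix with every cell exactly 0 or 1.  Stored as ``int8``.
    names
        One unique, non-empty label per column.
    """

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise BinaryFormatError("values must be a 2-D matrix")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise BinaryFormatError("dataset must have at least 1 row and 1 column")
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise BinaryFormatError(
                f"cell at row {bad[0]}, column {bad[1]} is not 0 or 1"
            )
        names = tuple(str(n) for n in self.names)
        if len(names) != arr.shape[1]:
            raise BinaryFormatError(
                f"{len(names)} names for {arr.shape[1]} columns"
            )
        if any(not n for n in names):
            raise BinaryFormatError("column names must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise BinaryFormatError(f"duplicate column names: {dupes}")
        object.__setattr__(self, "values", np.ascontiguousarray(arr, dtype=np.int8))
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        """Number of rows (individuals / households)."""
        return int(self.values.shape[0])

    @property
    def d(self) -> int:
        """Number of columns (binary indicators)."""
        return int(self.values.shape[1])

    def column_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), columns=list(self.names))

    def to_csv(self, path: str | Path) -> None:
        """Write in the same dialect :func:`read_binary_csv` reads."""
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class BootstrapEnsemble:
    """q with-replacement resamples of a source :class:`BinaryDataset`.

    Every replicate has the source's shape and names, and every replicate row
    is a row of the source.  The ensemble is a pure function of
    ``(source, q, seed)``.
    """

    source: BinaryDataset
    replicates: tuple[BinaryDataset, ...]
    q: int
    seed: int = field(default=0)

    def __post_init__(self) -> None:
        if self.q != len(self.replicates):
            raise ValueError("q does not match the number of replicates")

    @property
    def n(self) -> int:
        return self.source.n

    @property
    def d(self) -> int:
        return self.source.d

    @property
    def names(self) -> tuple[str, ...]:
        return self.source.names


def read_binary_csv(path: str | Path) -> BinaryDataset:
    """Read a comma-separated file with a header row into a BinaryDataset.

    Every body cell must be exactly ``0`` or ``1``; anything else (including
    a missing cell) is rejected with an error naming the offending row and
    column.  Row order is preserved.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise BinaryFormatError(f"{path}: file is empty") from None
    header = [h.strip() for h in header]
    if any(not h for h in header):
        raise BinaryFormatError(f"{path}: blank column name in header")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise BinaryFormatError(f"{path}: duplicate column names {dupes}")
    try:
        body = pd.read_csv(path, skiprows=1, header=None, dtype=str,
                           keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise BinaryFormatError(f"{path}: no data rows below the header") from None
    if body.shape[1] != len(header):
        raise BinaryFormatError(
            f"{path}: rows have {body.shape[1]} fields, header has {len(header)}"
        )
    raw = body.to_numpy(dtype=str)
    raw = np.char.strip(raw)
    ok = np.isin(raw, ("0", "1"))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise BinaryFormatError(
            f"{path}: data row {r + 1}, column {header[c]!r}: "
            f"invalid cell {raw[r, c]!r} (must be 0 or 1)"
        )
    return BinaryDataset(raw.astype(np.int8), tuple(header))


def validate_dataset(ds: BinaryDataset) -> list[str]:
    """Return one warning per degenerate (all-0 or all-1) column.

    Degenerate columns carry no pairwise information; graph inference
    excludes them rather than failing.
    """
    warnings = []
    sums = ds.values.sum(axis=0)
    for j, s in enumerate(sums):
        if s == 0:
            warnings.append(f"column {ds.names[j]!r} is constant 0")
        elif s == ds.n:
            warnings.append(f"column {ds.names[j]!r} is constant 1")
    return warnings


def nondegenerate_columns(ds: BinaryDataset) -> list[int]:
    """Indices of columns taking both values."""
    sums = ds.values.sum(axis=0)
    return [j for j in range(ds.d) if 0 < sums[j] < ds.n]


def derive_seeds(master: int, count: int) -> list[int]:
    """Deterministically derive ``count`` independent sub-seeds (< 2**31)."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(count, dtype=np.uint64)]


def bootstrap_resample(ds: BinaryDataset, q: int = 100, seed: int = 0) -> BootstrapEnsemble:
    """Draw ``q`` with-replacement resamples of the dataset's rows.

    Replicate ``k`` uses its own deterministically derived random stream, so
    the ensemble is reproducible for a fixed ``(ds, q, seed)`` and replicates
    are mutually independent.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    children = np.random.SeedSequence(seed).spawn(q)
    replicates = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, ds.n, size=ds.n)
        replicates.append(BinaryDataset(ds.values[idx], ds.names))
    return BootstrapEnsemble(ds, tuple(replicates), q=q, seed=int(seed))
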