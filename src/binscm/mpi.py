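"""Multidimensional Poverty Index from a binary indicator matrix.

The Alkire-Foster style adjusted headcount M0 = q0 x a0: each row's
deprivation degree d_i is its fraction of active indicators (equal weights);
rows with d_i strictly above the threshold are deprived; q0 is the deprived
headcount ratio and a0 the mean deprivation degree among the deprived.
The threshold is a required parameter because the official cutoff varies
between countries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinaryDataset

__all__ = ["MPIResult", "mpi_index"]


@dataclass(frozen=True)
class MPIResult:
    deprivation_degrees: np.ndarray
    threshold: float
    q0: float
    a0: float
    m0: float

    def to_dict(self, ds: BinaryDataset | None = None) -> dict:
        out = {
            "q0": self.q0,
            "a0": self.a0,
            "m0": self.m0,
            "threshold": self.threshold,
        }
        if ds is not None:
            out["n"] = ds.n
            out["d"] = ds.d
        return out


def mpi_index(ds: BinaryDataset, threshold: float) -> MPIResult:
    """Compute M0 = q0 x a0 with strict-inequality deprivation cutoff.

    ``q0`` is the fraction of rows whose deprivation degree d_i (row mean of
    the indicators) exceeds ``threshold``; ``a0`` is the average d_i over
    those rows (0 when nobody is deprived, so m0 = 0 exactly when no row is
    deprived).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if ds.n < 1:
        raise ValueError("empty dataset")
    degrees = ds.values.mean(axis=1)
    deprived = degrees > threshold
    q0 = float(deprived.mean())
    a0 = float(degrees[deprived].mean()) if deprived.any() else 0.0
    return MPIResult(
        deprivation_degrees=degrees,
        threshold=float(threshold),
        q0=q0,
        a0=a0,
        m0=q0 * a0,
    )
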