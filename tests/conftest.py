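"""Shared fixtures: contingency-table datasets and simulated benchmark data."""

from __future__ import annotations

import numpy as np
import pytest

from binscm.data import BinaryDataset


def table_dataset(n11: int, n10: int, n01: int, n00: int,
                  names: tuple[str, str] = ("a", "b")) -> BinaryDataset:
    """Build a two-column dataset realizing exact 2x2 counts.

    Cell order is (1,1), (1,0), (0,1), (0,0) for columns (a, b).
    """
    rows = (
        [[1, 1]] * n11 + [[1, 0]] * n10 + [[0, 1]] * n01 + [[0, 0]] * n00
    )
    return BinaryDataset(np.array(rows, dtype=np.int8), names)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def table_40_10_10_40() -> BinaryDataset:
    """Positively associated pair with symmetric marginals (n=100)."""
    return table_dataset(40, 10, 10, 40)


@pytest.fixture
def table_40_0_20_40() -> BinaryDataset:
    """Asymmetric pair with a structural zero cell (n=100)."""
    return table_dataset(40, 0, 20, 40)
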