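"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ecotype.matrix import GenotypeMatrix


def make_matrix(rows: dict[str, list[str]], accessions: dict[str, str],
                marker_ids: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-sample call lists."""
    n = len(next(iter(rows.values())))
    markers = marker_ids or [f"M{j + 1}" for j in range(n)]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
    return GenotypeMatrix(frame, pd.Series(accessions))


def brute_force_ss(x: np.ndarray, acc: np.ndarray,
                   reg: np.ndarray | None = None) -> dict[str, float]:
    """Independent sums-of-squares oracle: direct group-mean decomposition.

    Computes every stratum's SS from deviations around group means on the
    encoded vectors, never touching the distance-matrix identities used
    by the implementation.
    """

    def ss_around_means(labels: np.ndarray) -> float:
        total = 0.0
        for lab in set(labels):
            sub = x[labels == lab]
            total += ((sub - sub.mean(axis=0)) ** 2).sum()
        return total

    grand = ((x - x.mean(axis=0)) ** 2).sum()
    ss_wp = ss_around_means(acc)
    out = {"total": grand, "WP": ss_wp}
    if reg is None:
        out["AP"] = grand - ss_wp
    else:
        ss_wr = ss_around_means(reg)
        out["AR"] = grand - ss_wr
        out["AP"] = ss_wr - ss_wp
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
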