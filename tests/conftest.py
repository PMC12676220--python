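import numpy as np
import pandas as pd
import pytest

from burdenval.config import (LifeExpectancyTable, SyntheticConfig,
                              default_benchmarks)
from burdenval.reference_tables import load_published_vlw


@pytest.fixture(scope="session")
def le():
    return LifeExpectancyTable()


@pytest.fixture(scope="session")
def benchmarks():
    return {b.name: b for b in default_benchmarks()}


@pytest.fixture(scope="session")
def published():
    """Published 2021 Indonesian VLW tables, tidy layout."""
    return load_published_vlw()


@pytest.fixture
def noiseless_config():
    """Factory for noise-free synthetic configs with small province counts."""
    def make(**overrides):
        defaults = dict(n_provinces=6, noise_cv=0.0, seed=7)
        defaults.update(overrides)
        return SyntheticConfig(**defaults)
    return make


def brute_force_kmeans_1d(values, k):
    """Exhaustive optimal contiguous partition of sorted 1-D values.

    Enumerates all ways to cut the sorted sequence into k contiguous
    groups and returns (labels in original order, minimal SSE).  The
    independent oracle for the clustering implementation.
    """
    from itertools import combinations

    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="stable")
    svals = arr[order]
    n = len(svals)

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    best_cost, best_bounds = np.inf, None
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = sum(sse(svals[bounds[i]:bounds[i + 1]]) for i in range(k))
        if cost < best_cost - 1e-12:
            best_cost, best_bounds = cost, bounds
    labels_sorted = np.empty(n, dtype=int)
    for i in range(k):
        labels_sorted[best_bounds[i]:best_bounds[i + 1]] = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, best_cost
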