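import numpy as np
import pandas as pd
import pytest

from sapor.descriptors import FeatureTable
from sapor.synthetic import BlockSpec, generate_block_table


@pytest.fixture(scope="session")
def block_table():
    """Default planted-block table (20 blocks x 8 features, 5 informative)."""
    return generate_block_table(BlockSpec(seed=0))


@pytest.fixture(scope="session")
def small_block_table():
    """Small separable table for fast CV tests."""
    return generate_block_table(
        BlockSpec(n_blocks=5, block_size=4, n_rows=300, informative_blocks=(0, 1), seed=3)
    )


@pytest.fixture()
def tiny_table():
    """Hand-built 6x4 feature table with one missing cell."""
    X = pd.DataFrame(
        {
            "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "b": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            "c": [1.0, 1.0, 2.0, 2.0, 3.0, np.nan],
            "d": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        },
        index=[f"m{i}" for i in range(6)],
    )
    y = pd.Series([0, 0, 0, 1, 1, 1], index=X.index)
    return FeatureTable(X, y)


# ---------------------------------------------------------------------------
# independent brute-force oracles used across test modules
# ---------------------------------------------------------------------------


def brute_force_auroc(scores, labels):
    """All positive-negative pairs; ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_ks(x, y):
    """sup |ECDF_x - ECDF_y| over the pooled sample points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.unique(np.concatenate([x, y]))
    d = 0.0
    for v in grid:
        d = max(d, abs(np.mean(x <= v) - np.mean(y <= v)))
    return d


def interpolated_percentile(values, p):
    """Linear-interpolation percentile on the sorted order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (p / 100.0) * (len(v) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])
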