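import numpy as np
import pandas as pd
import pytest

from coversample import CohortMatrix, DistanceConfig


@pytest.fixture
def line_cohort():
    """1-D cohort at coordinates {0, 1, 2, 3}."""
    return CohortMatrix.from_array(np.array([[0.0], [1.0], [2.0], [3.0]]))


@pytest.fixture
def raw_cfg():
    """Euclidean distance on raw coordinates, coverage range n=1..2."""
    return DistanceConfig(standardize=False, n_lo=1, n_hi=2)


@pytest.fixture
def mixed_cohort():
    """Two rows, one numeric + one categorical feature, for Gower checks."""
    df = pd.DataFrame({"num": [0.0, 5.0, 10.0], "cat": ["a", "b", "a"]})
    return CohortMatrix(df, {"num": "numeric", "cat": "categorical"})


def random_cohort(rng, n_max=50, p_max=5):
    n = int(rng.integers(4, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    return CohortMatrix.from_array(rng.normal(size=(n, p)))


def brute_nth_nn(X, sample, n, metric="euclidean"):
    """Independent oracle: O(N * |sample|) enumeration of nth NN distances."""
    total = 0.0
    for i in range(X.shape[0]):
        d = []
        for j in sample:
            diff = X[i] - X[j]
            if metric == "euclidean":
                d.append(float(np.sqrt((diff**2).sum())))
            elif metric == "manhattan":
                d.append(float(np.abs(diff).sum()))
            else:
                raise ValueError(metric)
        total += sorted(d)[n - 1]
    return total
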