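"""Pairwise distances and the nth nearest neighbor coverage metric.

The coverage of a candidate sample S for a cohort of N patients is scored by
the nth nearest neighbor distance

    sum_{i=1..N} d_i^(n)

where d_i^(n) is the distance from cohort member i to the nth closest member
of S.  Sampled members count themselves (distance 0 at n=1).  Lower totals
mean every patient has a nearby sampled representative, i.e. better coverage.
Averaging the totals over a range of n (default 1..10) gives the selection
criterion; the sum is non-decreasing in n, so profiles over n are monotone.

All computations are exact (full pairwise distances, order statistics by
partial sort); no approximate nearest-neighbor index is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .cohort import CohortMatrix, DistanceConfig

logger = logging.getLogger("coversample")


@dataclass(frozen=True)
class DistanceProfile:
    """Total nth NN distance for n = 1..n_max; non-decreasing in n."""

    per_n: np.ndarray
    n_max: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_n", np.asarray(self.per_n, dtype=float))
        if len(self.per_n) != self.n_max:
            raise ValueError("per_n length must equal n_max")


def _standardized_numeric(cohort: CohortMatrix, cfg: DistanceConfig) -> np.ndarray:
    """Numeric feature matrix for euclidean/manhattan, optionally z-scored.

    Standardization uses the full cohort's mean/SD so that sub-blocks of the
    pairwise matrix are consistent.  Zero-variance columns are dropped (their
    z-score is undefined) with a logged warning.
    """
    if cohort.categorical_columns:
        raise ValueError(
            f"metric {cfg.metric!r} does not accept categorical columns "
            f"{cohort.categorical_columns}; use metric='gower' for mixed data"
        )
    X = cohort.numeric_values()
    if not cfg.standardize:
        return X
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cohort.numeric_columns, keep) if not k]
        logger.warning("dropping zero-variance columns from distance: %s", dropped)
        if not keep.any():
            raise ValueError("all numeric columns have zero variance; cannot standardize")
    X = X[:, keep]
    return (X - X.mean(axis=0)) / sd[keep]


def _gower_matrix(cohort: CohortMatrix, rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Gower dissimilarity: per-feature scores averaged with equal weight.

    Numeric features contribute |a-b| / range (range over the full cohort;
    zero-range columns contribute 0); categorical features contribute the
    mismatch indicator.  Values lie in [0, 1].
    """
    num_cols = cohort.numeric_columns
    cat_cols = cohort.categorical_columns
    p = len(num_cols) + len(cat_cols)
    total = np.zeros((len(rows_a), len(rows_b)))
    if num_cols:
        X = cohort.data[num_cols].to_numpy(dtype=float)
        rng = X.max(axis=0) - X.min(axis=0)
        zero = rng == 0
        if zero.any():
            logger.warning(
                "gower: zero-range numeric columns contribute 0: %s",
                [c for c, z in zip(num_cols, zero) if z],
            )
        rng = np.where(zero, 1.0, rng)
        scaled = X / rng
        total += cdist(scaled[rows_a], scaled[rows_b], metric="cityblock")
    for col in cat_cols:
        vals = cohort.data[col].to_numpy()
        total += vals[rows_a][:, None] != vals[rows_b][None, :]
    return total / p


def _resolve_rows(cohort: CohortMatrix, rows) -> np.ndarray:
    if rows is None:
        return np.arange(cohort.n)
    rows = np.asarray(list(rows) if not isinstance(rows, np.ndarray) else rows, dtype=int)
    if rows.size and (rows.min() < 0 or rows.max() >= cohort.n):
        raise IndexError(f"row indices out of range for cohort of size {cohort.n}")
    return rows


def pairwise_distance(
    cohort: CohortMatrix,
    rows_a=None,
    rows_b=None,
    cfg: DistanceConfig = DistanceConfig(),
) -> np.ndarray:
    """Distance matrix between two row subsets of the cohort.

    ``rows_a``/``rows_b`` default to all rows.  Standardization and Gower
    ranges are always computed on the full cohort, so distances between any
    two rows do not depend on which subsets are requested.
    """
    ra = _resolve_rows(cohort, rows_a)
    rb = _resolve_rows(cohort, rows_b)
    if cfg.metric == "gower":
        return _gower_matrix(cohort, ra, rb)
    X = _standardized_numeric(cohort, cfg)
    scipy_name = {"euclidean": "euclidean", "manhattan": "cityblock"}[cfg.metric]
    return cdist(X[ra], X[rb], metric=scipy_name)


def _check_sample(sample: np.ndarray, n: int) -> None:
    if sample.size == 0:
        raise ValueError("sample is empty")
    if n < 1 or n > sample.size:
        raise ValueError(f"n={n} must satisfy 1 <= n <= sample size {sample.size}")


def _nth_totals_from_D(D: np.ndarray, n_max: int) -> np.ndarray:
    """Totals of the 1st..n_max-th order statistics of each row of D."""
    if n_max == D.shape[1]:
        smallest = np.sort(D, axis=1)
    else:
        smallest = np.sort(np.partition(D, n_max - 1, axis=1)[:, :n_max], axis=1)
    return smallest[:, :n_max].sum(axis=0)


def nth_nn_distance(cohort: CohortMatrix, sample, n: int, cfg: DistanceConfig = DistanceConfig()) -> float:
    """Total distance from every cohort member to its nth nearest sampled member.

    The sum runs over all N cohort rows, sampled ones included: a sampled
    member's own presence in the sample counts as its 1st nearest neighbor at
    distance 0.  Ties in the neighbor ordering are immaterial because only
    the nth order statistic of the distance multiset is used.
    """
    sample = _resolve_rows(cohort, sample)
    _check_sample(sample, n)
    D = pairwise_distance(cohort, None, sample, cfg)
    return float(np.partition(D, n - 1, axis=1)[:, n - 1].sum())


def mean_nn_distance(cohort: CohortMatrix, sample, cfg: DistanceConfig = DistanceConfig()) -> float:
    """Mean of the nth NN distance over n = cfg.n_lo .. cfg.n_hi.

    This is the default sample-selection criterion; averaging over a range of
    n makes the score insensitive to the exact choice of n.
    """
    sample = _resolve_rows(cohort, sample)
    _check_sample(sample, cfg.n_hi)
    D = pairwise_distance(cohort, None, sample, cfg)
    totals = _nth_totals_from_D(D, cfg.n_hi)
    return float(totals[cfg.n_lo - 1 : cfg.n_hi].mean())


def nn_distance_profile(
    cohort: CohortMatrix, sample, n_max: int, cfg: DistanceConfig = DistanceConfig()
) -> DistanceProfile:
    """nth NN distance for every n = 1..n_max (the curves plotted per sample)."""
    sample = _resolve_rows(cohort, sample)
    _check_sample(sample, n_max)
    D = pairwise_distance(cohort, None, sample, cfg)
    return DistanceProfile(per_n=_nth_totals_from_D(D, n_max), n_max=n_max)
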