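"""Cluster-stratified sample pools and coverage-optimal selection.

The selection procedure: cluster the cohort at each k in a grid, draw R
stratified samples (equal allocation across clusters) per k to form a pool,
score every pool member with the mean nth nearest neighbor distance, and
keep the member with the smallest score.  Random and truth-cluster samples
are provided as baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .cohort import CohortMatrix, DistanceConfig
from .distance import _nth_totals_from_D, _standardized_numeric, pairwise_distance

logger = logging.getLogger("coversample")

# cohorts up to this size get one full pairwise matrix shared by all pool
# members during selection (N=6000 doubles is ~288 MB transient)
_FULL_MATRIX_MAX_N = 6000


@dataclass
class ClusterModel:
    """Cluster labels for every cohort row, in 1..k."""

    labels: np.ndarray
    k: int
    method: str
    linkage: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")

    def sizes(self) -> np.ndarray:
        """Cluster sizes indexed by cluster id - 1 (may contain zeros)."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


@dataclass(frozen=True)
class SamplingConfig:
    """Pool-generation settings.

    ``m`` is the chart-review budget; ``k_grid`` the cluster counts explored;
    ``replications`` the stratified draws per k.  The default grid {2,3,4,5}
    reflects that very large k (10+) degrades coverage performance; pass the
    wide grid explicitly for sensitivity analyses.
    """

    m: int = 120
    k_grid: Sequence[int] = (2, 3, 4, 5)
    replications: int = 100
    seed: int = 0
    method: str = "hierarchical"
    linkage: str = "ward"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be positive")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if any(k < 1 for k in self.k_grid):
            raise ValueError("k_grid values must be >= 1")
        if self.method not in ("hierarchical", "kmeans"):
            raise ValueError(f"unknown clustering method {self.method!r}")


@dataclass
class SampleSelection:
    """A candidate chart-review sample: row indices plus provenance."""

    indices: np.ndarray
    provenance: dict = field(default_factory=dict)
    metric_value: float | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("sample indices must be unique")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _feature_space(cohort: CohortMatrix, cfg: DistanceConfig) -> np.ndarray:
    """Coordinates used for Ward/k-means clustering (standardized numeric)."""
    return _standardized_numeric(cohort, replace(cfg, metric="euclidean"))


def hierarchical_tree(cohort: CohortMatrix, cfg: DistanceConfig, method: str = "ward") -> np.ndarray:
    """Build the linkage matrix once; cut it at several k with :func:`cut_tree_at`.

    Ward requires euclidean geometry and works from standardized coordinates;
    complete/average linkage work from the pairwise matrix of any configured
    metric (including gower), so mixed-type cohorts cluster through gower +
    complete/average.
    """
    if method == "ward":
        if cfg.metric != "euclidean":
            raise ValueError("ward linkage requires the euclidean metric; use complete or average")
        return scipy_linkage(_feature_space(cohort, cfg), method="ward")
    if method not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    D = pairwise_distance(cohort, None, None, cfg)
    return scipy_linkage(squareform(D, checks=False), method=method)


def cut_tree_at(Z: np.ndarray, k: int, method: str, cfg_linkage: str) -> ClusterModel:
    labels = fcluster(Z, t=k, criterion="maxclust")
    realized = len(np.unique(labels))
    if realized < k:
        # degenerate cohort (duplicate rows): the dendrogram cannot separate k
        # groups; keep the deterministic cut and relabel into 1..realized
        logger.warning("hierarchical cut produced %d < k=%d clusters (degenerate cohort)", realized, k)
        labels = np.unique(labels, return_inverse=True)[1] + 1
        k = realized
    return ClusterModel(labels=labels, k=k, method=method, linkage=cfg_linkage)


def fit_clusters(
    cohort: CohortMatrix,
    k: int,
    method: str = "hierarchical",
    cfg: DistanceConfig = DistanceConfig(),
    linkage: str = "ward",
    seed: int = 0,
) -> ClusterModel:
    """Cluster the cohort into k groups.

    Hierarchical clustering is deterministic given linkage and metric;
    k-means is deterministic given the seed.  Empty k-means clusters trigger
    re-initialization with the next derived seed (up to 10 attempts).
    """
    if not 1 <= k <= cohort.n:
        raise ValueError(f"k={k} must lie in 1..N={cohort.n}")
    if method == "hierarchical":
        if k == cohort.n:
            return ClusterModel(np.arange(1, cohort.n + 1), k, method, linkage)
        Z = hierarchical_tree(cohort, cfg, linkage)
        return cut_tree_at(Z, k, method, linkage)
    if method == "kmeans":
        X = _feature_space(cohort, cfg)
        for attempt in range(10):
            state = int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0] % (2**31))
            try:
                km = KMeans(n_clusters=k, random_state=state, n_init=10).fit(X)
            except ValueError as err:  # fewer distinct points than clusters
                raise ValueError(f"k-means failed for k={k}: {err}") from err
            labels = km.labels_ + 1
            if len(np.unique(labels)) == k:
                return ClusterModel(labels, k, method, seed=seed)
            logger.warning("k-means attempt %d produced an empty cluster; re-seeding", attempt)
        raise RuntimeError(f"k-means produced empty clusters in 10 attempts for k={k}")
    raise ValueError(f"unknown clustering method {method!r}")


# ---------------------------------------------------------------------------
# allocation and draws
# ---------------------------------------------------------------------------

def allocate_quota(cluster_sizes, m: int) -> np.ndarray:
    """Equal per-cluster quotas summing to m.

    Each cluster receives floor(m/k); the remainder goes one-each to the
    largest clusters (ties to the lowest cluster id).  A cluster whose quota
    would exceed its size contributes all its members and the shortfall is
    redistributed over the remaining clusters by the same rule, iterating
    until feasible.  Equal (not proportional) allocation is deliberate: the
    aim is even subgroup representation, e.g. 100 charts over 4 clusters ->
    25 from each regardless of cluster size.
    """
    sizes = np.asarray(cluster_sizes, dtype=int)
    if (sizes < 0).any():
        raise ValueError("cluster sizes must be non-negative")
    if m > sizes.sum():
        raise ValueError(f"cannot allocate m={m} over clusters totalling {sizes.sum()}")
    quota = np.zeros(len(sizes), dtype=int)
    active = [j for j in range(len(sizes)) if sizes[j] > 0]
    remaining = m
    while remaining > 0:
        base, rem = divmod(remaining, len(active))
        extra = set(sorted(active, key=lambda j: (-sizes[j], j))[:rem])
        want = {j: base + (1 if j in extra else 0) for j in active}
        capped = [j for j in active if quota[j] + want[j] >= sizes[j]]
        if not capped:
            for j in active:
                quota[j] += want[j]
            remaining = 0
        else:
            for j in capped:
                remaining -= sizes[j] - quota[j]
                quota[j] = sizes[j]
                active.remove(j)
    return quota


def stratified_sample(cluster: ClusterModel, quota, rng: np.random.Generator) -> np.ndarray:
    """Draw quota[j] indices uniformly without replacement within cluster j."""
    quota = np.asarray(quota, dtype=int)
    if len(quota) != cluster.k:
        raise ValueError("quota length must equal k")
    out = []
    for j in range(cluster.k):
        members = np.flatnonzero(cluster.labels == j + 1)
        if quota[j] > len(members):
            raise ValueError(f"quota {quota[j]} exceeds cluster {j + 1} size {len(members)}")
        if quota[j]:
            out.append(rng.choice(members, size=quota[j], replace=False))
    return np.sort(np.concatenate(out)) if out else np.empty(0, dtype=int)


def random_sample(N: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Simple random sample of m of N rows without replacement (the usual
    chart-review default and the benchmark baseline)."""
    if m > N:
        raise ValueError(f"m={m} exceeds N={N}")
    return np.sort(rng.choice(N, size=m, replace=False))


def truth_sample(true_labels, m: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified sample on the known generating clusters (simulation only)."""
    labels = np.asarray(true_labels, dtype=int)
    uniq = np.unique(labels)
    remap = {c: i + 1 for i, c in enumerate(uniq)}
    relabeled = np.array([remap[c] for c in labels])
    model = ClusterModel(relabeled, k=len(uniq), method="provided")
    quota = allocate_quota(model.sizes(), m)
    return stratified_sample(model, quota, rng)


# ---------------------------------------------------------------------------
# pool generation and optimal selection
# ---------------------------------------------------------------------------

def _child_rng(master_seed: int, k: int, replicate: int) -> np.random.Generator:
    # documented derivation: every (k, replicate) stream is re-derivable in
    # isolation from the master seed
    return np.random.default_rng(np.random.SeedSequence([master_seed, k, replicate]))


def generate_sample_pool(
    cohort: CohortMatrix,
    sampling_cfg: SamplingConfig,
    dist_cfg: DistanceConfig = DistanceConfig(),
) -> list[SampleSelection]:
    """The candidate pool: |k_grid| x replications stratified samples.

    For hierarchical clustering one dendrogram is built and cut at every k in
    the grid (equivalent to refitting, much cheaper); k-means is refit per k
    with a derived seed.  Each (k, replicate) draw uses an independently
    derived child generator, so the pool is reproducible from the master seed
    and any single member can be re-derived.
    """
    pool: list[SampleSelection] = []
    Z = None
    if sampling_cfg.method == "hierarchical":
        Z = hierarchical_tree(cohort, dist_cfg, sampling_cfg.linkage)
    for k in sampling_cfg.k_grid:
        if sampling_cfg.method == "hierarchical":
            model = cut_tree_at(Z, k, "hierarchical", sampling_cfg.linkage)
        else:
            kseed = int(np.random.SeedSequence([sampling_cfg.seed, k]).generate_state(1)[0] % (2**31))
            model = fit_clusters(cohort, k, "kmeans", dist_cfg, seed=kseed)
        quota = allocate_quota(model.sizes(), sampling_cfg.m)
        for r in range(sampling_cfg.replications):
            rng = _child_rng(sampling_cfg.seed, k, r)
            idx = stratified_sample(model, quota, rng)
            pool.append(
                SampleSelection(
                    indices=idx,
                    provenance={
                        "method": sampling_cfg.method,
                        "k": int(k),
                        "replicate": int(r),
                        "seed": int(sampling_cfg.seed),
                    },
                )
            )
    return pool


def select_optimal(
    pool: list[SampleSelection],
    cohort: CohortMatrix,
    dist_cfg: DistanceConfig = DistanceConfig(),
) -> SampleSelection:
    """Score every pool member and return the one with minimal coverage score.

    The score is the mean nth NN distance over cfg.n_lo..n_hi; ties go to the
    earliest pool position.  For cohorts up to ~6000 rows the full pairwise
    matrix is computed once and column-sliced per member, which makes scoring
    a pool of hundreds of candidates cheap.
    """
    if not pool:
        raise ValueError("empty sample pool")
    sl = slice(dist_cfg.n_lo - 1, dist_cfg.n_hi)
    D_full = pairwise_distance(cohort, None, None, dist_cfg) if cohort.n <= _FULL_MATRIX_MAX_N else None
    for sel in pool:
        if dist_cfg.n_hi > sel.indices.size:
            raise ValueError(f"n_hi={dist_cfg.n_hi} exceeds sample size {sel.indices.size}")
        D = D_full[:, sel.indices] if D_full is not None else pairwise_distance(cohort, None, sel.indices, dist_cfg)
        sel.metric_value = float(_nth_totals_from_D(D, dist_cfg.n_hi)[sl].mean())
    best = int(np.argmin([sel.metric_value for sel in pool]))
    chosen = pool[best]
    logger.info(
        "selected pool member %d (k=%s, replicate=%s) with coverage score %.4f over %d candidates",
        best, chosen.provenance.get("k"), chosen.provenance.get("replicate"),
        chosen.metric_value, len(pool),
    )
    return chosen


def coverage_sample(
    cohort: CohortMatrix,
    sampling_cfg: SamplingConfig,
    dist_cfg: DistanceConfig = DistanceConfig(),
) -> SampleSelection:
    """One-shot convenience: generate the pool and return the optimal member."""
    return select_optimal(generate_sample_pool(cohort, sampling_cfg, dist_cfg), cohort, dist_cfg)
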