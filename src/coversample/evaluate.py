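"""Computable-phenotype fitting, AUROC evaluation, balance diagnostics and
the sampling-method benchmark.

The evaluation contract mirrors how chart-review samples are judged in
practice: fit a probabilistic phenotype model (logistic regression, plain or
LASSO) on the labeled sample, score every *unsampled* patient, and compare
discrimination (AUROC, overall and within subgroups) across sampling
strategies.  Standardized mean differences quantify how demographically
balanced competing samples are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score

from .cohort import CohortMatrix, DistanceConfig
from .distance import mean_nn_distance
from .sampling import SamplingConfig, coverage_sample, random_sample, truth_sample
from .simulate import OutcomeModelSpec, ScenarioSpec, simulate_features, simulate_outcomes

logger = logging.getLogger("coversample")


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# computable phenotype model
# ---------------------------------------------------------------------------

@dataclass
class CPModel:
    """Fitted probabilistic computable phenotype (logistic form)."""

    intercept: float
    coefficients: np.ndarray
    regularization: str = "none"
    penalty: float = 0.0
    training_ids: np.ndarray | None = None

    def predict_proba(self, features) -> np.ndarray:
        X = features.numeric_values() if isinstance(features, CohortMatrix) else np.asarray(features, float)
        return expit(self.intercept + X @ self.coefficients)


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, CohortMatrix):
        return features.numeric_values()
    return np.asarray(features, dtype=float)


def fit_cp(
    features,
    outcomes,
    regularization: str = "none",
    penalty: float = 1.0,
    max_iter: int = 2000,
    cv_seed: int = 0,
) -> CPModel:
    """Fit a logistic computable phenotype on a labeled sample.

    ``regularization``:
      * ``"none"`` — plain maximum likelihood (the simulation default);
      * ``"l1"``   — LASSO at the given penalty strength (lambda = penalty);
      * ``"l1-cv"``— LASSO with the penalty chosen by 5-fold cross-validation
        on the training sample, deterministic given ``cv_seed`` (the
        real-data workflow).

    Raises if the training labels are single-class or the optimizer fails to
    converge.
    """
    X = _as_matrix(features)
    y = np.asarray(outcomes, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training outcomes contain a single class ({classes[0]}); need both cases and controls")
    if regularization == "none":
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter)
    elif regularization == "l1":
        est = LogisticRegression(l1_ratio=1, C=1.0 / penalty, solver="liblinear",
                                 max_iter=max_iter, random_state=0)
    elif regularization == "l1-cv":
        est = LogisticRegressionCV(l1_ratios=(1.0,), solver="liblinear", cv=5, Cs=10,
                                   max_iter=max_iter, random_state=cv_seed,
                                   scoring="neg_log_loss", use_legacy_attributes=False)
    else:
        raise ValueError(f"unknown regularization {regularization!r}")
    est.fit(X, y)
    n_iter = int(np.max(est.n_iter_))
    if n_iter >= max_iter:
        raise ConvergenceError(f"logistic fit did not converge within {max_iter} iterations")
    if regularization == "l1-cv":
        penalty = float(1.0 / np.atleast_1d(est.C_)[0])
    return CPModel(
        intercept=float(est.intercept_[0]),
        coefficients=est.coef_.ravel().copy(),
        regularization=regularization,
        penalty=penalty if regularization != "none" else 0.0,
    )


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Probability a random case outscores a random control, ties count 1/2."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auroc_ci(
    scores, labels, n_boot: int = 1000, rng: np.random.Generator | None = None, level: float = 0.95
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI: cases and controls are resampled
    separately so every replicate keeps both classes."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if rng is None:
        rng = np.random.default_rng(0)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC CI requires both classes present")
    cases = s[y == 1]
    controls = s[y == 0]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        bc = rng.choice(cases, size=len(cases), replace=True)
        bn = rng.choice(controls, size=len(controls), replace=True)
        # Mann-Whitney on the two resampled score sets
        vals[b] = stats.mannwhitneyu(bc, bn)[0] / (len(bc) * len(bn))
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def subgroup_auroc(
    scores, labels, groups, n_boot: int = 1000, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """AUROC with CI within each subgroup independently.

    Groups whose test labels are single-class are reported with NaN AUROC
    (not evaluable) rather than raising — tiny demographic strata routinely
    contain only controls.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    g = np.asarray(groups)
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for grp in pd.unique(g):
        mask = g == grp
        row = {"group": grp, "n": int(mask.sum()), "n_cases": int(y[mask].sum())}
        if len(np.unique(y[mask])) < 2:
            row.update(auroc=np.nan, ci_lo=np.nan, ci_hi=np.nan)
        else:
            row["auroc"] = auroc(s[mask], y[mask])
            row["ci_lo"], row["ci_hi"] = auroc_ci(s[mask], y[mask], n_boot=n_boot, rng=rng)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------

def smd(prop_a: float, prop_b: float) -> float:
    """Standardized mean difference for a binary variable observed at
    prevalence ``prop_a`` in one sample and ``prop_b`` in the other."""
    for p_ in (prop_a, prop_b):
        if not 0.0 <= p_ <= 1.0:
            raise ValueError(f"proportion {p_} outside [0, 1]")
    denom = np.sqrt((prop_a * (1 - prop_a) + prop_b * (1 - prop_b)) / 2.0)
    if denom == 0.0:
        return 0.0 if prop_a == prop_b else float("inf")
    return float(abs(prop_a - prop_b) / denom)


def smd_multilevel(props_a, props_b) -> float:
    """Mahalanobis-type SMD for a categorical variable with L levels.

    Uses the first L-1 level proportions with the averaged multinomial
    covariance S = (S_a + S_b)/2, S_x = diag(p_x) - p_x p_x^T:
    d = sqrt(T' S^-1 T), T = p_a - p_b.  Reduces to the binary form at L=2.
    A pseudo-inverse is used (with a logged note) when S is singular, e.g.
    when a level is absent from both samples.
    """
    pa = np.asarray(props_a, dtype=float)
    pb = np.asarray(props_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("proportion vectors must have equal length")
    for v in (pa, pb):
        if abs(v.sum() - 1.0) > 1e-6 or (v < 0).any():
            raise ValueError("each proportion vector must be non-negative and sum to 1")
    T = (pa - pb)[:-1]
    cov = lambda p: np.diag(p[:-1]) - np.outer(p[:-1], p[:-1])
    S = 0.5 * (cov(pa) + cov(pb))
    try:
        sol = np.linalg.solve(S, T)
    except np.linalg.LinAlgError:
        logger.warning("singular covariance in multi-level SMD; using pseudo-inverse")
        sol = np.linalg.pinv(S) @ T
    return float(np.sqrt(T @ sol))


def balance_table(demographics: pd.DataFrame, idx_a, idx_b, variables=None) -> pd.DataFrame:
    """Per-variable level proportions in two samples plus one SMD per variable.

    Binary variables use the pooled-variance form, multi-level ones the
    Mahalanobis form; levels are taken as the union observed in the full
    table so the two samples are compared on a common support.
    """
    variables = list(variables) if variables is not None else list(demographics.columns)
    rows = []
    for var in variables:
        levels = pd.unique(demographics[var].dropna())
        pa = np.array([(demographics[var].iloc[idx_a] == lv).mean() for lv in levels])
        pb = np.array([(demographics[var].iloc[idx_b] == lv).mean() for lv in levels])
        d = smd(pa[0], pb[0]) if len(levels) == 2 else smd_multilevel(pa, pb)
        for i, lv in enumerate(levels):
            rows.append({"variable": var, "level": lv, "prop_a": pa[i], "prop_b": pb[i],
                         "smd": d if i == 0 else np.nan})
    return pd.DataFrame(rows)


def compare_methods(paired_aurocs_a, paired_aurocs_b) -> float:
    """Two-sided paired t-test p-value on per-dataset AUROC differences.

    Degenerate zero-variance differences are flagged in the log and return
    p=1 when all differences are 0 (no evidence of any difference) or p=0
    when they are identical and nonzero.
    """
    a = np.asarray(paired_aurocs_a, dtype=float)
    b = np.asarray(paired_aurocs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of at least 2 paired values")
    d = a - b
    if np.ptp(d) == 0.0:
        logger.warning("zero-variance paired differences (all equal to %g); degenerate test", d[0])
        return 1.0 if d[0] == 0.0 else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Across-dataset summary of the sampling-method benchmark.

    ``summary`` has one row per (method, scope): mean coverage score, mean
    AUROC, 95% across-dataset CI, and the paired p-value vs the random
    baseline for overall rows.  ``per_dataset`` holds the raw per-dataset
    results the summary aggregates.
    """

    summary: pd.DataFrame
    per_dataset: pd.DataFrame
    n_datasets: int
    n_skipped: int = 0
    p_values: dict = field(default_factory=dict)


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    v = np.asarray(values, float)
    m, se = v.mean(), v.std(ddof=1) / np.sqrt(len(v))
    half = stats.t.ppf(0.5 + level / 2, len(v) - 1) * se
    return float(m - half), float(m + half)


_BENCH_METHODS = ("hierarchical", "kmeans", "random", "truth")
# stable per-method tags for seed derivation (str hash is process-randomized)
_METHOD_TAG = {m: i + 1 for i, m in enumerate(_BENCH_METHODS)}


def _draw_sample(method, cohort, labels, sampling_cfg, dist_cfg, seed_seq):
    if method in ("hierarchical", "kmeans"):
        cfg = SamplingConfig(
            m=sampling_cfg.m, k_grid=sampling_cfg.k_grid, replications=sampling_cfg.replications,
            seed=int(seed_seq.generate_state(1)[0] % (2**31)), method=method,
            linkage=sampling_cfg.linkage,
        )
        return coverage_sample(cohort, cfg, dist_cfg).indices
    rng = np.random.default_rng(seed_seq)
    if method == "random":
        return random_sample(cohort.n, sampling_cfg.m, rng)
    if method == "truth":
        return truth_sample(labels, sampling_cfg.m, rng)
    raise ValueError(f"unknown benchmark method {method!r}")


def run_benchmark(
    scenario: ScenarioSpec,
    outcome: OutcomeModelSpec,
    n_datasets: int,
    m: int = 120,
    sampling_cfg: SamplingConfig | None = None,
    dist_cfg: DistanceConfig = DistanceConfig(),
    seed: int = 0,
    methods: tuple[str, ...] = _BENCH_METHODS,
) -> EvalReport:
    """Simulate n_datasets cohorts and benchmark sampling strategies on each.

    Per dataset: realize features and outcomes, draw one sample of size m per
    method, fit an unpenalized logistic phenotype on each sample, score all
    unsampled rows, and record the coverage score of the sample plus overall
    and per-true-cluster AUROCs on the test rows.  Datasets whose samples
    remain single-class after 5 redraws are skipped (logged) for all methods
    to preserve pairing.  The truth baseline is dropped automatically when
    the scenario has a single effective cluster.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    if m > scenario.N:
        raise ValueError(f"m={m} exceeds cohort size N={scenario.N}")
    if sampling_cfg is None:
        sampling_cfg = SamplingConfig(m=m)
    effective_clusters = int((scenario.proportions > 0).sum())
    methods = tuple(methods)
    if effective_clusters == 1 and "truth" in methods:
        methods = tuple(mth for mth in methods if mth != "truth")

    records = []
    n_skipped = 0
    for d in range(n_datasets):
        root = np.random.SeedSequence([seed, d])
        data_rng = np.random.default_rng(root.spawn(1)[0])
        sim = simulate_features(scenario, data_rng)
        y = simulate_outcomes(sim, outcome, data_rng)
        dataset_rows, skip = [], False
        for method in methods:
            fitted = None
            for attempt in range(5):
                idx = _draw_sample(method, sim.features, sim.cluster_labels, sampling_cfg,
                                   dist_cfg, np.random.SeedSequence([seed, d, attempt, _METHOD_TAG[method]]))
                if len(np.unique(y[idx])) < 2:
                    logger.warning("dataset %d method %s: single-class sample, redrawing (attempt %d)",
                                   d, method, attempt + 1)
                    continue
                try:
                    fitted = fit_cp(sim.features.numeric_values()[idx], y[idx], "none")
                except ConvergenceError:
                    logger.warning("dataset %d method %s: non-convergent fit, redrawing", d, method)
                    continue
                break
            if fitted is None:
                skip = True
                break
            test = np.setdiff1d(np.arange(scenario.N), idx)
            scores = fitted.predict_proba(sim.features.numeric_values()[test])
            row = {
                "dataset": d,
                "method": method,
                "mean_nn_distance": mean_nn_distance(sim.features, idx, dist_cfg),
                "auroc_overall": auroc(scores, y[test]),
            }
            if effective_clusters > 1:
                for j in range(1, scenario.k + 1):
                    if scenario.proportions[j - 1] == 0:
                        continue
                    gmask = sim.cluster_labels[test] == j
                    row[f"auroc_cluster_{j}"] = (
                        auroc(scores[gmask], y[test][gmask])
                        if len(np.unique(y[test][gmask])) >= 2 else np.nan
                    )
            dataset_rows.append(row)
        if skip:
            n_skipped += 1
            logger.warning("dataset %d skipped entirely (unfittable sample)", d)
            continue
        records.extend(dataset_rows)

    per_dataset = pd.DataFrame(records)
    if per_dataset.empty:
        raise RuntimeError("all datasets were skipped; cannot summarize")

    auroc_cols = [c for c in per_dataset.columns if c.startswith("auroc_")]
    summary_rows, p_values = [], {}
    for method in methods:
        sub = per_dataset[per_dataset["method"] == method]
        for col in auroc_cols:
            vals = sub[col].dropna().to_numpy()
            if len(vals) == 0:
                continue
            lo, hi = _t_ci(vals)
            summary_rows.append({
                "method": method,
                "scope": col.replace("auroc_", ""),
                "mean_nn_distance": sub["mean_nn_distance"].mean() if col == "auroc_overall" else np.nan,
                "auroc": vals.mean(), "ci_lo": lo, "ci_hi": hi,
            })
        if method != "random" and "random" in methods:
            merged = sub.merge(per_dataset[per_dataset["method"] == "random"],
                               on="dataset", suffixes=("", "_rand"))
            p_values[method] = compare_methods(merged["auroc_overall"], merged["auroc_overall_rand"])
    summary = pd.DataFrame(summary_rows)
    summary["p_vs_random"] = [
        p_values.get(r.method, np.nan) if r.scope == "overall" else np.nan for r in summary.itertuples()
    ]
    return EvalReport(summary=summary, per_dataset=per_dataset,
                      n_datasets=n_datasets, n_skipped=n_skipped, p_values=p_values)
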