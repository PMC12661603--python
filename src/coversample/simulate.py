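"""Clustered-cohort simulator with logistic phenotype outcomes.

Features follow a cluster-mixture factor model: row i with cluster label j
gets X_i = B_j + e_i, where B is a k x p centroid matrix and e is i.i.d.
noise from a two-component scale mixture of centered normals (heavy-ish
tails, mimicking outlier-prone clinical measurements).  Binary outcomes
follow a logistic model with cluster effects plus feature effects; half of
the features carry no outcome signal, playing the role of clinically
recorded but irrelevant variables.

Five scenario sets fix the cluster proportions:

    0: (1.0, 0, 0, 0)          no subgroup structure
    1: (0.25, 0.25, 0.25, 0.25) equal subgroups
    2: (0.1, 0.3, 0.3, 0.3)     one minority subgroup
    3: (0.1, 0.1, 0.4, 0.4)     two minority subgroups
    4: (0.1, 0.1, 0.1, 0.7)     one dominant majority
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import CohortMatrix

SCENARIO_PROPORTIONS: dict[int, tuple[float, ...]] = {
    0: (1.0, 0.0, 0.0, 0.0),
    1: (0.25, 0.25, 0.25, 0.25),
    2: (0.1, 0.3, 0.3, 0.3),
    3: (0.1, 0.1, 0.4, 0.4),
    4: (0.1, 0.1, 0.1, 0.7),
}

#: between-centroid distances are scaled to this multiple of the noise SD;
#: calibrated so hierarchical clustering at the true k recovers planted
#: labels with adjusted Rand > 0.9 on average while cluster tails overlap
CENTROID_SEPARATION = 7.0

#: magnitude of the nonzero feature coefficients in the default outcome
#: model; calibrated jointly with the separation so a full-information
#: logistic fit scores AUROC ~0.75-0.85 on held-out data
BETA_MAGNITUDE = 0.35

#: target marginal event rate for the default outcome model
TARGET_EVENT_RATE = 0.3


@dataclass(frozen=True)
class NoiseSpec:
    """Centered normal scale mixture for the feature deviations e."""

    weights: tuple[float, ...] = (0.9, 0.1)
    scales: tuple[float, ...] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.scales):
            raise ValueError("weights and scales must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @property
    def sd(self) -> float:
        return float(np.sqrt(sum(w * s**2 for w, s in zip(self.weights, self.scales))))


@dataclass
class ScenarioSpec:
    """Generative parameters for one simulated cohort family."""

    N: int
    p: int
    proportions: np.ndarray
    B: np.ndarray
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if (self.proportions < 0).any() or abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")
        if self.B.shape != (len(self.proportions), self.p):
            raise ValueError(f"B must be k x p = {len(self.proportions)} x {self.p}, got {self.B.shape}")

    @property
    def k(self) -> int:
        return len(self.proportions)


@dataclass
class OutcomeModelSpec:
    """Logistic outcome model: logit P(y=1) = a0 + alpha[cluster] + X @ beta."""

    alpha0: float
    alpha: np.ndarray
    beta: np.ndarray
    signal_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha[0] != 0.0:
            raise ValueError("cluster 1 is the reference; alpha[0] must be 0")
        expected = round(self.signal_fraction * len(self.beta))
        if np.count_nonzero(self.beta) != expected:
            raise ValueError(
                f"beta must have exactly {expected} nonzero entries for signal_fraction={self.signal_fraction}"
            )


@dataclass
class SimulatedCohort:
    features: CohortMatrix
    cluster_labels: np.ndarray
    outcomes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)
        if len(self.cluster_labels) != self.features.n:
            raise ValueError("cluster_labels length must equal cohort size")


def make_scenario(set_id: int, N: int = 10_000, p: int = 10, seed: int = 0) -> ScenarioSpec:
    """Build a scenario with the stated cluster proportions and default B/noise.

    The centroid matrix B is drawn once from the seed (spherical normal rows)
    and rescaled so the mean between-centroid distance equals
    ``CENTROID_SEPARATION`` times the noise SD; it is persisted on the spec
    so every dataset in a scenario family shares the same geometry.
    """
    if set_id not in SCENARIO_PROPORTIONS:
        raise ValueError(f"unknown scenario set {set_id}; expected one of {sorted(SCENARIO_PROPORTIONS)}")
    proportions = np.array(SCENARIO_PROPORTIONS[set_id])
    noise = NoiseSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    k = len(proportions)
    raw = rng.standard_normal((k, p))
    raw -= raw.mean(axis=0)
    dists = [np.linalg.norm(raw[a] - raw[b]) for a in range(k) for b in range(a + 1, k)]
    B = raw * (CENTROID_SEPARATION * noise.sd / np.mean(dists))
    return ScenarioSpec(N=N, p=p, proportions=proportions, B=B, noise=noise, seed=seed)


def simulate_features(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Realize one cohort: multinomial cluster labels, X = B[label] + e."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.k, size=spec.N, p=spec.proportions) + 1
    comp = rng.choice(len(spec.noise.scales), size=(spec.N, spec.p), p=spec.noise.weights)
    e = rng.standard_normal((spec.N, spec.p)) * np.asarray(spec.noise.scales)[comp]
    X = spec.B[labels - 1] + e
    return SimulatedCohort(features=CohortMatrix.from_array(X), cluster_labels=labels)


def _linear_predictor(cohort: SimulatedCohort, model: OutcomeModelSpec, with_intercept: bool = True) -> np.ndarray:
    X = cohort.features.numeric_values()
    if X.shape[1] != len(model.beta):
        raise ValueError(f"beta length {len(model.beta)} != p={X.shape[1]}")
    if cohort.cluster_labels.max() > len(model.alpha):
        raise ValueError("cluster label exceeds alpha length")
    lp = model.alpha[cohort.cluster_labels - 1] + X @ model.beta
    return lp + model.alpha0 if with_intercept else lp


def event_probabilities(cohort: SimulatedCohort, model: OutcomeModelSpec) -> np.ndarray:
    """Analytic per-row event probabilities under the logistic model."""
    return expit(_linear_predictor(cohort, model))


def simulate_outcomes(
    cohort: SimulatedCohort, model: OutcomeModelSpec, rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli outcomes at the logistic probabilities."""
    prob = event_probabilities(cohort, model)
    return (rng.random(len(prob)) < prob).astype(int)


def default_outcome_model(
    k: int = 4, p: int = 10, seed: int = 0, scenario: ScenarioSpec | None = None
) -> OutcomeModelSpec:
    """Default effect sizes: half the features informative, distinct cluster risks.

    The first floor(p/2) features get alternating coefficients of magnitude
    ``BETA_MAGNITUDE`` (the rest are outcome noise); cluster effects cycle
    through (0, +0.5, -0.5, +1.0) with cluster 1 as reference.  When a scenario is supplied, the
    intercept is calibrated by a 1-D root search on a 20,000-row draw so the
    marginal event rate is ~= TARGET_EVENT_RATE; without one it defaults to
    logit(TARGET_EVENT_RATE).
    """
    beta = np.zeros(p)
    n_signal = p // 2
    beta[:n_signal] = [BETA_MAGNITUDE if i % 2 == 0 else -BETA_MAGNITUDE for i in range(n_signal)]
    base = [0.0, 0.5, -0.5, 1.0]
    alpha = np.array([base[j % 4] for j in range(k)])
    model = OutcomeModelSpec(alpha0=float(logit(TARGET_EVENT_RATE)), alpha=alpha, beta=beta)
    if scenario is not None:
        calib = replace_N(scenario, 20_000)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 929]))
        draw = simulate_features(calib, rng)
        lp = _linear_predictor(draw, model, with_intercept=False)
        model.alpha0 = float(brentq(lambda a0: expit(a0 + lp).mean() - TARGET_EVENT_RATE, -30.0, 30.0))
    return model


def replace_N(spec: ScenarioSpec, N: int) -> ScenarioSpec:
    """Copy of a scenario with a different cohort size (same geometry)."""
    return ScenarioSpec(N=N, p=spec.p, proportions=spec.proportions.copy(), B=spec.B.copy(),
                        noise=spec.noise, seed=spec.seed)
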