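"""Phenotype fitting, AUROC machinery, SMDs and the benchmark report shape."""

import numpy as np
import pandas as pd
import pytest

from coversample import (
    auroc,
    auroc_ci,
    balance_table,
    compare_methods,
    fit_cp,
    make_scenario,
    default_outcome_model,
    run_benchmark,
    smd,
    smd_multilevel,
    subgroup_auroc,
)


def brute_auroc(scores, labels):
    """Independent oracle: explicit case-control pair enumeration with ties at 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    cases, controls = s[y == 1], s[y == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
            ([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0], 0.75),
        ],
    )
    def test_worked_examples(self, scores, labels, expected):
        assert auroc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_pair_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(6, 60))
            scores = rng.choice(np.round(rng.normal(size=8), 2), size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(brute_auroc(scores, labels), abs=1e-12)


class TestAurocCI:
    def test_perfect_separation_upper_bound(self):
        scores = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        lo, hi = auroc_ci(scores, labels, n_boot=200, rng=np.random.default_rng(0))
        assert hi == pytest.approx(1.0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        a = auroc_ci(scores, labels, n_boot=200, rng=np.random.default_rng(1))
        b = auroc_ci(scores, labels, n_boot=200, rng=np.random.default_rng(1))
        assert a == b

    def test_width_shrinks_with_sample_size(self):
        """Monte-Carlo: the CI from n=5000 is narrower than from n=100."""
        widths = {100: [], 5000: []}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            for n in widths:
                x = rng.normal(size=n)
                y = (x + rng.normal(size=n) > 0).astype(int)
                lo, hi = auroc_ci(x, y, n_boot=150, rng=rng)
                widths[n].append(hi - lo)
        assert np.mean(widths[5000]) < np.mean(widths[100])

    def test_brackets_point_estimate(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = (x + rng.normal(size=200) > 0).astype(int)
        lo, hi = auroc_ci(x, y, n_boot=400, rng=rng)
        assert lo <= auroc(x, y) <= hi


class TestSubgroupAuroc:
    def test_single_class_group_not_evaluable(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        groups = ["a", "a", "a", "b"]  # group b: controls only
        tab = subgroup_auroc(scores, labels, groups, n_boot=100).set_index("group")
        assert np.isnan(tab.loc["b", "auroc"])

    def test_one_group_equals_overall(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        tab = subgroup_auroc(scores, labels, np.repeat("all", 50), n_boot=100)
        assert tab.loc[0, "auroc"] == pytest.approx(auroc(scores, labels))

    def test_disjoint_groups_match_filtered(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        groups = np.repeat(["g1", "g2"], 40)
        tab = subgroup_auroc(scores, labels, groups, n_boot=100).set_index("group")
        for g, sl in (("g1", slice(0, 40)), ("g2", slice(40, 80))):
            assert tab.loc[g, "auroc"] == pytest.approx(auroc(scores[sl], labels[sl]))


class TestSMD:
    def test_binary_examples(self):
        assert smd(0.47, 0.43) == pytest.approx(0.080, abs=5e-4)
        assert smd(0.3, 0.3) == 0.0
        assert smd(0.6, 0.4) == pytest.approx(0.2 / np.sqrt(0.24), abs=1e-9)

    def test_binary_rejects_bad_proportions(self):
        with pytest.raises(ValueError):
            smd(1.2, 0.5)

    def test_multilevel_identical_is_zero(self):
        assert smd_multilevel([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0

    def test_multilevel_reduces_to_binary(self):
        assert smd_multilevel([0.47, 0.53], [0.43, 0.57]) == pytest.approx(smd(0.47, 0.43))

    def test_multilevel_reference_values(self):
        # 4-level age-band comparison between two samples of 100
        got = smd_multilevel([0.02, 0.11, 0.38, 0.49], [0.03, 0.24, 0.38, 0.35])
        assert got == pytest.approx(0.391, abs=5e-4)
        # 5-level race/ethnicity comparison
        got = smd_multilevel([0.15, 0.39, 0.40, 0.02, 0.04], [0.13, 0.44, 0.36, 0.03, 0.04])
        assert got == pytest.approx(0.131, abs=5e-4)

    def test_multilevel_validates_sum(self):
        with pytest.raises(ValueError):
            smd_multilevel([0.5, 0.1], [0.5, 0.5])

    def test_balance_table(self):
        df = pd.DataFrame({"sex": ["m"] * 47 + ["f"] * 53 + ["m"] * 43 + ["f"] * 57})
        tab = balance_table(df, np.arange(100), np.arange(100, 200))
        assert tab.loc[0, "smd"] == pytest.approx(0.080, abs=5e-4)
        assert tab["prop_a"].sum() == pytest.approx(1.0)


class TestCompareMethods:
    def test_identical_vectors_degenerate(self):
        assert compare_methods([0.7, 0.71, 0.72], [0.7, 0.71, 0.72]) == 1.0

    def test_hand_computed_paired_t(self):
        b = np.array([0.70, 0.71, 0.69, 0.72])
        a = b + np.array([0.05, 0.04, 0.06, 0.05])
        # t = 0.05 / (sd/2) = 12.2474 on 3 df -> p = 0.0011722
        assert compare_methods(a, b) == pytest.approx(0.0011722, abs=1e-6)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0.7, 0.02, 20), rng.normal(0.68, 0.02, 20)
        assert compare_methods(a, b) == pytest.approx(compare_methods(b, a))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_methods([0.1, 0.2], [0.1])


class TestFitCP:
    def test_separable_penalized_perfect_training_auroc(self):
        X = np.concatenate([np.full((20, 1), -2.0), np.full((20, 1), 2.0)])
        y = np.repeat([0, 1], 20)
        model = fit_cp(X, y, "l1", penalty=1.0)
        assert auroc(model.predict_proba(X), y) == 1.0

    def test_huge_l1_penalty_zeroes_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] + rng.normal(size=100) > 0).astype(int)
        model = fit_cp(X, y, "l1", penalty=1e6)
        assert np.allclose(model.coefficients, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_cp(np.ones((5, 2)), np.ones(5))

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] - X[:, 1] + rng.normal(size=200) > 0).astype(int)
        a = fit_cp(X, y)
        perm = rng.permutation(200)
        b = fit_cp(X[perm], y[perm])
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-6)

    def test_parameter_recovery_within_3se(self):
        """Unpenalized fit on 50k draws from a known logistic model recovers
        the generating coefficients within 3 standard errors."""
        rng = np.random.default_rng(8)
        n, true_beta, true_b0 = 50_000, np.array([0.8, -0.5, 0.0, 0.3]), -0.7
        X = rng.normal(size=(n, 4))
        p = 1 / (1 + np.exp(-(true_b0 + X @ true_beta)))
        y = (rng.random(n) < p).astype(int)
        model = fit_cp(X, y)
        # observed-information standard errors
        Xd = np.column_stack([np.ones(n), X])
        phat = model.predict_proba(X)
        W = phat * (1 - phat)
        cov = np.linalg.inv(Xd.T @ (Xd * W[:, None]))
        se = np.sqrt(np.diag(cov))
        est = np.concatenate([[model.intercept], model.coefficients])
        truth = np.concatenate([[true_b0], true_beta])
        assert (np.abs(est - truth) <= 3 * se).all()


class TestBenchmarkShape:
    def test_report_contract(self):
        """Small benchmark run: 4 methods x (overall + per-cluster) rows,
        paired p-values vs random, and coverage distances recorded."""
        spec = make_scenario(2, N=500, p=10, seed=2)
        outcome = default_outcome_model(4, 10, seed=2, scenario=spec)
        from coversample import SamplingConfig

        rep = run_benchmark(
            spec, outcome, n_datasets=3, m=60, seed=2,
            sampling_cfg=SamplingConfig(m=60, k_grid=(2, 4), replications=5),
        )
        methods = set(rep.summary["method"])
        assert methods == {"hierarchical", "kmeans", "random", "truth"}
        for m_ in methods:
            scopes = set(rep.summary[rep.summary.method == m_]["scope"])
            assert scopes == {"overall", "cluster_1", "cluster_2", "cluster_3", "cluster_4"}
        assert set(rep.p_values) == {"hierarchical", "kmeans", "truth"}
        overall = rep.summary[rep.summary.scope == "overall"]
        assert overall["mean_nn_distance"].notna().all()
        assert ((overall["ci_lo"] <= overall["auroc"]) & (overall["auroc"] <= overall["ci_hi"])).all()

    def test_truth_dropped_without_structure(self):
        spec = make_scenario(0, N=400, p=10, seed=3)
        outcome = default_outcome_model(4, 10, seed=3, scenario=spec)
        from coversample import SamplingConfig

        rep = run_benchmark(
            spec, outcome, n_datasets=2, m=50, seed=3,
            sampling_cfg=SamplingConfig(m=50, k_grid=(2,), replications=3),
        )
        assert "truth" not in set(rep.summary["method"])
        assert set(rep.summary["scope"]) == {"overall"}

    def test_deterministic_under_seed(self):
        spec = make_scenario(2, N=400, p=10, seed=4)
        outcome = default_outcome_model(4, 10, seed=4, scenario=spec)
        from coversample import SamplingConfig

        kw = dict(n_datasets=2, m=40, seed=9,
                  sampling_cfg=SamplingConfig(m=40, k_grid=(2,), replications=3))
        a = run_benchmark(spec, outcome, **kw)
        b = run_benchmark(spec, outcome, **kw)
        pd.testing.assert_frame_equal(a.per_dataset, b.per_dataset)
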