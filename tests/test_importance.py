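import itertools

import numpy as np
import pytest
from scipy import stats

import permfit as pf
from permfit.importance import P_FLOOR
from permfit.learners import RiskEstimator


def _lookup_estimator(mapping, n_features=1):
    """Estimator returning a fixed probability per (single-column) value."""
    def predict(X):
        return np.array([mapping[v] for v in X[:, 0]])
    return RiskEstimator(_predict=predict, learner_kind="stub", n_features=n_features)


def _table(X, y, kinds=None):
    X = np.asarray(X, float)
    meta, cmap, names = [], {}, []
    for j in range(X.shape[1]):
        nm = f"f{j}"
        meta.append(pf.FeatureMeta(nm, "continuous"))
        cmap[nm] = [j]
        names.append(nm)
    return pf.CohortTable(X, y, meta, cmap, names)


class TestPermuteFeature:
    def test_constant_column_unchanged(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        np.testing.assert_array_equal(pf.permute_feature(X, 0, seed=3), X)

    def test_single_row_unchanged(self):
        X = np.array([[1.0, 2.0]])
        np.testing.assert_array_equal(pf.permute_feature(X, 1, seed=0), X)

    def test_multiset_identical_and_nonidentity(self):
        """For a seed whose draw is verified non-identity, the permuted
        column has the same sorted values but differs somewhere."""
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        seed = next(
            s for s in range(100)
            if not np.array_equal(np.random.default_rng(s).permutation(5), np.arange(5))
        )
        X = col[:, None]
        out = pf.permute_feature(X, 0, seed=seed)
        np.testing.assert_array_equal(np.sort(out[:, 0]), col)
        assert np.any(out[:, 0] != col)

    def test_block_permutation_moves_columns_jointly(self):
        rng = np.random.default_rng(4)
        levels = rng.integers(0, 3, 20)
        X = np.column_stack([(levels == 1).astype(float), (levels == 2).astype(float),
                             rng.normal(size=20)])
        out = pf.permute_feature(X, [0, 1], seed=11)
        # dummy pattern stays valid: at most one indicator set per row
        assert np.all(out[:, 0] + out[:, 1] <= 1)
        # joint multiset of rows is preserved
        orig = sorted(map(tuple, X[:, :2]))
        perm = sorted(map(tuple, out[:, :2]))
        assert orig == perm
        np.testing.assert_array_equal(out[:, 2], X[:, 2])


class TestPerObsImportance:
    def test_equal_probabilities_zero(self):
        p = np.array([0.3, 0.7])
        np.testing.assert_array_equal(
            pf.per_obs_importance(p, p, np.array([1, 0])), [0.0, 0.0]
        )

    def test_worked_example_arithmetic(self):
        """Hand-computed log-likelihood-ratio scores for the 4-observation
        example; mean is ~0.476."""
        y = np.array([1, 0, 1, 0])
        pi = np.array([0.9, 0.2, 0.8, 0.3])
        pip = np.array([0.6, 0.5, 0.5, 0.6])
        scores = pf.per_obs_importance(pi, pip, y)
        expected = np.array(
            [np.log(0.9 / 0.6), np.log(0.8 / 0.5), np.log(0.8 / 0.5), np.log(0.7 / 0.4)]
        )
        np.testing.assert_allclose(scores, expected, rtol=1e-12)
        assert abs(scores.mean() - 0.476) < 5e-4

    def test_sign_monotonicity(self):
        # case observation whose probability drops after permutation scores > 0
        s = pf.per_obs_importance(np.array([0.6]), np.array([0.9]), np.array([1]))
        assert s[0] < 0
        s = pf.per_obs_importance(np.array([0.9]), np.array([0.6]), np.array([1]))
        assert s[0] > 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pf.per_obs_importance(np.ones(3) / 2, np.ones(2) / 2, np.zeros(3))


class TestImportanceTest:
    def test_ignored_feature_scores_zero_p_one(self):
        """An estimator that never looks at feature j is unaffected by its
        permutation: score exactly 0, p exactly 1."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = (rng.random(30) < 0.5).astype(int)
        est = RiskEstimator(
            _predict=lambda A: 1 / (1 + np.exp(-A[:, 0])),
            learner_kind="stub", n_features=2,
        )
        res = pf.importance_test(est, _table(X, y), "f1", pf.PermutationPlan(20, 0))
        assert res.score == 0.0 and res.p_value == 1.0 and res.z == 0.0

    def test_constant_feature_p_one(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.full(20, 2.0), rng.normal(size=20)])
        y = (rng.random(20) < 0.5).astype(int)
        est = RiskEstimator(
            _predict=lambda A: 1 / (1 + np.exp(-(A[:, 0] + A[:, 1]))),
            learner_kind="stub", n_features=2,
        )
        res = pf.importance_test(est, _table(X, y), "f0", pf.PermutationPlan(10, 3))
        assert res.score == 0.0 and res.p_value == 1.0

    def test_worked_example_z_statistic(self):
        """n_V=4, one permutation, fixed probability vectors: z equals
        mean/(s/sqrt(4)) computed by independent arithmetic (spec form of
        the variance)."""
        y = np.array([1, 0, 1, 0])
        vals = np.array([10.0, 20.0, 30.0, 40.0])
        pi = {10.0: 0.9, 20.0: 0.2, 30.0: 0.8, 40.0: 0.3}
        est = _lookup_estimator(pi)
        plan = pf.PermutationPlan(n_perm=1, seed=5)
        order = np.random.default_rng(plan.seeds[0]).permutation(4)
        res = pf.importance_test(
            est, _table(vals[:, None], y), "f0", plan, variance_mode="simple"
        )
        # independent oracle
        p0 = np.array([pi[v] for v in vals])
        pp = np.array([pi[v] for v in vals[order]])
        sc = y * np.log(p0 / pp) + (1 - y) * np.log((1 - p0) / (1 - pp))
        exp_z = sc.mean() / (sc.std(ddof=1) / 2.0)
        assert res.z == pytest.approx(exp_z, rel=1e-12)
        assert res.p_value == pytest.approx(
            max(float(stats.norm.sf(exp_z)), P_FLOOR), rel=1e-12
        )

    def test_z_times_se_equals_score(self, small_cohort):
        est = pf.fit_logistic(small_cohort)
        res = pf.importance_test(est, small_cohort, "b1", pf.PermutationPlan(25, 7))
        assert res.z * res.se == pytest.approx(res.score, rel=1e-12)

    def test_enumeration_oracle_matches_monte_carlo(self):
        """For n_V=4, the mean score over ALL 4! permutations (brute force)
        matches the large-n_perm Monte-Carlo mean within 2 MC standard
        errors."""
        rng = np.random.default_rng(9)
        vals = np.array([0.5, -1.2, 2.0, 0.1])
        y = np.array([1, 0, 0, 1])
        def prob(v):
            return 1 / (1 + np.exp(-1.3 * v))
        est = RiskEstimator(
            _predict=lambda A: prob(A[:, 0]), learner_kind="stub", n_features=1
        )
        p0 = prob(vals)
        all_means = []
        for perm in itertools.permutations(range(4)):
            pp = prob(vals[list(perm)])
            sc = y * np.log(p0 / pp) + (1 - y) * np.log((1 - p0) / (1 - pp))
            all_means.append(sc.mean())
        exact = np.mean(all_means)
        n_perm = 3000
        res = pf.importance_test(
            est, _table(vals[:, None], y), "f0", pf.PermutationPlan(n_perm, 2)
        )
        mc_se = np.std(all_means, ddof=1) / np.sqrt(n_perm)
        assert abs(res.score - exact) <= 2 * mc_se

    def test_strong_signal_detected(self):
        """A feature driving the outcome through a known logistic model is
        flagged at p < 0.001 in at least 90% of 50 replicates (n=1000,
        logistic learner)."""
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(size=(1000, 3))
            y = (rng.random(1000) < 1 / (1 + np.exp(-(1.5 * X[:, 0] - 0.5)))).astype(int)
            cohort = _table(X, y)
            res = pf.run_permfit(cohort, "logistic", n_perm=30, seed=rep)
            p = {r.feature: r.p_value for r in res}["f0"]
            hits += p < 0.001
        assert hits >= 45

    def test_invariant_to_other_column_order(self):
        """Reordering columns other than j (with bookkeeping updated) leaves
        the importance result for j unchanged, given an order-insensitive
        estimator."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        est = RiskEstimator(
            _predict=lambda A: 1 / (1 + np.exp(-A.sum(axis=1))),
            learner_kind="stub", n_features=3,
        )
        t1 = _table(X, y)
        # swap columns 1 and 2, renaming so that "f0" keeps its data
        t2 = _table(X[:, [0, 2, 1]], y)
        plan = pf.PermutationPlan(40, 21)
        r1 = pf.importance_test(est, t1, "f0", plan)
        r2 = pf.importance_test(est, t2, "f0", plan)
        assert r1.score == pytest.approx(r2.score, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_validation_too_small(self, small_cohort):
        est = pf.fit_logistic(small_cohort)
        with pytest.raises(ValueError, match=">= 2"):
            pf.importance_test(est, small_cohort.subset_rows([0]), "b1")


class TestRunPermfit:
    def test_one_result_per_clinical_feature_in_order(self):
        sim = pf.simulate_cohort(pf.pe_study_spec(n=250, seed=2))
        res = pf.run_permfit(sim.table, "logistic", n_perm=10, seed=2)
        assert [r.feature for r in res] == sim.table.feature_names
        assert len(res) == 22           # smoking tested once, as one feature
        assert all(np.isfinite(r.z) for r in res)
        assert all(0 < r.p_value <= 1 for r in res)

    def test_reproducible_given_seed(self):
        sim = pf.simulate_cohort(pf.pe_study_spec(n=200, seed=3))
        r1 = pf.run_permfit(sim.table, "logistic", n_perm=10, seed=5)
        r2 = pf.run_permfit(sim.table, "logistic", n_perm=10, seed=5)
        assert [(r.score, r.p_value) for r in r1] == [(r.score, r.p_value) for r in r2]

    def test_kfold_scores_every_observation(self):
        sim = pf.simulate_cohort(pf.pe_study_spec(n=200, seed=4))
        res = pf.run_permfit(sim.table, "logistic", n_perm=10, seed=4, k_folds=4)
        assert all(r.n_validation == 200 for r in res)

    def test_alpha_validation(self):
        sim = pf.simulate_cohort(pf.pe_study_spec(n=100, seed=5))
        with pytest.raises(ValueError, match="alpha"):
            pf.run_permfit(sim.table, "logistic", alpha=1.5, seed=0)

    def test_estimator_failure_propagates(self, small_cohort):
        bad = RiskEstimator(
            _predict=lambda A: (_ for _ in ()).throw(RuntimeError("boom")),
            learner_kind="stub", n_features=small_cohort.X.shape[1],
        )
        with pytest.raises(RuntimeError, match="boom"):
            pf.importance_test(bad, small_cohort, "b1")


def test_select_important_table_like_pvalues():
    """p-values shaped like the published importance table ({<0.001, 0.011,
    0.028} among 22) select exactly 3 features at alpha=0.05, ordered by
    p."""
    ps = [0.0005, 0.011, 0.028] + [0.05 + 0.04 * i for i in range(19)]
    names = ["pe_history", "chronic_prednisone", "dvt_history"] + [
        f"null{i}" for i in range(19)
    ]
    rng = np.random.default_rng(0)
    order = rng.permutation(22)
    results = [
        pf.ImportanceResult(names[i], 0.1, 0.01, 1.0, ps[i], 100) for i in order
    ]
    sel = pf.select_important(results, alpha=0.05)
    assert sel == ["pe_history", "chronic_prednisone", "dvt_history"]


def test_select_important_edge_cases():
    results = [pf.ImportanceResult("a", 0.0, 0.0, 0.0, 1.0, 10)]
    assert pf.select_important(results, 0.05) == []
    assert pf.select_important(results, 0.0) == []      # strict inequality
    with pytest.raises(ValueError):
        pf.select_important([], 0.05)


def test_select_important_adjustment_flag():
    results = [
        pf.ImportanceResult("a", 0.1, 0.01, 5.0, 0.001, 50),
        pf.ImportanceResult("b", 0.1, 0.05, 2.0, 0.04, 50),
    ]
    assert pf.select_important(results, 0.05) == ["a", "b"]
    assert pf.select_important(results, 0.05, adjust="bonferroni") == ["a"]


def test_display_p_convention():
    r = pf.ImportanceResult("x", 0.2, 0.01, 20.0, 1e-10, 100)
    assert r.display_p == "<0.001"
    r = pf.ImportanceResult("x", 0.01, 0.01, 1.0, 0.158, 100)
    assert r.display_p == "0.158"
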