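"""Rule discovery: forests, rule extraction, the penalized solve, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from sepsisrules import CohortTable, FitConfig, RuleEnsemble, parse_rule
from sepsisrules.rulefit import (
    _objective,
    cv_select,
    extract_rules,
    fit_path,
    fit_sparse_logistic,
    grow_forest,
    lambda_max,
    predict_proba,
    rulefit,
    simplify_rule,
)
from sepsisrules.rules import canonical_key


def _toy_table(n=200, seed=0, p=3, signal_col=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    if signal_col is None:
        y = np.where(rng.random(n) < 0.4, 1, -1)
    else:
        y = np.where(X[signal_col] > 0, 1, -1)
    if abs(y.sum()) == n:
        y[0] = -y[0]
    time = np.where(y == 1, 3.0, 10.0)
    return CohortTable(X, y, time, y == 1)


def solve_oracle(R, y, lam):
    """Independent convex solve: split w = u - v, u,v >= 0, box-constrained
    L-BFGS-B on the smooth equivalent objective."""
    N, q = R.shape
    def obj(z):
        u, v, b = z[:q], z[q:2 * q], z[-1]
        m = y * (R @ (u - v) + b)
        return np.logaddexp(0, -m).mean() + lam * (u + v).sum()
    res = minimize(obj, np.zeros(2 * q + 1), method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * q) + [(None, None)],
                   options=dict(maxiter=5000, ftol=1e-15, gtol=1e-12))
    return res.fun


class TestForest:
    def test_depth_one_gives_stumps(self):
        table = _toy_table(seed=1)
        forest = grow_forest(table, 10, FitConfig(max_depth=1, min_node=5, seed=0))
        for est in forest.estimators_:
            assert est.get_depth() == 1

    def test_depth_mix_never_exceeds_cap(self):
        table = _toy_table(seed=1)
        forest = grow_forest(table, 12, FitConfig(max_depth=3, min_node=5, seed=0))
        assert len(forest.estimators_) == 12
        assert max(e.get_depth() for e in forest.estimators_) <= 3

    def test_zero_trees_rejected(self):
        with pytest.raises(ValueError):
            grow_forest(_toy_table(), 0, FitConfig())

    def test_constant_outcome_rejected(self):
        table = _toy_table(seed=2)
        table.y[:] = 1
        table.event[:] = True
        with pytest.raises(ValueError, match="constant"):
            grow_forest(table, 5, FitConfig())

    def test_perfect_binary_predictor_dominates_stumps(self):
        """A single perfectly separating predictor has zero Gini impurity at
        its split, so every stump that sees it splits on it."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"sig": np.repeat([0.0, 1.0], 50),
                          "noise": rng.normal(size=100)})
        y = np.where(X["sig"] > 0.5, 1, -1)
        table = CohortTable(X, y, np.ones(100), y == 1)
        forest = grow_forest(table, 20, FitConfig(max_depth=1, mtry=1.0, min_node=5, seed=0))
        for est in forest.estimators_:
            assert est.tree_.feature[0] == 0


class TestExtractRules:
    def test_stump_yields_two_rules(self):
        table = _toy_table(seed=4, signal_col="x0")
        forest = grow_forest(table, 1, FitConfig(max_depth=1, min_node=5, seed=1))
        rules = extract_rules(forest, table.predictor_names)
        assert len(rules) == 2
        ops = sorted(r.conditions[0].op for r in rules)
        assert ops == ["<=", ">"]
        assert rules[0].conditions[0].threshold == rules[1].conditions[0].threshold

    def test_depth2_tree_yields_six_rules(self):
        """A full depth-2 tree has 2 depth-1 and 4 depth-2 non-root nodes."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": np.tile([0.0, 1.0], 50), "b": np.repeat([0.0, 1.0], 50)})
        y = np.where((X["a"] > 0.5) ^ (X["b"] > 0.5), 1, -1)  # XOR forces depth 2
        table = CohortTable(X, y, np.ones(100), y == 1)
        forest = grow_forest(table, 1, FitConfig(max_depth=2, depth_mix=False,
                                                 mtry=1.0, min_node=5, bootstrap=False, seed=2))
        rules = extract_rules(forest, table.predictor_names)
        assert len(rules) == 6

    def test_identical_trees_deduplicate(self):
        table = _toy_table(seed=6, signal_col="x1")
        cfg = FitConfig(max_depth=2, depth_mix=False, min_node=5, bootstrap=False,
                        mtry=1.0, seed=3)
        one = extract_rules(grow_forest(table, 1, cfg), table.predictor_names)
        two = extract_rules(grow_forest(table, 2, cfg), table.predictor_names)
        assert {canonical_key(r) for r in one} == {canonical_key(r) for r in two}

    def test_simplify_drops_vacuous_condition(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0], "b": [5.0, 6.0, 7.0, 8.0]})
        rule = parse_rule("a <= 1.5 & b <= 100")  # second condition excludes nobody
        out = simplify_rule(rule, X)
        assert [c.variable for c in out.conditions] == ["a"]


class TestSparseLogistic:
    def test_lambda_max_gives_null_model(self):
        rng = np.random.default_rng(7)
        R = (rng.random((60, 4)) < 0.4).astype(float)
        y = np.where(rng.random(60) < 0.3, 1.0, -1.0)
        lmax = lambda_max(R, y)
        w, b = fit_sparse_logistic(R, y, lmax * 1.0001)
        assert np.all(w == 0)
        n_pos = (y == 1).sum()
        assert b == pytest.approx(np.log(n_pos / (60 - n_pos)), abs=1e-8)

    def test_matches_independent_convex_solver(self):
        """Objective gap <= 1e-6 against a generic convex solve on small
        random instances."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            N, q = 20, int(rng.integers(2, 6))
            R = (rng.random((N, q)) < 0.5).astype(float)
            y = np.where(rng.random(N) < 0.4, 1.0, -1.0)
            if abs(y.sum()) == N:
                y[0] = -y[0]
            lam = 0.05
            w, b = fit_sparse_logistic(R, y, lam)
            assert _objective(R, y, w, b, lam) - solve_oracle(R, y, lam) <= 1e-6

    def test_duplicated_column_weights_sum(self):
        """Duplicated endorsement columns: the solution is non-unique but
        the objective with the summed weight on one column is identical."""
        rng = np.random.default_rng(8)
        R1 = (rng.random((80, 3)) < 0.5).astype(float)
        y = np.where(rng.random(80) < 0.4, 1.0, -1.0)
        lam = 0.02
        w1, b1 = fit_sparse_logistic(R1, y, lam)
        R2 = np.hstack([R1, R1[:, [0]]])
        w2, b2 = fit_sparse_logistic(R2, y, lam)
        merged = np.array([w2[0] + w2[3], w2[1], w2[2]])
        assert _objective(R1, y, merged, b2, lam) == pytest.approx(
            _objective(R1, y, w1, b1, lam), abs=1e-6
        )

    def test_nonbinary_y_rejected(self):
        with pytest.raises(ValueError, match="-1"):
            fit_sparse_logistic(np.ones((4, 1)), np.array([0, 1, 0, 1]), 0.1)

    def test_loss_term_is_average_negative_log_likelihood(self):
        """The optimized loss equals the mean negative log of the model's
        conditional probability over the sample."""
        rng = np.random.default_rng(9)
        R = (rng.random((30, 2)) < 0.5).astype(float)
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        w, b = rng.normal(size=2), 0.3
        probs = 1.0 / (1.0 + np.exp(-y * (R @ w + b)))
        assert _objective(R, y, w, b, 0.0) == pytest.approx(
            -np.log(probs).mean(), abs=1e-12
        )

    def test_sparsity_path_monotone(self):
        """Nonzero count is non-increasing in the penalty on a fixed matrix."""
        rng = np.random.default_rng(10)
        R = (rng.random((100, 8)) < 0.5).astype(float)
        y = np.where(rng.random(100) < 0.4, 1.0, -1.0)
        lmax = lambda_max(R, y)
        lams = np.geomspace(lmax, 0.01 * lmax, 12)
        path = fit_path(R, y, lams, tol=1e-8)
        nz = [int((w != 0).sum()) for w, _ in path]
        assert all(a <= b for a, b in zip(nz, nz[1:]))  # lams decreasing

    def test_null_model_predicts_prevalence(self):
        rng = np.random.default_rng(11)
        R = (rng.random((50, 3)) < 0.5).astype(float)
        y = np.where(rng.random(50) < 0.3, 1.0, -1.0)
        w, b = fit_sparse_logistic(R, y, lambda_max(R, y) + 0.01)
        prev = (y == 1).mean()
        assert expit(R @ w + b) == pytest.approx(np.full(50, prev), abs=1e-8)


class TestCVAndEndToEnd:
    def test_singleton_grids_returned_directly(self):
        table = _toy_table(n=150, seed=12, signal_col="x0")
        cfg = FitConfig(n_trees_grid=(10,), lambda_grid=(0.05,), cv_folds=3,
                        min_node=5, seed=0)
        ens = rulefit(table, cfg)
        assert ens.n_trees_selected == 10
        assert ens.lambda_selected == 0.05

    def test_one_se_rule_verified_by_table_scan(self):
        table = _toy_table(n=300, seed=13, signal_col="x1")
        cfg = FitConfig(n_trees_grid=(8, 16), lambda_grid="auto", n_lambda=8,
                        lambda_min_ratio=0.05, cv_folds=3, min_node=5, seed=5)
        sel = cv_select(table, cfg)
        df = sel.cv_table
        best = df.sort_values(["mean_error", "n_trees", "lam"],
                              ascending=[True, True, False]).iloc[0]
        cutoff = best["mean_error"] + best["se_error"]
        at_n = df[df["n_trees"] == int(best["n_trees"])]
        expected = at_n.loc[at_n["mean_error"] <= cutoff, "lam"].max()
        assert sel.lambda_selected == expected
        assert sel.n_trees_selected == int(best["n_trees"])

    def test_cv_reproducible_under_seed(self):
        table = _toy_table(n=200, seed=14, signal_col="x0")
        cfg = FitConfig(n_trees_grid=(6,), lambda_grid="auto", n_lambda=5,
                        lambda_min_ratio=0.1, cv_folds=3, min_node=5, seed=21)
        a, b = cv_select(table, cfg), cv_select(table, cfg)
        assert a.lambda_selected == b.lambda_selected
        pd.testing.assert_frame_equal(a.cv_table, b.cv_table)

    def test_rulefit_annotates_support_and_direction(self):
        table = _toy_table(n=400, seed=15, signal_col="x0")
        cfg = FitConfig(n_trees_grid=(20,), lambda_grid=(0.02,), min_node=10, seed=1)
        ens = rulefit(table, cfg)
        assert len(ens.rules) > 0
        for r in ens.rules:
            assert r.weight != 0
            assert 0 < r.support < 1
            assert r.direction == ("increasing" if r.weight > 0 else "decreasing")

    def test_ensemble_json_round_trip(self):
        table = _toy_table(n=300, seed=16, signal_col="x1")
        cfg = FitConfig(n_trees_grid=(15,), lambda_grid=(0.03,), min_node=10, seed=2)
        ens = rulefit(table, cfg)
        back = RuleEnsemble.from_json(ens.to_json())
        assert back.intercept == ens.intercept
        assert [r.to_dict() for r in back.rules] == [r.to_dict() for r in ens.rules]
        assert np.allclose(back.predict_proba(table.X), ens.predict_proba(table.X))


class TestPredictProba:
    def test_origin_gives_half(self):
        ens = RuleEnsemble(rules=[], intercept=0.0, lambda_selected=1.0,
                           n_trees_selected=1, intercept_only=True)
        assert predict_proba(ens, {"anything": 1.0}) == 0.5

    def test_hand_computed_sigmoid(self):
        rule = parse_rule("GCS <= 8", "rule_001")
        rule = rule.__class__(rule_id="rule_001", conditions=rule.conditions, weight=1.5)
        ens = RuleEnsemble(rules=[rule], intercept=-2.0, lambda_selected=0.1,
                           n_trees_selected=1)
        p_endorse = predict_proba(ens, {"GCS": 5.0})
        p_not = predict_proba(ens, {"GCS": 12.0})
        assert p_endorse == pytest.approx(1 / (1 + np.exp(2.0 - 1.5)), abs=1e-12)
        assert p_not == pytest.approx(1 / (1 + np.exp(2.0)), abs=1e-12)
        assert p_endorse > p_not  # positive weight raises the probability

    def test_missing_variable_fails(self):
        rule = parse_rule("GCS <= 8", "rule_001")
        rule = rule.__class__(rule_id="rule_001", conditions=rule.conditions, weight=1.0)
        ens = RuleEnsemble(rules=[rule], intercept=0.0, lambda_selected=0.1,
                           n_trees_selected=1)
        with pytest.raises(KeyError):
            predict_proba(ens, {"HR": 100.0})
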