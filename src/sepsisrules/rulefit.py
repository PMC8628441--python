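"""Rule discovery and pruning: random-forest rule generation plus
ℓ1-regularized logistic selection.

The two-step construction: (1) grow a bootstrap random forest of shallow
classification trees (default depth 3) on the binary in-hospital-death
outcome and read every root-to-node path as a candidate conjunctive rule;
(2) build the patients x rules binary endorsement matrix R and select a
sparse weight vector by solving

    min_{w,b}  (1/N) sum_i log(1 + exp(-y_i (w^T r(x_i) + b)))  +  lam * ||w||_1

with the intercept unpenalized and y in {-1, +1}.  The number of trees and
the penalty lam are tuned by stratified k-fold cross-validation on the
misclassification rate at the 0.5 probability threshold, with the usual
one-standard-error rule for lam.  Rules with nonzero weight form the fitted
ensemble; each carries its training support and a direction given by the
sign of its weight (positive = endorsing increases death risk).

The penalized solve is cyclic coordinate descent on a per-coordinate
quadratic majorizer of the logistic loss (curvature bound ``mean(R_j^2)/4``),
which guarantees monotone descent without line searches; convergence is
declared on the max-norm of the subgradient optimality violation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable
from .rules import (
    Condition,
    InfeasibleRuleError,
    Rule,
    canonical_key,
    canonicalize,
    rule_endorsement,
    rule_support,
)

__all__ = [
    "FitConfig",
    "RuleEnsemble",
    "CVSelection",
    "ConvergenceError",
    "grow_forest",
    "extract_rules",
    "fit_sparse_logistic",
    "fit_path",
    "lambda_max",
    "cv_select",
    "rulefit",
    "predict_proba",
    "build_endorsements",
]


class ConvergenceError(RuntimeError):
    """Penalized solve failed to reach the optimality tolerance."""


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the discovery stage.

    ``n_trees_grid`` and the lam grid (``lambda_grid="auto"`` builds a
    geometric sequence of ``n_lambda`` values from lam_max down to
    ``lambda_min_ratio * lam_max``) are searched by ``cv_folds``-fold
    stratified CV on misclassification; ``lambda_rule`` picks either the
    minimizer ("min") or the largest lam within one SE of it ("1se").
    """

    max_depth: int = 3
    n_trees_grid: tuple[int, ...] = (125, 250, 375)
    mtry: int | float | str = "sqrt"
    bootstrap: bool = True
    lambda_grid: tuple[float, ...] | str = "auto"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.001
    cv_folds: int = 10
    lambda_rule: str = "1se"
    min_node: int = 10
    rules_from: str = "all_nodes"  # or "leaves"
    depth_mix: bool = True  # cycle tree depths 1..max_depth across the ensemble
    subrule_closure: bool = True  # candidates closed under condition deletion
    tol: float = 1e-7
    cv_tol: float = 1e-4  # looser optimality inside CV; error rates are insensitive
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.rules_from not in ("all_nodes", "leaves"):
            raise ValueError("rules_from must be 'all_nodes' or 'leaves'")
        if not isinstance(self.lambda_grid, str):
            grid = tuple(float(v) for v in self.lambda_grid)
            if any(v <= 0 for v in grid):
                raise ValueError("explicit lambda_grid must be strictly positive")
            if any(a <= b for a, b in zip(grid, grid[1:])):
                raise ValueError("explicit lambda_grid must be strictly decreasing")
            object.__setattr__(self, "lambda_grid", grid)
        if not all(isinstance(t, (int, np.integer)) and t >= 1 for t in self.n_trees_grid):
            raise ValueError("n_trees_grid entries must be positive integers")


@dataclass
class RuleEnsemble:
    """The fitted model: selected rules with weights, plus the intercept.

    Death probability of a patient x is ``sigmoid(sum_k w_k r_k(x) + b)``.
    ``intercept_only`` flags the degenerate fit where the penalty removed
    every rule.
    """

    rules: list[Rule]
    intercept: float
    lambda_selected: float
    n_trees_selected: int
    n_candidates: int = 0
    objective: float = float("nan")
    seed: int = 0
    intercept_only: bool = False

    def __post_init__(self):
        if any(r.weight in (None, 0.0) for r in self.rules):
            raise ValueError("every reported rule must carry a nonzero weight")

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight for r in self.rules], dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return predict_proba(self, X)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rules": [r.to_dict() for r in self.rules],
                "intercept": self.intercept,
                "lambda_selected": self.lambda_selected,
                "n_trees_selected": self.n_trees_selected,
                "n_candidates": self.n_candidates,
                "objective": self.objective,
                "seed": self.seed,
                "intercept_only": self.intercept_only,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, s: str) -> "RuleEnsemble":
        d = json.loads(s)
        return cls(
            rules=[Rule.from_dict(r) for r in d["rules"]],
            intercept=d["intercept"],
            lambda_selected=d["lambda_selected"],
            n_trees_selected=d["n_trees_selected"],
            n_candidates=d.get("n_candidates", 0),
            objective=d.get("objective", float("nan")),
            seed=d.get("seed", 0),
            intercept_only=d.get("intercept_only", False),
        )


# ---------------------------------------------------------------------------
# rule generation


def _stage_seed(seed: int, n_trees: int, fold: int) -> int:
    # deterministic per (seed, grid point, fold); fold=-1 is the full-data fit
    return (seed * 1_000_003 + n_trees * 9176 + (fold + 2) * 7919) % (2**31 - 1)


@dataclass
class Forest:
    """A randomized tree ensemble, possibly mixing maximum depths.

    Shallow trees contribute short, high-support rules and deeper trees
    contribute higher-order interactions; cycling depths from 1 up to the
    configured maximum keeps both in the candidate pool (trees never exceed
    ``max_depth``)."""

    estimators_: list
    n_trees: int


def grow_forest(table: CohortTable, n_trees: int, config: FitConfig, *, fold: int = -1) -> Forest:
    """Grow the randomized tree ensemble rules are read from: ``n_trees``
    bootstrap classification trees with ``mtry`` candidate features per
    split, leaves of at least ``min_node`` subjects, depth <= max_depth."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    _require_complete(table.X)
    y01 = (table.y == 1).astype(int)
    if y01.min() == y01.max():
        raise ValueError("outcome is constant; trees have no split signal")
    Xv = table.X.to_numpy(dtype=float)

    depths = (
        list(range(1, config.max_depth + 1)) if config.depth_mix else [config.max_depth]
    )
    base = n_trees // len(depths)
    counts = [base + (1 if i < n_trees % len(depths) else 0) for i in range(len(depths))]
    estimators = []
    for depth, count in zip(depths, counts):
        if count == 0:
            continue
        forest = RandomForestClassifier(
            n_estimators=count,
            criterion="gini",
            max_depth=depth,
            max_features=config.mtry,
            min_samples_leaf=config.min_node,
            bootstrap=config.bootstrap,
            random_state=(_stage_seed(config.seed, n_trees, fold) + depth) % (2**31 - 1),
            n_jobs=1,
        )
        forest.fit(Xv, y01)
        estimators.extend(forest.estimators_)
    return Forest(estimators_=estimators, n_trees=n_trees)


def extract_rules(
    forest: Forest,
    feature_names: Sequence[str],
    rules_from: str = "all_nodes",
) -> list[Rule]:
    """One candidate rule per non-root tree node: the conjunction of split
    conditions on the path from the root.  Canonicalized, deduplicated, and
    purged of infeasible (empty-truth-set) conjunctions."""
    seen: dict[tuple, Rule] = {}
    for est in forest.estimators_:
        tree = est.tree_
        stack: list[tuple[int, tuple[Condition, ...]]] = [(0, ())]
        while stack:
            node, path = stack.pop()
            left, right = tree.children_left[node], tree.children_right[node]
            is_leaf = left == -1
            if path and (rules_from == "all_nodes" or is_leaf):
                try:
                    rule = canonicalize(Rule(conditions=path))
                except InfeasibleRuleError:
                    rule = None
                if rule is not None:
                    seen.setdefault(canonical_key(rule), rule)
            if not is_leaf:
                var = feature_names[tree.feature[node]]
                thr = float(tree.threshold[node])
                stack.append((right, path + (Condition(var, ">", thr),)))
                stack.append((left, path + (Condition(var, "<=", thr),)))
    return [
        replace(rule, rule_id=f"c{i:04d}")
        for i, rule in enumerate(seen.values())
    ]


def simplify_rule(rule: Rule, X: pd.DataFrame) -> Rule:
    """Minimal equivalent form on a reference table: drop every condition
    whose removal leaves the endorsement vector unchanged.

    Shallow tree paths often carry conditions that exclude nobody (e.g. a
    split far in a distribution tail); the pruned rule endorses exactly the
    same patients, so the fit is unaffected and the reported rule is the
    minimal description of its endorsement set."""
    base = rule_endorsement(rule, X)
    conditions = list(rule.conditions)
    changed = True
    while changed and len(conditions) > 1:
        changed = False
        for i in range(len(conditions)):
            trial = Rule(conditions=tuple(conditions[:i] + conditions[i + 1:]))
            if np.array_equal(rule_endorsement(trial, X), base):
                del conditions[i]
                changed = True
                break
    return replace(rule, conditions=tuple(conditions))


def build_endorsements(rules: Sequence[Rule], X: pd.DataFrame) -> np.ndarray:
    """N x q binary endorsement matrix R, column j = r_j over the rows."""
    if not rules:
        return np.zeros((len(X), 0), dtype=float)
    return np.column_stack([rule_endorsement(r, X) for r in rules]).astype(float)


# ---------------------------------------------------------------------------
# the penalized solve


def _objective(R: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, lam: float) -> float:
    margins = y * (R @ w + b)
    return float(np.logaddexp(0.0, -margins).mean() + lam * np.abs(w).sum())


def _kkt_violation(g: np.ndarray, gb: float, w: np.ndarray, lam: float) -> float:
    """Max-norm violation of the subgradient optimality conditions."""
    viol = np.where(
        w != 0.0,
        np.abs(g + lam * np.sign(w)),
        np.maximum(np.abs(g) - lam, 0.0),
    )
    return float(max(viol.max(initial=0.0), abs(gb)))


def _null_intercept(y: np.ndarray) -> float:
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes are required")
    return float(np.log(n_pos / n_neg))


def lambda_max(R: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the all-zero weight vector is optimal."""
    b0 = _null_intercept(y)
    p0 = expit(-y * b0)
    g = -(R.T @ (y * p0)) / len(y)
    return float(np.abs(g).max(initial=0.0))


def fit_sparse_logistic(
    R: np.ndarray,
    y: np.ndarray,
    lam: float,
    w_init: np.ndarray | None = None,
    b_init: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> tuple[np.ndarray, float]:
    """Solve the ℓ1-penalized average logistic loss to subgradient tolerance.

    Cyclic coordinate descent with per-coordinate majorizer curvature
    ``mean(R_j^2)/4`` (a global bound on the logistic curvature, so every
    update decreases the objective).  Returns ``(w, b)``; raises
    :class:`ConvergenceError` if the KKT violation stays above ``tol``.
    """
    R = np.asarray(R, dtype=float)
    y = np.asarray(y, dtype=float)
    if R.ndim != 2 or len(y) != R.shape[0]:
        raise ValueError("R must be N x q with len(y) == N")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("y must be coded in {-1, +1}")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    N, q = R.shape

    w = np.zeros(q) if w_init is None else np.asarray(w_init, dtype=float).copy()
    b = _null_intercept(y) if b_init is None else float(b_init)
    f = R @ w + b
    y01 = (y + 1.0) / 2.0

    cur_obj = _objective(R, y, w, b, lam)
    for _ in range(max_iter):
        p = expit(f)  # P(y = +1 | x)
        g = R.T @ (p - y01) / N
        gb = float((p - y01).mean())
        if _kkt_violation(g, gb, w, lam) <= tol:
            return w, b
        active = np.flatnonzero((w != 0.0) | (np.abs(g) >= lam * (1.0 - 1e-12)))
        if active.size == 0:
            # only the intercept violates: damped Newton on b alone
            hb = max(float((p * (1.0 - p)).mean()), 1e-10)
            db = float(np.clip(-gb / hb, -4.0, 4.0))
            b += db
            f += db
            cur_obj = _objective(R, y, w, b, lam)
            continue

        # proximal-Newton step: quadratic (IRLS) model of the loss at f,
        # minimized over the active coordinates by coordinate descent with
        # Gram ("covariance") updates, then an objective-decrease safeguard.
        RA = np.ascontiguousarray(R[:, active])
        wa = w[active].copy()
        wa_old = wa.copy()
        b_old = b
        W = np.clip(p * (1.0 - p), 1e-6, None)
        resid = y01 - p  # equals W * (z - f) for working response z
        G = (RA * W[:, None]).T @ RA / N
        u = RA.T @ W / N
        hb = max(float(W.mean()), 1e-10)
        s = RA.T @ resid / N
        sb = float(resid.mean())
        diag = np.maximum(np.diag(G).copy(), 1e-10)

        for _ in range(1000):  # CD sweeps on the quadratic model
            max_step = 0.0
            for jj in range(active.size):
                zj = diag[jj] * wa[jj] + s[jj]
                wn = np.sign(zj) * max(abs(zj) - lam, 0.0) / diag[jj]
                d = wn - wa[jj]
                if d != 0.0:
                    wa[jj] = wn
                    s -= d * G[:, jj]
                    sb -= d * u[jj]
                    max_step = max(max_step, abs(d))
            db = sb / hb
            if db != 0.0:
                b_step = db
                b += b_step
                s -= b_step * u
                sb -= b_step * hb
                max_step = max(max_step, abs(b_step))
            if max_step < tol * 1e-2:
                break

        # safeguard: halve the Newton step while the true objective worsens
        w[active] = wa
        f = R @ w + b
        new_obj = _objective(R, y, w, b, lam)
        halvings = 0
        while new_obj > cur_obj + 1e-14 and halvings < 30:
            wa = (wa + wa_old) / 2.0
            b = (b + b_old) / 2.0
            w[active] = wa
            f = R @ w + b
            new_obj = _objective(R, y, w, b, lam)
            halvings += 1
        cur_obj = new_obj
    p = expit(-y * f)
    g = -(R.T @ (y * p)) / N
    gb = -float((y * p).mean())
    raise ConvergenceError(
        f"sparse logistic solve did not converge: KKT violation "
        f"{_kkt_violation(g, gb, w, lam):.3e} > tol {tol:.1e} "
        f"after {max_iter} iterations"
    )


def fit_path(
    R: np.ndarray,
    y: np.ndarray,
    lambdas: Sequence[float],
    tol: float = 1e-6,
) -> list[tuple[np.ndarray, float]]:
    """Warm-started solution path along a decreasing penalty sequence."""
    out = []
    w, b = None, None
    for lam in lambdas:
        w, b = fit_sparse_logistic(R, y, lam, w_init=w, b_init=b, tol=tol)
        out.append((w.copy(), b))
    return out


# ---------------------------------------------------------------------------
# cross-validated selection and the end-to-end fit


@dataclass
class CVSelection:
    n_trees_selected: int
    lambda_selected: float
    cv_table: pd.DataFrame  # n_trees, lam, mean_error, se_error, mean_nonzero

    def to_csv(self, path: str | Path) -> None:
        self.cv_table.to_csv(path, index=False)


def _lambda_grid(config: FitConfig, R: np.ndarray, y: np.ndarray) -> np.ndarray:
    if isinstance(config.lambda_grid, str):
        lmax = max(lambda_max(R, y), 1e-10)
        return np.geomspace(lmax, config.lambda_min_ratio * lmax, config.n_lambda)
    return np.asarray(config.lambda_grid, dtype=float)


def _rules_and_R(table: CohortTable, n_trees: int, config: FitConfig, fold: int):
    """Grow, extract, and reduce to endorsement-distinct candidates.

    Rules whose endorsement columns coincide on the training rows are
    indistinguishable to the penalized fit (the ℓ1 solution splits their
    weight arbitrarily), so only the first representative of each distinct
    column is kept."""
    forest = grow_forest(table, n_trees, config, fold=fold)
    rules = extract_rules(forest, table.predictor_names, config.rules_from)
    if config.subrule_closure:
        # close the pool under condition deletion: tree paths contribute
        # their prefixes already, and this adds the remaining
        # sub-conjunctions, so a rule is never representable only with a
        # spurious extra split attached
        closed: dict[tuple, Rule] = {canonical_key(r): r for r in rules}
        frontier = list(closed.values())
        while frontier:
            nxt = []
            for rule in frontier:
                if len(rule.conditions) < 2:
                    continue
                for i in range(len(rule.conditions)):
                    sub = Rule(conditions=rule.conditions[:i] + rule.conditions[i + 1:])
                    key = canonical_key(sub)
                    if key not in closed:
                        closed[key] = sub
                        nxt.append(sub)
            frontier = nxt
        rules = list(closed.values())
    rules = [simplify_rule(r, table.X) for r in rules]
    R = build_endorsements(rules, table.X)
    if R.shape[1] > 1:
        _, inverse = np.unique(R, axis=1, return_inverse=True)
        best: dict[int, int] = {}
        for j, grp in enumerate(inverse):
            g = int(grp)
            if g not in best or len(rules[j]) < len(rules[best[g]]):
                best[g] = j
        keep = np.sort(np.fromiter(best.values(), dtype=int))
        rules = [rules[j] for j in keep]
        R = R[:, keep]
    return rules, R


def _subset(table: CohortTable, idx: np.ndarray) -> CohortTable:
    return CohortTable(
        table.X.iloc[idx], table.y[idx], table.time[idx], table.event[idx]
    )


def cv_select(table: CohortTable, config: FitConfig) -> CVSelection:
    """Pick (n_trees, lam) by stratified k-fold CV on misclassification.

    For each tree count, the lam grid is anchored at the full-data lam_max
    (glmnet-style) and, within each fold, rules are regrown on the training
    split only, so held-out error is honest about rule discovery as well as
    weighting.  Selection: grid point minimizing mean error; under the 1-SE
    rule the largest lam whose mean error is within one standard error of
    that minimum, at the tree count achieving the minimum.  Ties prefer
    fewer trees, then a larger penalty.
    """
    _require_complete(table.X)
    y = table.y
    counts = np.bincount((y == 1).astype(int), minlength=2)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"cannot stratify {config.cv_folds} folds: minority class has "
            f"only {counts.min()} members"
        )
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**32)
    )
    splits = list(skf.split(table.X, (y == 1).astype(int)))

    records = []
    for n_trees in config.n_trees_grid:
        _, R_full = _rules_and_R(table, int(n_trees), config, fold=-1)
        lambdas = _lambda_grid(config, R_full, y)
        L = len(lambdas)
        errors = np.zeros((config.cv_folds, L))
        nonzeros = np.zeros((config.cv_folds, L))
        for fold, (tr, te) in enumerate(splits):
            rules, R_tr = _rules_and_R(_subset(table, tr), int(n_trees), config, fold=fold)
            R_te = build_endorsements(rules, table.X.iloc[te])
            path = fit_path(R_tr, y[tr], lambdas, tol=config.cv_tol)
            for li, (w, b) in enumerate(path):
                prob = expit(R_te @ w + b)
                pred = np.where(prob >= 0.5, 1, -1)
                errors[fold, li] = float((pred != y[te]).mean())
                nonzeros[fold, li] = int((w != 0).sum())
        mean = errors.mean(axis=0)
        se = errors.std(axis=0, ddof=1) / np.sqrt(config.cv_folds)
        for li, lam in enumerate(lambdas):
            records.append(
                {
                    "n_trees": int(n_trees),
                    "lam": float(lam),
                    "mean_error": mean[li],
                    "se_error": se[li],
                    "mean_nonzero": nonzeros[:, li].mean(),
                }
            )
    cv_table = pd.DataFrame.from_records(records)

    # grid minimum; ties -> fewer trees, then larger lam
    best = cv_table.sort_values(
        ["mean_error", "n_trees", "lam"], ascending=[True, True, False]
    ).iloc[0]
    n_sel = int(best["n_trees"])
    if config.lambda_rule == "min":
        lam_sel = float(best["lam"])
    else:
        cutoff = best["mean_error"] + best["se_error"]
        at_n = cv_table[cv_table["n_trees"] == n_sel]
        lam_sel = float(at_n.loc[at_n["mean_error"] <= cutoff, "lam"].max())
    return CVSelection(n_sel, lam_sel, cv_table)


def rulefit(table: CohortTable, config: FitConfig | None = None) -> RuleEnsemble:
    """End-to-end rule discovery: grow, extract, prune, annotate.

    Returns the selected-rule ensemble with weights, intercept, per-rule
    training support, and direction = sign of the fitted weight.
    """
    config = config or FitConfig()
    _require_complete(table.X)

    singleton = (
        len(config.n_trees_grid) == 1
        and not isinstance(config.lambda_grid, str)
        and len(config.lambda_grid) == 1
    )
    if singleton:
        n_sel, lam_sel = int(config.n_trees_grid[0]), float(config.lambda_grid[0])
        cv = None
    else:
        cv = cv_select(table, config)
        n_sel, lam_sel = cv.n_trees_selected, cv.lambda_selected

    candidates, R = _rules_and_R(table, n_sel, config, fold=-1)
    w, b = fit_sparse_logistic(R, table.y, lam_sel, tol=config.tol)
    keep = np.flatnonzero(w != 0.0)

    selected = []
    for rank, j in enumerate(keep):
        rule = candidates[j]
        selected.append(
            replace(
                rule,
                rule_id=f"rule_{rank + 1:03d}",
                weight=float(w[j]),
                support=rule_support(rule, table.X),
                direction="increasing" if w[j] > 0 else "decreasing",
            )
        )
    ensemble = RuleEnsemble(
        rules=selected,
        intercept=float(b),
        lambda_selected=lam_sel,
        n_trees_selected=n_sel,
        n_candidates=len(candidates),
        objective=_objective(R, table.y.astype(float), w, b, lam_sel),
        seed=config.seed,
        intercept_only=len(selected) == 0,
    )
    if cv is not None:
        ensemble.cv_table = cv.cv_table  # attached for reporting
    return ensemble


def predict_proba(ensemble: RuleEnsemble, x: pd.DataFrame | pd.Series | dict) -> np.ndarray | float:
    """Death probability sigmoid(w^T r(x) + b) for one patient or a table."""
    if isinstance(x, (dict, pd.Series)):
        X = pd.DataFrame([dict(x)])
        return float(predict_proba(ensemble, X)[0])
    eta = np.full(len(x), ensemble.intercept, dtype=float)
    for rule in ensemble.rules:
        eta += rule.weight * rule_endorsement(rule, x)
    return expit(eta)


def _require_complete(X: pd.DataFrame) -> None:
    if X.isna().to_numpy().any():
        bad = [c for c in X.columns if X[c].isna().any()]
        raise ValueError(f"predictor matrix has missing values in columns {bad}; impute first")
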