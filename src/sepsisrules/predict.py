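"""Prediction analysis: logistic regression on rule endorsements, the
repeated 70/30-split AUC protocol, DeLong comparisons, calibration, and the
qSOFA bedside score.

The prediction model is deliberately simple: an unpenalized logistic
regression on the binary endorsement indicators of the retained rules.  Its
discrimination is summarized by the mean (SD) test-set AUC over repeated
stratified 70/30 train/test splits (default 100 repeats).  Competing models
scored on the same subjects are compared with the DeLong test for correlated
AUCs; because DeLong needs paired scores on a common test set, comparisons
are computed on one canonical seed-fixed split while the repeat-wise AUC
distributions are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .cohort import CohortTable
from .rules import Rule, rule_endorsement

__all__ = [
    "RuleLogisticModel",
    "DelongResult",
    "PredictionReport",
    "endorsement_matrix",
    "fit_rule_model",
    "repeated_split_eval",
    "delong_test",
    "calibration_curve",
    "qsofa_score",
]


def endorsement_matrix(rules: Sequence[Rule], table: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """N x m binary endorsement matrix; column j is rule j's indicator."""
    X = table.X if isinstance(table, CohortTable) else table
    ids = [r.rule_id for r in rules]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate rule_ids in the rule set")
    data = {r.rule_id: rule_endorsement(r, X) for r in rules}
    return pd.DataFrame(data, index=X.index, dtype=np.int8)


@dataclass
class RuleLogisticModel:
    """Fitted logistic model over endorsement columns.

    ``ridge_used`` records the documented fallback: when the maximum
    likelihood fit separates or fails to converge, the model is refit with a
    small ridge penalty.
    """

    columns: list[str]
    coef: np.ndarray
    intercept: float
    ridge_used: bool = False
    dropped_constant: list[str] = field(default_factory=list)

    def predict_proba(self, Z: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in Z.columns]
        if missing:
            raise KeyError(f"endorsement matrix lacks fitted columns {missing}")
        A = Z[self.columns].to_numpy(dtype=float)
        return expit(A @ self.coef + self.intercept)

    def summary(self) -> str:
        lines = [
            f"logistic model on {len(self.columns)} endorsement columns",
            f"ridge fallback engaged: {self.ridge_used}",
        ]
        if self.dropped_constant:
            lines.append(f"constant columns dropped: {self.dropped_constant}")
        for c, w in zip(self.columns, self.coef):
            lines.append(f"  {c}: {w:+.4f}")
        lines.append(f"  intercept: {self.intercept:+.4f}")
        return "\n".join(lines)


_RIDGE_ALPHA = 1e-2  # small L2 penalty used only on separation/non-convergence


def fit_rule_model(Z: pd.DataFrame, y: np.ndarray) -> RuleLogisticModel:
    """Maximum-likelihood logistic regression of death (+1) on endorsements.

    Constant columns are dropped (coefficient unidentifiable next to the
    intercept).  On detected separation or non-convergence the fit falls back
    to a lightly ridge-penalized solve, flagged on the returned model.
    """
    y = np.asarray(y)
    if Z.shape[1] < 1:
        raise ValueError("need at least one endorsement column")
    y01 = (y == 1).astype(float)
    if y01.min() == y01.max():
        raise ValueError("outcome is constant; cannot fit")

    keep = [c for c in Z.columns if Z[c].nunique() > 1]
    dropped = [c for c in Z.columns if c not in keep]
    A = Z[keep].to_numpy(dtype=float)

    if not keep:
        base = float(np.log(y01.mean() / (1 - y01.mean())))
        return RuleLogisticModel([], np.zeros(0), base, False, dropped)

    beta, converged = _newton_logistic(A, y01, ridge=0.0)
    separated = np.abs(beta).max() > 15.0  # endorsement scale: |coef|>15 is separation
    if not converged or separated:
        beta, _ = _newton_logistic(A, y01, ridge=_RIDGE_ALPHA)
        ridge_used = True
    else:
        ridge_used = False
    return RuleLogisticModel(keep, beta[:-1], float(beta[-1]), ridge_used, dropped)


def _newton_logistic(
    A: np.ndarray, y01: np.ndarray, ridge: float, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, bool]:
    """Damped Newton-Raphson for (optionally ridge-penalized) logistic MLE.
    The intercept (last coefficient) is never penalized."""
    n, p = A.shape
    D = np.hstack([A, np.ones((n, 1))])
    beta = np.zeros(p + 1)
    beta[-1] = float(np.log((y01.mean() + 1e-12) / (1 - y01.mean() + 1e-12)))
    pen = np.full(p + 1, ridge)
    pen[-1] = 0.0

    def nll(bv):
        eta = D @ bv
        return float(np.logaddexp(0, eta).sum() - y01 @ eta + 0.5 * (pen * bv**2).sum())

    cur = nll(beta)
    for _ in range(max_iter):
        eta = D @ beta
        mu = expit(eta)
        grad = D.T @ (mu - y01) + pen * beta
        if np.abs(grad).max() < tol * n:
            return beta, True
        W = np.clip(mu * (1 - mu), 1e-10, None)
        H = (D * W[:, None]).T @ D + np.diag(pen + 1e-12)
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(40):
            cand = beta - t * step
            val = nll(cand)
            if val <= cur:
                beta, cur = cand, val
                break
            t /= 2.0
        else:
            return beta, False
    return beta, np.abs(D.T @ (expit(D @ beta) - y01) + pen * beta).max() < 1e-6 * n


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    delta: float
    p_value: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, pos: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong V10/V01 placement components."""
    s_pos, s_neg = scores[pos], scores[~pos]
    m, n = len(s_pos), len(s_neg)
    all_r = _midrank(scores)
    pos_r = _midrank(s_pos)
    neg_r = _midrank(s_neg)
    auc = (all_r[pos].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[pos] - pos_r) / n          # per-positive placements
    v01 = 1.0 - (all_r[~pos] - neg_r) / m   # per-negative placements
    return float(auc), v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray, y: np.ndarray) -> DelongResult:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Scores must be paired (same subjects); ``y`` is the outcome in {-1,+1}
    (or {0,1}).  Identical score vectors give delta 0, p = 1 exactly.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(y)
    if not (len(scores_a) == len(scores_b) == len(y)):
        raise ValueError("scores and outcomes must have equal length")
    pos = (y == 1) if set(np.unique(y)) <= {-1, 1} else y.astype(bool)
    if pos.all() or not pos.any():
        raise ValueError("both outcome classes are required")

    auc_a, v10_a, v01_a = _structural_components(scores_a, pos)
    auc_b, v10_b, v01_b = _structural_components(scores_b, pos)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0 or np.array_equal(scores_a, scores_b):
        return DelongResult(auc_a, auc_b, float(delta), 1.0 if delta == 0 else 0.0)
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, float(delta), float(min(p, 1.0)))


@dataclass
class PredictionReport:
    """Repeat-wise AUCs with summary, DeLong comparisons on the canonical
    split, and a calibration table from pooled test-set predictions."""

    per_repeat_auc: list[float]
    mean_auc: float
    sd_auc: float
    comparisons: list[tuple]  # (name, model mean AUC, canonical-split DeLong p)
    calibration: pd.DataFrame
    n_redrawn_splits: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model": "rule-based", "mean_auc": self.mean_auc, "sd_auc": self.sd_auc, "delong_p": np.nan}]
        for name, mean_auc, p in self.comparisons:
            rows.append({"model": name, "mean_auc": mean_auc, "sd_auc": np.nan, "delong_p": p})
        return pd.DataFrame(rows)


def _stratified_split(y: np.ndarray, test_frac: float, rng: np.random.Generator):
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y != 1)
    n_te_pos = max(1, int(round(test_frac * len(idx_pos))))
    n_te_neg = max(1, int(round(test_frac * len(idx_neg))))
    te = np.concatenate(
        [
            rng.permutation(idx_pos)[:n_te_pos],
            rng.permutation(idx_neg)[:n_te_neg],
        ]
    )
    mask = np.zeros(len(y), dtype=bool)
    mask[te] = True
    return np.flatnonzero(~mask), np.flatnonzero(mask)


ScoreFn = Callable[[CohortTable, np.ndarray, np.ndarray], np.ndarray]
# a baseline scorer receives (table, train_idx, test_idx) and returns
# risk scores for the test rows


def repeated_split_eval(
    rules: Sequence[Rule],
    table: CohortTable,
    n_repeats: int = 100,
    test_frac: float = 0.30,
    seed: int = 0,
    baselines: Mapping[str, ScoreFn] | None = None,
    n_bins: int = 10,
) -> PredictionReport:
    """The repeated-split protocol: per repeat, fit the rule-endorsement
    logistic model on a stratified 70% training split and compute the AUC on
    the held-out 30%; report the mean and SD across repeats.

    Baselines (named scorer callables) are evaluated per repeat as well, and
    compared with the rule model by DeLong on the canonical first split.
    Splits whose test part is one-class are redrawn (counted on the report).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    Z = endorsement_matrix(rules, table)
    y = table.y

    aucs: list[float] = []
    baseline_aucs: dict[str, list[float]] = {k: [] for k in (baselines or {})}
    pooled_probs: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    canonical: tuple | None = None
    redrawn = 0

    for rep in range(n_repeats):
        for _ in range(100):
            tr, te = _stratified_split(y, test_frac, rng)
            if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                break
            redrawn += 1
        else:
            raise RuntimeError("could not draw a two-class split")
        model = fit_rule_model(Z.iloc[tr], y[tr])
        probs = model.predict_proba(Z.iloc[te])
        aucs.append(float(roc_auc_score((y[te] == 1).astype(int), probs)))
        pooled_probs.append(probs)
        pooled_y.append(y[te])
        base_scores = {}
        for name, fn in (baselines or {}).items():
            s = np.asarray(fn(table, tr, te), dtype=float)
            baseline_aucs[name].append(float(roc_auc_score((y[te] == 1).astype(int), s)))
            base_scores[name] = s
        if rep == 0:
            canonical = (te, probs, base_scores)

    comparisons = []
    if baselines and canonical is not None:
        te, probs, base_scores = canonical
        for name in baselines:
            res = delong_test(probs, base_scores[name], y[te])
            comparisons.append((name, float(np.mean(baseline_aucs[name])), res.p_value))

    calib = calibration_curve(np.concatenate(pooled_probs), np.concatenate(pooled_y), n_bins)
    return PredictionReport(
        per_repeat_auc=aucs,
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        comparisons=comparisons,
        calibration=calib,
        n_redrawn_splits=redrawn,
    )


def calibration_curve(probs: np.ndarray, y: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width reliability table: per occupied bin, the bin midpoint,
    mean predicted probability, observed event rate, and count."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    events = (y == 1) if set(np.unique(y)) <= {-1, 1} else y.astype(bool)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        if not m.any():
            continue
        rows.append(
            {
                "bin_mid": (edges[b] + edges[b + 1]) / 2.0,
                "mean_predicted": float(probs[m].mean()),
                "observed_rate": float(events[m].mean()),
                "n": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)


def qsofa_score(sbp: float, rr: float, gcs: int) -> int:
    """quick SOFA: one point each for systolic BP <= 100 mmHg, respiratory
    rate >= 22 /min, and GCS < 15.  Range 0-3."""
    if not 3 <= gcs <= 15:
        raise ValueError(f"GCS must be an integer in 3..15, got {gcs}")
    return int(sbp <= 100) + int(rr >= 22) + int(gcs < 15)
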