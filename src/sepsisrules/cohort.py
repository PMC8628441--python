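"""Synthetic sepsis-like ICU cohorts with known ground truth.

Real sepsis cohorts for in-hospital mortality modelling live behind
credentialed access, so every stage of the pipeline is exercised on simulated
cohorts instead.  The generator draws worst-value-within-24h style predictors
from truncated Gaussians (optionally tied by a Gaussian copula), plants
*rules* — conjunctions of threshold conditions — whose endorsement shifts the
death log-odds, and emits survival-style outcome columns (event day for
deaths, discharge day for censored survivors).  Because the outcome is driven
by rule endorsements rather than linear effects, rule-recovery experiments
have exact ground truth, and :func:`bayes_auc` gives the AUC ceiling any
fitted model can approach.

Default predictor marginals emulate the baseline statistics of a sepsis ICU
population of 2021 patients with 675 in-hospital deaths (prevalence 0.334):
worst-within-24h physiological and lab measurements with the pooled
mean/SD of the two outcome groups.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .rules import Rule, parse_rule, rule_endorsement

__all__ = [
    "PredictorSpec",
    "PlantedRule",
    "LOSModel",
    "CohortSpec",
    "CohortTable",
    "generate_cohort",
    "inject_missingness",
    "bayes_auc",
    "default_predictors",
    "write_cohort",
    "read_cohort",
]

WORST_MODES = ("minimum", "maximum", "extreme_from_reference")


@dataclass(frozen=True)
class PredictorSpec:
    """Marginal distribution and 'worst value' convention of one predictor.

    ``worst_mode`` states which direction of a measurement is clinically
    adverse: ``minimum`` (e.g. GCS, MAP), ``maximum`` (e.g. heart rate,
    creatinine), or ``extreme_from_reference`` for two-tailed variables
    (potassium, sodium) where ``reference_interval`` gives the normal range.
    """

    name: str
    mean: float
    sd: float
    lower_bound: float | None = None
    upper_bound: float | None = None
    worst_mode: str = "maximum"
    reference_interval: tuple[float, float] | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be > 0, got {self.sd}")
        if (
            self.lower_bound is not None
            and self.upper_bound is not None
            and not self.lower_bound < self.upper_bound
        ):
            raise ValueError(f"{self.name}: lower_bound must be < upper_bound")
        if self.worst_mode not in WORST_MODES:
            raise ValueError(f"{self.name}: unknown worst_mode {self.worst_mode!r}")
        if (self.worst_mode == "extreme_from_reference") != (
            self.reference_interval is not None
        ):
            raise ValueError(
                f"{self.name}: reference_interval is required iff "
                "worst_mode='extreme_from_reference'"
            )
        if self.reference_interval is not None:
            lo, hi = self.reference_interval
            if not lo < hi:
                raise ValueError(f"{self.name}: reference interval must have lo < hi")


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth risk rule: endorsing it adds ``log_odds_weight`` to the
    death log-odds."""

    rule: Rule
    log_odds_weight: float

    def __post_init__(self):
        if len(self.rule.conditions) < 1:
            raise ValueError("a planted rule needs at least one condition")
        if not np.isfinite(self.log_odds_weight):
            raise ValueError("planted rule weight must be finite")


@dataclass(frozen=True)
class LOSModel:
    """Length-of-stay model: discharge day lognormal (moment-matched to the
    survivor mean/SD in days), death day ``2 + Geometric(death_geom_p) - 1``
    capped at discharge — the outcome window opens on ICU day 2."""

    discharge_mean: float = 11.9
    discharge_sd: float = 10.7
    death_geom_p: float = 1.0 / 6.0

    def __post_init__(self):
        if self.discharge_mean <= 0 or self.discharge_sd <= 0:
            raise ValueError("discharge mean and sd must be positive")
        if not 0 < self.death_geom_p <= 1:
            raise ValueError("death_geom_p must be in (0, 1]")

    @property
    def lognorm_params(self) -> tuple[float, float]:
        """(mu, sigma) of the matched lognormal."""
        sigma2 = np.log1p((self.discharge_sd / self.discharge_mean) ** 2)
        mu = np.log(self.discharge_mean) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; one seed => one cohort."""

    n: int
    predictors: tuple[PredictorSpec, ...]
    correlation: np.ndarray | None = None
    planted_rules: tuple[PlantedRule, ...] = ()
    intercept: float = -0.69  # sigmoid(-0.69) ~ 0.334 baseline death odds
    missing_rate: float = 0.0
    los_model: LOSModel = field(default_factory=LOSModel)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        object.__setattr__(self, "planted_rules", tuple(self.planted_rules))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            object.__setattr__(self, "correlation", C)
            p = len(self.predictors)
            if C.shape != (p, p):
                raise ValueError(f"correlation must be {p}x{p}, got {C.shape}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ValueError("correlation matrix must be positive semi-definite")
        known = set(names)
        for pr in self.planted_rules:
            unknown = set(pr.rule.variables) - known
            if unknown:
                raise ValueError(
                    f"planted rule references unknown predictors {sorted(unknown)}"
                )

    @property
    def predictor_names(self) -> list[str]:
        return [p.name for p in self.predictors]

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "predictors": [dataclasses.asdict(p) for p in self.predictors],
            "correlation": None
            if self.correlation is None
            else np.asarray(self.correlation).tolist(),
            "planted_rules": [
                {"rule": pr.rule.to_dict(), "log_odds_weight": pr.log_odds_weight}
                for pr in self.planted_rules
            ],
            "intercept": self.intercept,
            "missing_rate": self.missing_rate,
            "los_model": dataclasses.asdict(self.los_model),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        preds = []
        for p in d["predictors"]:
            p = dict(p)
            if p.get("reference_interval") is not None:
                p["reference_interval"] = tuple(p["reference_interval"])
            preds.append(PredictorSpec(**p))
        planted = []
        for pr in d.get("planted_rules", []):
            rule = (
                parse_rule(pr["rule"])
                if isinstance(pr["rule"], str)
                else Rule.from_dict(pr["rule"])
            )
            planted.append(PlantedRule(rule, float(pr["log_odds_weight"])))
        corr = d.get("correlation")
        return cls(
            n=int(d["n"]),
            predictors=tuple(preds),
            correlation=None if corr is None else np.asarray(corr, dtype=float),
            planted_rules=tuple(planted),
            intercept=float(d.get("intercept", -0.69)),
            missing_rate=float(d.get("missing_rate", 0.0)),
            los_model=LOSModel(**d["los_model"]) if "los_model" in d else LOSModel(),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class CohortTable:
    """Patients x predictors plus outcome columns — the common currency.

    ``y`` is the in-hospital death outcome coded {-1, +1} (+1 = death);
    ``time`` the event/censoring day; ``event`` True iff death observed.
    In-hospital death is fully observed, so ``y == +1`` iff ``event``.
    """

    X: pd.DataFrame
    y: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        n = len(self.X)
        if not (len(self.y) == len(self.time) == len(self.event) == n):
            raise ValueError("X, y, time, event must have equal length")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("y must be coded in {-1, +1}")
        if (self.time < 0).any():
            raise ValueError("times must be >= 0")
        if not np.array_equal(self.y == 1, self.event):
            raise ValueError("y == +1 must coincide with event == True")
        if self.X.columns.duplicated().any():
            raise ValueError("predictor column names must be unique")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def death_rate(self) -> float:
        return float((self.y == 1).mean())

    def to_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        df.insert(0, "patient_id", self.X.index)
        df["death"] = (self.y == 1).astype(int)
        df["time"] = self.time
        df["event"] = self.event.astype(int)
        return df.reset_index(drop=True)

    def with_X(self, X: pd.DataFrame) -> "CohortTable":
        return CohortTable(X, self.y.copy(), self.time.copy(), self.event.copy())


def default_predictors(include_age: bool = True) -> tuple[PredictorSpec, ...]:
    """Default marginals: pooled mean/SD of worst-within-24h measurements in a
    sepsis ICU cohort (675 deaths / 1346 survivors), with physiologic
    truncation bounds and per-variable worst-value directions."""
    w = 675.0 / 2021.0
    # (name, death mean, death sd, survivor mean, survivor sd,
    #  lower, upper, worst_mode, reference interval)
    rows = [
        ("GCS", 11, 3, 9, 3, 3, 15, "minimum", None),
        ("Temperature", 37, 1.6, 36.4, 1.8, 30, 43, "maximum", None),
        ("MAP", 68.8, 46.8, 64.9, 56.8, 10, 300, "minimum", None),
        ("pH.art", 7.3, 0.1, 7.2, 0.2, 6.6, 7.9, "minimum", None),
        ("Heart.rate", 98.4, 33.1, 101.7, 43.3, 20, 300, "maximum", None),
        ("Resp.rate", 20.3, 16, 17.5, 19.5, 0, 80, "maximum", None),
        ("Sodium", 139.1, 6.6, 137.7, 7.3, 110, 180, "extreme_from_reference", (135, 145)),
        ("Potassium.serum", 4, 0.7, 4.4, 0.9, 1.5, 9, "extreme_from_reference", (3.7, 5.1)),
        ("Creatinine", 1.7, 1.5, 2.3, 1.7, 0.1, 20, "maximum", None),
        ("Hematocrit", 30.8, 5.8, 30.6, 6.7, 10, 60, "minimum", None),
        ("WBC", 15.6, 10.7, 17.2, 20.8, 0.1, 150, "maximum", None),
        ("Albumin", 2.6, 0.4, 2.5, 0.5, 0.5, 6, "minimum", None),
        ("Bilirubin", 1.8, 3, 3.5, 6, 0.05, 50, "maximum", None),
        ("Platelets", 216.2, 139.8, 197, 152.8, 5, 1000, "minimum", None),
    ]
    if include_age:
        rows.append(("Age", 66, 17.8, 69.7, 15.5, 16, 100, "minimum", None))
    specs = []
    for name, m1, s1, m2, s2, lo, hi, mode, ref in rows:
        mean = w * m1 + (1 - w) * m2
        var = w * (s1**2 + m1**2) + (1 - w) * (s2**2 + m2**2) - mean**2
        specs.append(
            PredictorSpec(
                name=name,
                mean=round(mean, 3),
                sd=round(float(np.sqrt(var)), 3),
                lower_bound=float(lo),
                upper_bound=float(hi),
                worst_mode=mode,
                reference_interval=ref,
            )
        )
    return tuple(specs)


def _draw_predictors(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Truncated-Gaussian marginals, joined by a Gaussian copula when a
    correlation matrix is supplied (copula preserves the marginals)."""
    p = len(spec.predictors)
    if spec.correlation is None:
        Z = rng.standard_normal((n, p))
    else:
        # eigendecomposition square root: robust to PSD-but-singular inputs
        vals, vecs = np.linalg.eigh(spec.correlation)
        root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
        Z = rng.standard_normal((n, p)) @ root.T
    cols = {}
    for j, ps in enumerate(spec.predictors):
        if ps.lower_bound is None and ps.upper_bound is None:
            x = ps.mean + ps.sd * Z[:, j]
        else:
            a = -np.inf if ps.lower_bound is None else (ps.lower_bound - ps.mean) / ps.sd
            b = np.inf if ps.upper_bound is None else (ps.upper_bound - ps.mean) / ps.sd
            u = stats.norm.cdf(Z[:, j])
            x = stats.truncnorm.ppf(u, a, b, loc=ps.mean, scale=ps.sd)
        cols[ps.name] = x
    return pd.DataFrame(cols)


def true_risk(spec: CohortSpec, X: pd.DataFrame) -> np.ndarray:
    """True death probability sigmoid(intercept + sum w_k * r_k(x)) per row."""
    eta = np.full(len(X), spec.intercept, dtype=float)
    for pr in spec.planted_rules:
        eta += pr.log_odds_weight * rule_endorsement(pr.rule, X)
    return expit(eta)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a full synthetic cohort: predictors, death outcome, and event or
    censoring day.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    X = _draw_predictors(spec, spec.n, rng)
    X.index = pd.Index([f"p{i:06d}" for i in range(spec.n)], name="patient_id")

    prob = true_risk(spec, X)
    death = rng.random(spec.n) < prob
    y = np.where(death, 1, -1)

    mu, sigma = spec.los_model.lognorm_params
    discharge = np.exp(mu + sigma * rng.standard_normal(spec.n))
    death_day = 2.0 + rng.geometric(spec.los_model.death_geom_p, spec.n) - 1.0
    time = np.where(death, np.minimum(death_day, np.maximum(discharge, 2.0)), discharge)

    table = CohortTable(X, y, time, death)
    if spec.missing_rate > 0:
        table = inject_missingness(
            table, spec.missing_rate, seed=int(rng.integers(0, 2**31))
        )
    return table


def inject_missingness(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """MCAR masking: each predictor cell is set to NaN independently with
    probability ``rate``.  Outcome columns are never masked."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    mask = rng.random(table.X.shape) < rate
    arr = table.X.to_numpy(dtype=float).copy()
    arr[mask] = np.nan
    X = pd.DataFrame(arr, index=table.X.index, columns=table.X.columns)
    return table.with_X(X)


def bayes_auc(spec: CohortSpec, n_mc: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo AUC of the *true* risk score against simulated outcomes —
    the ceiling any fitted model can approach on cohorts from ``spec``."""
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a usable oracle estimate")
    rng = np.random.default_rng(seed)
    X = _draw_predictors(spec, n_mc, rng)
    prob = true_risk(spec, X)
    ydead = rng.random(n_mc) < prob
    if ydead.all() or not ydead.any():
        raise ValueError("degenerate outcome draw; adjust intercept or n_mc")
    # Mann-Whitney AUC via rank statistic
    order = stats.rankdata(prob)
    n1 = int(ydead.sum())
    n0 = n_mc - n1
    auc = (order[ydead].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc)


# ---------------------------------------------------------------------------
# delimited-text interchange


def write_cohort(table: CohortTable, path: str | Path, spec: CohortSpec | None = None) -> None:
    """Write the cohort as CSV (missing cells empty) plus, when the generating
    spec is known, a JSON sidecar with the spec and seed."""
    path = Path(path)
    table.to_frame().to_csv(path, index=False, na_rep="")
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        sidecar.write_text(json.dumps(spec.to_dict(), indent=2))


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path)
    for col in ("patient_id", "death", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort file {path} lacks required column {col!r}")
    X = df.drop(columns=["patient_id", "death", "time", "event"])
    X.index = pd.Index(df["patient_id"], name="patient_id")
    y = np.where(df["death"].to_numpy() == 1, 1, -1)
    return CohortTable(X, y, df["time"].to_numpy(float), df["event"].to_numpy(bool))
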