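"""End-to-end orchestration: simulate -> preprocess -> discover -> analyze ->
evaluate, reproducibly from one config and one master seed.

Every stochastic stage receives a seed derived from the master seed and the
stage name, so changing evaluation settings never perturbs discovery.  Each
run writes plain-text artifacts (CSV tables, JSON models) plus a manifest
with the config hash, derived seeds, and artifact checksums; two runs with
the same config produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    default_predictors,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .preprocess import knn_impute
from .predict import repeated_split_eval
from .rulefit import FitConfig, rulefit
from .survival import FilterCriteria, filter_rules, write_rule_report

__all__ = ["EvalConfig", "RunConfig", "run_pipeline", "StageError"]

logger = logging.getLogger("sepsisrules")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class EvalConfig:
    n_repeats: int = 100
    test_frac: float = 0.30
    n_bins: int = 10


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run."""

    cohort: CohortSpec | str
    fit: FitConfig = field(default_factory=FitConfig)
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    eval: EvalConfig = field(default_factory=EvalConfig)
    output_dir: str = "runs/default"
    seed: int = 0
    log_level: str = "INFO"
    knn_k: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cohort = raw.get("cohort", "default")
        if isinstance(cohort, dict):
            cohort = CohortSpec.from_dict(cohort)
        elif cohort == "default":
            cohort = CohortSpec(n=2021, predictors=default_predictors())
        fit = FitConfig(**_tupled(raw.get("fit", {})))
        filt_raw = dict(raw.get("filter", {}))
        if "support_range" in filt_raw:
            filt_raw["support_range"] = tuple(filt_raw["support_range"])
        filt = FilterCriteria(**filt_raw)
        ev = EvalConfig(**raw.get("eval", {}))
        return cls(
            cohort=cohort,
            fit=fit,
            filter=filt,
            eval=ev,
            output_dir=str(raw.get("output_dir", "runs/default")),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            knn_k=int(raw.get("knn_k", 5)),
        )

    def canonical_dict(self) -> dict:
        d = {
            "cohort": self.cohort.to_dict()
            if isinstance(self.cohort, CohortSpec)
            else str(self.cohort),
            "fit": dataclasses.asdict(self.fit),
            "filter": dataclasses.asdict(self.filter),
            "eval": dataclasses.asdict(self.eval),
            "seed": self.seed,
            "knn_k": self.knn_k,
        }
        return d


def _tupled(fit_raw: dict) -> dict:
    fit_raw = dict(fit_raw)
    for key in ("n_trees_grid", "lambda_grid"):
        if key in fit_raw and isinstance(fit_raw[key], list):
            fit_raw[key] = tuple(fit_raw[key])
    return fit_raw


def derive_seed(master: int, stage: str) -> int:
    """Stage-specific seed: CRC32 of the stage name mixed with the master."""
    return (zlib.crc32(stage.encode("utf8")) ^ (master * 2654435761)) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # pragma: no cover - filesystem dependent
        raise StageError("setup", e)

    seeds = {s: derive_seed(config.seed, s) for s in ("simulate", "discover", "evaluate")}
    artifacts: dict[str, Path] = {}
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config.canonical_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "derived_seeds": seeds,
        "version": __version__,
    }

    def _finish_failure(stage: str, err: BaseException):
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest["artifacts"] = {k: _sha256(v) for k, v in artifacts.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, err)

    # -- simulate / load ----------------------------------------------------
    try:
        if isinstance(config.cohort, CohortSpec):
            spec = dataclasses.replace(config.cohort, seed=seeds["simulate"])
            logger.info("simulating cohort (n=%d)", spec.n)
            table = generate_cohort(spec)
            write_cohort(table, out / "cohort.csv", spec)
        else:
            logger.info("loading cohort from %s", config.cohort)
            table = read_cohort(config.cohort)
            write_cohort(table, out / "cohort.csv")
        artifacts["cohort"] = out / "cohort.csv"
    except StageError:
        raise
    except Exception as e:
        _finish_failure("simulate", e)

    # -- preprocess ---------------------------------------------------------
    try:
        if table.X.isna().to_numpy().any():
            logger.info("imputing missing predictors (kNN, k=%d)", config.knn_k)
            table = table.with_X(knn_impute(table.X, k=config.knn_k))
        write_cohort(table, out / "cohort_complete.csv")
        artifacts["cohort_complete"] = out / "cohort_complete.csv"
    except Exception as e:
        _finish_failure("preprocess", e)

    # -- discover -----------------------------------------------------------
    try:
        fit = dataclasses.replace(config.fit, seed=seeds["discover"])
        logger.info("running rule discovery (grids: trees=%s)", fit.n_trees_grid)
        ensemble = rulefit(table, fit)
        (out / "ensemble.json").write_text(ensemble.to_json())
        artifacts["ensemble"] = out / "ensemble.json"
        if hasattr(ensemble, "cv_table"):
            ensemble.cv_table.to_csv(out / "cv_table.csv", index=False)
            artifacts["cv_table"] = out / "cv_table.csv"
    except Exception as e:
        _finish_failure("discover", e)

    # -- analyze / filter ---------------------------------------------------
    try:
        retained, discarded = filter_rules(ensemble.rules, table, config.filter)
        write_rule_report(retained, table, out / "rule_report.csv")
        pd.DataFrame(
            [{"rule_id": r.rule_id, "reason": reason} for r, reason in discarded]
        ).to_csv(out / "discarded_rules.csv", index=False)
        artifacts["rule_report"] = out / "rule_report.csv"
        artifacts["discarded_rules"] = out / "discarded_rules.csv"
        logger.info("rules: %d discovered, %d retained", len(ensemble.rules), len(retained))
    except Exception as e:
        _finish_failure("analyze", e)

    # -- evaluate -----------------------------------------------------------
    try:
        kept_rules = [rep.rule for rep in retained]
        if not kept_rules:
            raise ValueError("no rules survived filtering; nothing to evaluate")
        report = repeated_split_eval(
            kept_rules,
            table,
            n_repeats=config.eval.n_repeats,
            test_frac=config.eval.test_frac,
            seed=seeds["evaluate"],
            n_bins=config.eval.n_bins,
        )
        report.to_frame().to_csv(out / "prediction_report.csv", index=False)
        report.calibration.to_csv(out / "calibration.csv", index=False)
        artifacts["prediction_report"] = out / "prediction_report.csv"
        artifacts["calibration"] = out / "calibration.csv"
        manifest["mean_auc"] = report.mean_auc
        manifest["sd_auc"] = report.sd_auc
    except Exception as e:
        _finish_failure("evaluate", e)

    manifest["n_rules_discovered"] = len(ensemble.rules)
    manifest["n_rules_retained"] = len(retained)
    manifest["artifacts"] = {k: _sha256(v) for k, v in artifacts.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
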