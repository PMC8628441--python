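"""Feature preparation: worst-value-within-24h extraction and kNN imputation.

ICU predictors arrive as timestamped measurement records; modelling uses one
value per patient per variable — the *worst* (most clinically adverse) value
observed in the first 24 hours after ICU admission.  Which direction is
"worse" is a per-variable convention carried on :class:`PredictorSpec`:
the minimum for variables where low is dangerous (GCS, MAP, arterial pH,
albumin, platelets, hematocrit), the maximum where high is dangerous (heart
rate, respiratory rate, creatinine, bilirubin, WBC, temperature), and the
value farthest outside the reference interval for two-tailed variables
(potassium, sodium).

Remaining holes are filled with k-nearest-neighbour imputation (default
k = 5): each missing cell becomes the mean of that column over the k nearest
complete donors, with Euclidean distance computed on the z-scored columns the
two rows share.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import PredictorSpec

__all__ = [
    "MeasurementRecord",
    "worst_value_24h",
    "knn_impute",
    "read_records",
    "write_records",
]

WINDOW_HOURS = 24.0


@dataclass(frozen=True)
class MeasurementRecord:
    """One timestamped measurement: patient, variable, hours since ICU
    admission, value."""

    patient_id: str
    variable: str
    time_offset: float
    value: float

    def __post_init__(self):
        if self.time_offset < 0:
            raise ValueError(
                f"time_offset must be >= 0 hours, got {self.time_offset} "
                f"({self.patient_id}/{self.variable})"
            )


def _worst(values: np.ndarray, spec: PredictorSpec) -> float:
    """Pick the worst value per the variable's convention.  For
    extreme_from_reference, records outside the reference interval are ranked
    by their distance beyond the nearer bound; if all fall inside, the one
    farthest from the interval midpoint wins.  Ties keep the earliest record
    (stable argmax)."""
    if spec.worst_mode == "minimum":
        return float(values.min())
    if spec.worst_mode == "maximum":
        return float(values.max())
    lo, hi = spec.reference_interval
    outside = np.where(values > hi, values - hi, np.where(values < lo, lo - values, 0.0))
    if outside.max() > 0:
        return float(values[int(np.argmax(outside))])
    mid = (lo + hi) / 2.0
    return float(values[int(np.argmax(np.abs(values - mid)))])


def worst_value_24h(
    records: Iterable[MeasurementRecord],
    specs: Sequence[PredictorSpec],
    patient_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Collapse timestamped records to one worst value per patient/variable.

    Only records with ``time_offset <= 24`` hours count; a patient/variable
    pair with no in-window record yields NaN.  Rows follow ``patient_ids``
    when given, else first-appearance order of patients in ``records``.
    """
    records = list(records)
    if not records:
        raise ValueError("no measurement records supplied")
    by_name = {s.name: s for s in specs}
    unknown = {r.variable for r in records} - set(by_name)
    if unknown:
        raise ValueError(f"records reference undeclared variables {sorted(unknown)}")

    if patient_ids is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.patient_id, None)
        patient_ids = list(seen)

    grouped: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if r.time_offset <= WINDOW_HOURS:
            grouped.setdefault((r.patient_id, r.variable), []).append(r.value)

    out = pd.DataFrame(
        np.nan,
        index=pd.Index(patient_ids, name="patient_id"),
        columns=[s.name for s in specs],
        dtype=float,
    )
    for (pid, var), vals in grouped.items():
        if pid in out.index:
            out.loc[pid, var] = _worst(np.asarray(vals, dtype=float), by_name[var])
    return out


def knn_impute(X: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing cells with the mean of the k nearest rows' values.

    Distance between two rows is the Euclidean distance over the z-scored
    columns observed in *both* rows; only rows observing the target column are
    eligible donors.  Neighbour ties are broken by row order (stable sort).
    Observed cells are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    obs = ~np.isnan(arr)

    all_missing = np.flatnonzero(~obs.any(axis=1))
    if all_missing.size:
        raise ValueError(
            f"row(s) {list(X.index[all_missing])} have every predictor missing; "
            "cannot impute"
        )
    short = [X.columns[j] for j in range(p) if obs[:, j].sum() < k]
    if short:
        raise ValueError(f"column(s) {short} have fewer than k={k} observed values")

    mu = np.nanmean(arr, axis=0)
    sd = np.nanstd(arr, axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (arr - mu) / sd

    out = arr.copy()
    for i in np.flatnonzero(~obs.all(axis=1)):
        diff = Z - Z[i]
        shared = obs & obs[i]
        diff[~shared] = 0.0
        d2 = np.einsum("ij,ij->i", diff, diff)
        d2[shared.sum(axis=1) == 0] = np.inf  # no shared coords: ineligible
        d2[i] = np.inf  # a row is never its own donor
        for j in np.flatnonzero(~obs[i]):
            cand = np.flatnonzero(obs[:, j] & np.isfinite(d2))
            if cand.size < k:
                raise ValueError(
                    f"fewer than k={k} donors for row {X.index[i]!r}, "
                    f"column {X.columns[j]!r}"
                )
            nearest = cand[np.argsort(d2[cand], kind="stable")[:k]]
            out[i, j] = arr[nearest, j].mean()
    return pd.DataFrame(out, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# delimited-text interchange


def read_records(path: str | Path) -> list[MeasurementRecord]:
    """Read records from CSV with columns
    patient_id, variable, time_offset_h, value."""
    df = pd.read_csv(path)
    required = {"patient_id", "variable", "time_offset_h", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"record file {path} lacks columns {sorted(missing)}")
    return [
        MeasurementRecord(str(r.patient_id), str(r.variable), float(r.time_offset_h), float(r.value))
        for r in df.itertuples(index=False)
    ]


def write_records(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "variable": [r.variable for r in records],
            "time_offset_h": [r.time_offset for r in records],
            "value": [r.value for r in records],
        }
    ).to_csv(path, index=False)
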