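"""Cohort metadata, referral-to-death intervals, and the median split.

Each patient carries the date of their first palliative-care referral
and their death date; the interval between the two (whole days, by
date subtraction) measures how early palliative care was integrated.
The cohort is split at the median interval: patients at or above the
threshold form the *early integration* group, the rest the *late
referral* group — mirroring a >= 22-day cut at a median of 22 days.

For an even cohort size the threshold defaults to the lower median
(an attained interval value) so the ">= threshold" rule always
references a realizable day count; a midpoint rule is available.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PatientRecord",
    "GroupAssignment",
    "MedianSplitter",
    "split_by_median",
    "cohort_summary",
    "percent",
    "read_cohort",
    "write_cohort_csv",
    "EARLY",
    "LATE",
]

EARLY = "early"
LATE = "late"


def _as_date(value: Union[str, dt.date]) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifiers, key dates, optional covariates."""

    patient_id: str
    referral_date: dt.date
    death_date: dt.date
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "referral_date", _as_date(self.referral_date))
        object.__setattr__(self, "death_date", _as_date(self.death_date))
        if self.death_date < self.referral_date:
            raise ValueError(
                f"patient {self.patient_id}: death_date precedes referral_date"
            )

    @property
    def referral_to_death_days(self) -> int:
        """Interval from first palliative referral to death, in days."""
        return (self.death_date - self.referral_date).days


@dataclass
class GroupAssignment:
    """Partition of the cohort into early / late groups at a threshold."""

    groups: dict[str, str]
    threshold_days: float

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values()} - {EARLY, LATE}
        if bad:
            raise ValueError(f"unknown group labels {bad}")

    def group_of(self, patient_id: str) -> str:
        return self.groups[patient_id]

    def patients(self, group: str) -> list[str]:
        return [p for p, g in self.groups.items() if g == group]

    @property
    def n_early(self) -> int:
        return sum(g == EARLY for g in self.groups.values())

    @property
    def n_late(self) -> int:
        return sum(g == LATE for g in self.groups.values())

    def __len__(self) -> int:
        return len(self.groups)


class MedianSplitter(BaseEstimator):
    """Median-threshold dichotomizer for referral-to-death intervals.

    scikit-learn style: ``fit`` learns the median threshold from
    intervals, ``predict`` labels intervals "early" (>= threshold) or
    "late" (< threshold).

    Parameters
    ----------
    rule : {"lower", "midpoint"}, default "lower"
        Even-n median convention. "lower" takes the lower middle
        order statistic (always an attained value); "midpoint" the
        usual average of the two middle values.

    Attributes
    ----------
    threshold_ : float
        The learned median threshold in days.
    """

    def __init__(self, rule: str = "lower"):
        self.rule = rule

    def fit(self, X: Sequence[float], y=None) -> "MedianSplitter":
        intervals = np.asarray(X, dtype=float).ravel()
        if intervals.size < 2:
            raise ValueError("need at least 2 patients to split at the median")
        if np.isnan(intervals).any():
            raise ValueError("intervals contain missing values")
        if self.rule == "lower":
            self.threshold_ = float(np.sort(intervals)[(intervals.size - 1) // 2])
        elif self.rule == "midpoint":
            self.threshold_ = float(np.median(intervals))
        else:
            raise ValueError(f"unknown median rule {self.rule!r}")
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise ValueError("MedianSplitter is not fitted")
        intervals = np.asarray(X, dtype=float).ravel()
        return np.where(intervals >= self.threshold_, EARLY, LATE)


def split_by_median(
    cohort: Iterable[PatientRecord], rule: str = "lower"
) -> GroupAssignment:
    """Split a cohort at the median referral-to-death interval.

    Patients with interval >= threshold go to the early-integration
    group (ties at the threshold are early, the ">= median" rule);
    the rest to the late-referral group.

    Raises
    ------
    ValueError
        Fewer than 2 patients.
    """
    records = list(cohort)
    intervals = [r.referral_to_death_days for r in records]
    splitter = MedianSplitter(rule=rule).fit(intervals)
    labels = splitter.predict(intervals)
    return GroupAssignment(
        {r.patient_id: str(lab) for r, lab in zip(records, labels)},
        threshold_days=splitter.threshold_,
    )


def percent(k: int, n: int) -> float:
    """Percentage with one-decimal half-up rounding (72/119 -> 60.5)."""
    if n == 0:
        return 0.0
    return float(
        (Decimal(k) * 100 / Decimal(n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def cohort_summary(
    cohort: Iterable[PatientRecord],
    groups: Optional[GroupAssignment] = None,
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Baseline-characteristics table: counts and percentages.

    One row per covariate level with n and percent of the cohort
    (one decimal, half-up). Numeric covariates are summarized by
    mean/SD instead of levels. Interval median/IQR and group sizes
    are attached in ``DataFrame.attrs``.
    """
    records = list(cohort)
    n = len(records)
    intervals = np.array([r.referral_to_death_days for r in records], dtype=float)

    if covariates is None:
        covariates = sorted({k for r in records for k in r.covariates})

    rows: list[dict] = []
    for cov in covariates:
        values = [r.covariates.get(cov) for r in records]
        present = [v for v in values if v is not None]
        numeric = present and all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in present)
        if numeric:
            arr = np.asarray(present, dtype=float)
            rows.append(
                {
                    "covariate": cov,
                    "level": "mean (SD)",
                    "n": len(present),
                    "percent": percent(len(present), n),
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if len(present) > 1 else 0.0,
                }
            )
        else:
            for level in sorted({str(v) for v in present}):
                k = sum(str(v) == level for v in present)
                rows.append(
                    {
                        "covariate": cov,
                        "level": level,
                        "n": k,
                        "percent": percent(k, n),
                        "mean": np.nan,
                        "sd": np.nan,
                    }
                )
    table = pd.DataFrame(rows, columns=["covariate", "level", "n", "percent", "mean", "sd"])
    q1, med, q3 = (np.percentile(intervals, [25, 50, 75]) if n else (np.nan,) * 3)
    table.attrs["n_patients"] = n
    table.attrs["interval_median"] = float(med)
    table.attrs["interval_iqr"] = (float(q1), float(q3))
    if groups is not None:
        table.attrs["n_early"] = groups.n_early
        table.attrs["n_late"] = groups.n_late
        table.attrs["threshold_days"] = groups.threshold_days
    return table


_DATE_COLS = ("referral_date", "death_date")


def read_cohort(path: Union[str, Path]) -> list[PatientRecord]:
    """Read patient records from CSV (ISO-8601 dates).

    Columns: patient_id, referral_date, death_date, plus any covariate
    columns. Rows with missing or malformed dates are collected and
    reported together in one error.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    errors: list[str] = []
    with path.open(encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                pid = row["patient_id"]
                referral, death = row["referral_date"], row["death_date"]
                if not referral or not death:
                    raise ValueError("missing referral_date or death_date")
                covs = {
                    k: _maybe_number(v)
                    for k, v in row.items()
                    if k not in ("patient_id", *_DATE_COLS) and v not in (None, "")
                }
                records.append(PatientRecord(pid, referral, death, covs))
            except (KeyError, ValueError) as exc:
                errors.append(f"{path}, line {i}: {exc}")
    if errors:
        raise ValueError("invalid cohort rows:\n  " + "\n  ".join(errors))
    if not records:
        raise ValueError(f"cohort file {path} has no patients")
    return records


def _maybe_number(value: str) -> object:
    try:
        f = float(value)
    except (TypeError, ValueError):
        return value
    return int(f) if f.is_integer() else f


def write_cohort_csv(cohort: Iterable[PatientRecord], path: Union[str, Path]) -> None:
    """Write patient records to CSV (round-trips through read_cohort)."""
    records = list(cohort)
    cov_cols = sorted({k for r in records for k in r.covariates})
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", *_DATE_COLS, *cov_cols])
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.referral_date.isoformat(),
                    r.death_date.isoformat(),
                    *[r.covariates.get(c, "") for c in cov_cols],
                ]
            )
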