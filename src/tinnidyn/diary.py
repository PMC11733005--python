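"""Diary and outcome I/O, compliance, and variability eligibility.

The daily diary asks ten questions each evening on a 0-100 visual analogue
scale (VAS); the app accepts a day's entry only once *all* ten questions are
answered, so a day is either complete or absent in well-formed data. The
treatment phase spans 12 weeks = 84 days, indexed 0..83.

Compliance is the fraction of the 84 expected days that were completed.
Eligibility for feature extraction requires minimal variability: every
question must show a strictly positive range over its observed days.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical question codes, in instrument order.
QUESTION_CODES: tuple[str, ...] = (
    "t-distress",
    "t-distress-day",
    "t-loudness",
    "t-loudness-max",
    "t-thoughts",
    "happiness",
    "jawbone",
    "movement",
    "neck",
    "stress",
)

#: Expected number of daily entries over the 12-week treatment phase.
N_DAYS: int = 84


class DiaryValidationError(ValueError):
    """Raised when a diary or outcome table violates its contract."""


@dataclass(frozen=True)
class CgiOutcome:
    """Clinical Global Impression - Improvement at final visit.

    cgi is an integer in 1..7 (1 = very much better ... 7 = very much
    worse); categories 1-3 denote clinical improvement.
    """

    patient_id: str
    cgi: int

    def __post_init__(self) -> None:
        if not (1 <= int(self.cgi) <= 7):
            raise DiaryValidationError(
                f"CGI-I must be in 1..7, got {self.cgi} for patient {self.patient_id}"
            )


@dataclass
class PatientDiary:
    """One patient's per-question observed series over the 84-day window.

    ``series`` maps each question code to an ordered list of (day, value)
    pairs over observed days only; ``completed_days`` is the derived set of
    days on which all ten questions have values. Partial days (possible in
    malformed or synthetic data) stay in ``series`` but never count toward
    ``completed_days``.
    """

    patient_id: str
    series: dict[str, list[tuple[int, float]]]
    completed_days: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        for q in QUESTION_CODES:
            self.series.setdefault(q, [])
            self.series[q] = sorted(self.series[q], key=lambda dv: dv[0])
        if not self.completed_days:
            self.completed_days = frozenset(self._derive_completed_days())

    def _derive_completed_days(self) -> set[int]:
        per_day: dict[int, int] = {}
        for q in QUESTION_CODES:
            for day, _ in self.series[q]:
                per_day[day] = per_day.get(day, 0) + 1
        return {d for d, k in per_day.items() if k == len(QUESTION_CODES)}

    def values(self, question: str) -> np.ndarray:
        """Observed values for one question, in day order, gaps closed."""
        return np.asarray([v for _, v in self.series[question]], dtype=float)


def _validate_row(i: int, day: int, question: str, value: float) -> None:
    if question not in QUESTION_CODES:
        raise DiaryValidationError(f"row {i}: unknown question code {question!r}")
    if not (0 <= day <= N_DAYS - 1):
        raise DiaryValidationError(f"row {i}: day {day} outside 0..{N_DAYS - 1}")
    if not np.isfinite(value) or not (0.0 <= value <= 100.0):
        raise DiaryValidationError(f"row {i}: value {value} outside [0, 100]")


def read_diary(path) -> list[PatientDiary]:
    """Read a long-format diary CSV (patient_id,day,question,value).

    Entries are grouped per patient and ordered by day within each
    question; completed days are derived. Raises DiaryValidationError for
    out-of-range values, unknown question codes, or duplicate
    (patient, day, question) triples, naming the offending row.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = ["patient_id", "day", "question", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DiaryValidationError(f"diary file missing columns: {missing}")

    for i, row in enumerate(df.itertuples(index=False)):
        _validate_row(i, int(row.day), str(row.question), float(row.value))
    dup = df.duplicated(subset=["patient_id", "day", "question"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        r = df.iloc[i]
        raise DiaryValidationError(
            f"row {i}: duplicate entry (patient {r['patient_id']}, "
            f"day {int(r['day'])}, question {r['question']})"
        )

    diaries: list[PatientDiary] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        series: dict[str, list[tuple[int, float]]] = {q: [] for q in QUESTION_CODES}
        for row in grp.itertuples(index=False):
            series[str(row.question)].append((int(row.day), float(row.value)))
        diaries.append(PatientDiary(patient_id=str(pid), series=series))
    return diaries


def read_outcomes(path) -> list[CgiOutcome]:
    """Read the outcome CSV (patient_id,cgi); one row per patient."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns or "cgi" not in df.columns:
        raise DiaryValidationError("outcome file must have columns patient_id,cgi")
    if df["patient_id"].duplicated().any():
        pid = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DiaryValidationError(f"duplicate outcome for patient {pid}")
    return [CgiOutcome(str(r.patient_id), int(r.cgi)) for r in df.itertuples(index=False)]


def day_index(date: str | _dt.date, start_date: str | _dt.date) -> int:
    """Convert an ISO date to a 0-based day index relative to a start date."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if isinstance(start_date, str):
        start_date = _dt.date.fromisoformat(start_date)
    return (date - start_date).days


def compliance(p: PatientDiary) -> float:
    """Fraction of the 84 expected days completed (all ten questions)."""
    return len(p.completed_days) / N_DAYS


def filter_by_compliance(
    diaries: list[PatientDiary], min_rate: float
) -> list[PatientDiary]:
    """Patients with compliance >= min_rate, order preserved.

    The threshold is inclusive: at min_rate 0.50, a patient with exactly
    42 of 84 completed days is retained.
    """
    if not (0.0 <= min_rate <= 1.0):
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    return [p for p in diaries if compliance(p) >= min_rate]


def variability_eligible(p: PatientDiary) -> bool:
    """True iff every question has strictly positive range over observed days.

    A question constant over the whole window makes several time-series
    features degenerate, so such patients are excluded before feature
    extraction. Raises DiaryValidationError if any question has no
    observations at all (patient not assessable).
    """
    for q in QUESTION_CODES:
        x = p.values(q)
        if x.size == 0:
            raise DiaryValidationError(
                f"patient {p.patient_id}: question {q!r} has no observations"
            )
        if x.max() - x.min() <= 0:
            return False
    return True
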