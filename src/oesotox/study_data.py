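"""Data model, delimited-file I/O and the packaged 21-study fixture.

Two granularities of observation coexist in re-irradiation dose/toxicity
pooling: some source studies report patient-by-patient doses
(:class:`PatientRecord`, the Bernoulli unit of the likelihood), others only
grouped summaries (:class:`CohortSummary`, the binomial unit).  Both are read
and written as plain CSV (UTF-8, header row, "." decimal, ``NA``/``NR``
accepted as missing).  No imputation is ever performed: missing values stay
missing and complete-case filtering happens downstream, per model.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "CohortSummary",
    "ToxicityEvent",
    "FixtureData",
    "SchemaError",
    "ValidationError",
    "PATIENT_COLUMNS",
    "COHORT_COLUMNS",
    "read_patients",
    "write_patients",
    "read_cohorts",
    "write_cohorts",
    "builtin_fixture",
    "median_split",
    "MedianSplit",
]

MISSING_TOKENS = ("", "NA", "NR", "NaN", "nan")

PATIENT_COLUMNS = [
    "patient_id",
    "study_id",
    "cdmax_gy_eqd2",
    "chemo",
    "interval_months",
    "event",
    "event_timing",
    "event_grade",
]

COHORT_COLUMNS = [
    "study_id",
    "n",
    "events",
    "cdmax_rep_gy_eqd2",
    "chemo_fraction",
    "interval_rep_months",
    "followup_rep_months",
]

EVENT_TIMINGS = ("none", "acute", "late", "both")
EVENT_CATEGORIES = (
    "perforation_tof",
    "oesophagitis_dysphagia",
    "bleeding",
    "stenosis",
)


class SchemaError(ValueError):
    """A delimited file does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a domain invariant; message carries the row number."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: cumulative oesophageal D_max (EQD2 Gy), covariates, outcome.

    ``chemo`` is 1 if concurrent chemotherapy was given with re-irradiation,
    0 if not, ``None`` if unrecorded.  ``event`` is 1 for any grade >=3
    oesophageal toxicity (acute or late).
    """

    patient_id: str
    study_id: str
    cdmax: float
    chemo: int | None
    interval_months: float | None
    event: int
    event_timing: str = "none"
    event_grade: int | None = None
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if self.cdmax < 0:
            raise ValidationError(f"cdmax must be >= 0, got {self.cdmax}")
        if self.chemo not in (0, 1, None):
            raise ValidationError(f"chemo must be 0, 1 or missing, got {self.chemo}")
        if self.interval_months is not None and self.interval_months < 0:
            raise ValidationError("interval_months must be >= 0")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event}")
        if self.event_timing not in EVENT_TIMINGS:
            raise ValidationError(f"unknown event_timing {self.event_timing!r}")
        if (self.event == 1) != (self.event_timing != "none"):
            raise ValidationError(
                f"event={self.event} inconsistent with event_timing={self.event_timing!r}"
            )
        if self.event_grade is not None and self.event_grade not in (3, 4, 5):
            raise ValidationError(f"event_grade must be 3, 4 or 5, got {self.event_grade}")
        if self.event == 0 and self.event_grade is not None:
            raise ValidationError("event_grade present for a non-event")


@dataclass(frozen=True)
class CohortSummary:
    """One study's grouped data: n, grade >=3 event count, representative
    (median) cumulative D_max, chemotherapy fraction, median interval."""

    study_id: str
    n: int
    events: int
    cdmax_rep: float
    chemo_fraction: float | None
    interval_rep_months: float | None = None
    followup_rep_months: float | None = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError(f"n must be positive, got {self.n}")
        if not 0 <= self.events <= self.n:
            raise ValidationError(
                f"events must lie in [0, n]={self.n}, got {self.events}"
            )
        if self.cdmax_rep < 0:
            raise ValidationError("cdmax_rep must be >= 0")
        if self.chemo_fraction is not None and not 0 <= self.chemo_fraction <= 1:
            raise ValidationError(
                f"chemo_fraction must lie in [0, 1], got {self.chemo_fraction}"
            )


@dataclass(frozen=True)
class ToxicityEvent:
    """One cell of the event-type table: count of raw grade >=3 events of a
    given (timing, grade, category) within a study."""

    study_id: str
    timing: str
    grade: int
    category: str
    count: int

    def __post_init__(self) -> None:
        if self.timing not in ("acute", "late"):
            raise ValidationError(f"timing must be acute or late, got {self.timing!r}")
        if self.grade not in (3, 4, 5):
            raise ValidationError(f"grade must be 3, 4 or 5, got {self.grade}")
        if self.category not in EVENT_CATEGORIES:
            raise ValidationError(f"unknown toxicity category {self.category!r}")
        if self.count <= 0:
            raise ValidationError("count must be a positive integer")


class FixtureData(NamedTuple):
    cohorts: list[CohortSummary]
    toxicity_events: list[ToxicityEvent]
    patients: list[PatientRecord]  # reconstructed pseudo-patient expansion


# ---------------------------------------------------------------------------
# CSV I/O


def _read_csv(path, mandatory: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(v)


def read_patients(path) -> list[PatientRecord]:
    """Read patient-level records, rejecting invalid rows with row numbers."""
    df = _read_csv(path, PATIENT_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    study_id=str(row.study_id),
                    cdmax=float(row.cdmax_gy_eqd2),
                    chemo=_opt_int(row.chemo),
                    interval_months=_opt_float(row.interval_months),
                    event=int(row.event),
                    event_timing=(
                        "none"
                        if _opt_float(row.event) == 0
                        and (row.event_timing is None or pd.isna(row.event_timing))
                        else str(row.event_timing)
                    ),
                    event_grade=_opt_int(row.event_grade),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
    return records


def write_patients(records: Iterable[PatientRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "study_id": r.study_id,
            "cdmax_gy_eqd2": r.cdmax,
            "chemo": r.chemo,
            "interval_months": r.interval_months,
            "event": r.event,
            "event_timing": r.event_timing,
            "event_grade": r.event_grade,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False, na_rep="NA")


def read_cohorts(path) -> list[CohortSummary]:
    """Read grouped study-level records, rejecting invalid rows."""
    df = _read_csv(path, COHORT_COLUMNS)
    extra_cols = [c for c in df.columns if c not in COHORT_COLUMNS]
    cohorts = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            cohorts.append(
                CohortSummary(
                    study_id=str(row["study_id"]),
                    n=int(row["n"]),
                    events=int(row["events"]),
                    cdmax_rep=float(row["cdmax_rep_gy_eqd2"]),
                    chemo_fraction=_opt_float(row["chemo_fraction"]),
                    interval_rep_months=_opt_float(row["interval_rep_months"]),
                    followup_rep_months=_opt_float(row["followup_rep_months"]),
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
    return cohorts


def write_cohorts(cohorts: Iterable[CohortSummary], path) -> None:
    rows = [
        {
            "study_id": c.study_id,
            "n": c.n,
            "events": c.events,
            "cdmax_rep_gy_eqd2": c.cdmax_rep,
            "chemo_fraction": c.chemo_fraction,
            "interval_rep_months": c.interval_rep_months,
            "followup_rep_months": c.followup_rep_months,
        }
        for c in cohorts
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Packaged fixture


def _data_path(name: str):
    return importlib.resources.files("oesotox.data").joinpath(name)


def _expand_cohort(
    cohort: CohortSummary, events: list[ToxicityEvent]
) -> list[PatientRecord]:
    """Deterministic pseudo-patient expansion of one grouped cohort.

    Every patient sits at the study's representative dose; chemotherapy is
    assigned to the first round(n * chemo_fraction) patients and events to
    the first `events` patients (events therefore co-occur with chemotherapy
    maximally — a documented reconstruction convention, not data).  Timing
    and grade of the event patients are rebuilt from the event-type table:
    dual-timing patients pair the study's acute and late raw events.
    """
    dual = int(cohort.extra.get("dual_timing_patients", 0) or 0)
    acute = sorted(
        [(e.grade, e.category) for e in events if e.timing == "acute" for _ in range(e.count)],
        reverse=True,
    )
    late = sorted(
        [(e.grade, e.category) for e in events if e.timing == "late" for _ in range(e.count)],
        reverse=True,
    )
    per_patient: list[tuple[str, int]] = []
    for _ in range(dual):
        a, l = acute.pop(0), late.pop(0)
        per_patient.append(("both", max(a[0], l[0])))
    per_patient += [("acute", g) for g, _ in acute] + [("late", g) for g, _ in late]
    if not per_patient:  # no event-table rows: grouped count only
        per_patient = [("late", 3)] * cohort.events
    if len(per_patient) != cohort.events:
        raise ValidationError(
            f"{cohort.study_id}: event-table expansion yields {len(per_patient)} "
            f"patients but grouped count is {cohort.events}"
        )
    n_chemo = (
        None if cohort.chemo_fraction is None else round(cohort.n * cohort.chemo_fraction)
    )
    records = []
    for i in range(cohort.n):
        has_event = i < cohort.events
        timing, grade = per_patient[i] if has_event else ("none", None)
        records.append(
            PatientRecord(
                patient_id=f"recon_{cohort.study_id}_{i + 1:03d}",
                study_id=cohort.study_id,
                cdmax=cohort.cdmax_rep,
                chemo=None if n_chemo is None else int(i < n_chemo),
                interval_months=cohort.interval_rep_months,
                event=int(has_event),
                event_timing=timing,
                event_grade=grade,
                reconstructed=True,
            )
        )
    return records


def builtin_fixture() -> FixtureData:
    """The packaged 21-study dataset (505 patients, 57 raw / 49 grouped events).

    Returns the transcribed study table, the raw event-type table, and a
    pseudo patient-level expansion of the grouped data (flagged
    ``reconstructed``) for exercising patient-level code paths.  Conservation
    invariants are enforced at load time.
    """
    cohorts = read_cohorts(_data_path("table1_cohorts.csv"))
    edf = pd.read_csv(_data_path("table2_events.csv"))
    events = [
        ToxicityEvent(
            study_id=str(r.study_id),
            timing=str(r.timing),
            grade=int(r.grade),
            category=str(r.category),
            count=int(r.count),
        )
        for r in edf.itertuples(index=False)
    ]

    raw_total = sum(e.count for e in events)
    dual_total = sum(int(c.extra.get("dual_timing_patients", 0) or 0) for c in cohorts)
    grouped_total = sum(c.events for c in cohorts)
    if raw_total - dual_total != grouped_total:
        raise ValidationError(
            f"fixture inconsistent: {raw_total} raw events - {dual_total} dual-timing "
            f"patients != {grouped_total} grouped events"
        )

    by_study: dict[str, list[ToxicityEvent]] = {}
    for e in events:
        by_study.setdefault(e.study_id, []).append(e)
    patients = [
        rec for c in cohorts for rec in _expand_cohort(c, by_study.get(c.study_id, []))
    ]
    return FixtureData(cohorts=cohorts, toxicity_events=events, patients=patients)


# ---------------------------------------------------------------------------
# Median split


class MedianSplit(NamedTuple):
    median: float
    labels: list  # "le" / "gt" per input value, None where input missing
    n_missing: int


def median_split(values: Sequence[float | None]) -> MedianSplit:
    """Split values at their median into "le" (<= median) and "gt" groups.

    Missing values (None/NaN) are excluded from the median and labelled
    ``None``.  A degenerate split (all non-missing values equal) labels
    everything "le" and warns.
    """
    arr = np.array([np.nan if v is None else float(v) for v in values], dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        raise ValueError("median_split requires at least one non-missing value")
    if finite.size < 2:
        raise ValueError("median_split requires >= 2 non-missing values")
    med = float(np.median(finite))
    labels = [None if np.isnan(v) else ("le" if v <= med else "gt") for v in arr]
    if np.all(finite <= med):
        warnings.warn(
            "degenerate median split: no values above the median", stacklevel=2
        )
    return MedianSplit(median=med, labels=labels, n_missing=int(np.isnan(arr).sum()))
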