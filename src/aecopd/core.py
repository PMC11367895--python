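"""Core domain types for respiratory exacerbation quantification.

An acute exacerbation of COPD (AECOPD) is graded on a six-level ordinal
severity scale running from *very mild* (no special treatment) to *very
severe* (ICU admission / intubation).  Counts of events per severity level
over a three-year recall window are collected from two channels — a
self-report questionnaire and adjudicated electronic health records (EHR)
— and the main analyses dichotomize at *moderate*: an "m/s" event is any
event of severity moderate or worse, i.e. one that required treatment
beyond home inhaler escalation.

This module holds the severity taxonomy, per-participant count containers,
the questionnaire CSV reader/writer, and cohort-level summaries.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SeverityLevel",
    "SEVERITY_LABELS",
    "MS_LEVELS",
    "SOURCES",
    "SeverityCounts",
    "Participant",
    "ExacerbationProfile",
    "CohortSummary",
    "ms_total",
    "load_questionnaire",
    "write_counts",
    "load_counts",
    "load_participants",
    "write_participants",
    "summarize_cohort",
    "review_window",
]


class SeverityLevel(enum.IntEnum):
    """Ordinal exacerbation severity, 1 (very mild) .. 6 (very severe).

    The clinical anchors are: very mild — no special treatment; mild —
    increased home inhaler use only; moderate — additional antibiotic or
    steroid medication kept at home; moderately severe — clinician-
    prescribed antibiotics and/or steroids; severe — hospital admission;
    very severe — ICU admission and/or intubation.
    """

    VERY_MILD = 1
    MILD = 2
    MODERATE = 3
    MODERATELY_SEVERE = 4
    SEVERE = 5
    VERY_SEVERE = 6

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "SeverityLevel":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown severity label: {label!r}") from None

    @property
    def is_moderate_or_worse(self) -> bool:
        """True for the dichotomized 'm/s' upper four levels."""
        return self >= SeverityLevel.MODERATE


SEVERITY_LABELS: tuple[str, ...] = tuple(lvl.label for lvl in SeverityLevel)
MS_LEVELS: tuple[SeverityLevel, ...] = tuple(
    lvl for lvl in SeverityLevel if lvl.is_moderate_or_worse
)

#: Valid provenance channels for a count vector.
SOURCES = ("self_report", "ehr", "combined")


def _check_int_count(value, what: str) -> int:
    if isinstance(value, bool):
        raise ValidationError(f"{what}: boolean is not a count")
    if isinstance(value, float):
        if not value.is_integer():
            raise ValidationError(f"{what}: non-integer count {value!r}")
        value = int(value)
    if not isinstance(value, (int, np.integer)):
        raise ValidationError(f"{what}: non-integer count {value!r}")
    value = int(value)
    if value < 0:
        raise ValidationError(f"{what}: negative count {value}")
    return value


@dataclass(frozen=True)
class SeverityCounts:
    """Event counts per severity level for one participant and one channel.

    Parameters
    ----------
    participant_id
        Opaque participant identifier.
    source
        One of ``"self_report"``, ``"ehr"``, ``"combined"``.
    counts
        Mapping from :class:`SeverityLevel` to a non-negative integer.
        Levels omitted from the mapping are stored as zero.
    window_years
        Length of the recall / review window (default 3 years).
    """

    participant_id: str
    source: str
    counts: Mapping[SeverityLevel, int]
    window_years: float = 3.0

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(
                f"source must be one of {SOURCES}, got {self.source!r}"
            )
        if not (self.window_years > 0):
            raise ValidationError("window_years must be positive")
        full: dict[SeverityLevel, int] = {}
        for lvl in SeverityLevel:
            raw = self.counts.get(lvl, 0)
            full[lvl] = _check_int_count(
                raw, f"participant {self.participant_id}, {lvl.label}"
            )
        for key in self.counts:
            if not isinstance(key, SeverityLevel):
                raise ValidationError(f"count key is not a SeverityLevel: {key!r}")
        object.__setattr__(self, "counts", full)

    @property
    def ms_total(self) -> int:
        """Total moderate-to-very-severe events (the dichotomized count)."""
        return sum(self.counts[lvl] for lvl in MS_LEVELS)

    @property
    def total(self) -> int:
        """Total events across all six severity levels."""
        return sum(self.counts.values())

    @property
    def ms_per_year(self) -> float:
        return self.ms_total / self.window_years

    def as_row(self) -> dict:
        row: dict = {"participant_id": self.participant_id}
        row.update({lvl.label: self.counts[lvl] for lvl in SeverityLevel})
        return row


def ms_total(counts: SeverityCounts) -> int:
    """Sum of moderate + moderately severe + severe + very severe counts."""
    return counts.ms_total


@dataclass(frozen=True)
class Participant:
    """Cohort member metadata used as regression covariates.

    Inclusion criteria (age >= 40 years, >= 20 pack-years of smoking) are
    enforced as invariants; "former" smoking denotes >= 1 year abstinent
    and is carried as metadata only.
    """

    participant_id: str
    age: float
    sex: str
    height_cm: float
    weight_kg: float
    smoking_status: str
    pack_years: float
    cohort: str
    enrollment_date: _dt.date

    def __post_init__(self) -> None:
        pid = self.participant_id
        if self.sex not in ("male", "female"):
            raise ValidationError(f"participant {pid}: sex must be male/female")
        if self.smoking_status not in ("current", "former"):
            raise ValidationError(
                f"participant {pid}: smoking_status must be current/former"
            )
        if self.cohort not in ("COPD", "TEPS"):
            raise ValidationError(f"participant {pid}: cohort must be COPD/TEPS")
        if not (self.age >= 40):
            raise ValidationError(f"participant {pid}: age {self.age} below 40")
        if not (self.pack_years >= 20):
            raise ValidationError(
                f"participant {pid}: pack_years {self.pack_years} below 20"
            )
        if not isinstance(self.enrollment_date, _dt.date):
            raise ValidationError(f"participant {pid}: enrollment_date not a date")


def review_window(
    participant: Participant, window_years: float = 3.0
) -> tuple[_dt.date, _dt.date]:
    """The EHR review / questionnaire recall window for a participant.

    The window is the ``window_years`` years ending at the enrollment date
    (the date the questionnaire was completed). Only the full default
    3-year window is supported; partial windows are a configuration error
    upstream.
    """
    end = participant.enrollment_date
    start = end - _dt.timedelta(days=round(window_years * 365))
    return start, end


@dataclass(frozen=True)
class ExacerbationProfile:
    """Per-participant counts from both channels, plus the combined count.

    ``combined_counts`` is the per-severity maximum over the two channels
    (see :func:`aecopd.agreement.combine_counts`) and may be ``None`` when
    only channel-specific analyses are required.
    """

    participant_id: str
    self_counts: SeverityCounts
    ehr_counts: SeverityCounts
    combined_counts: SeverityCounts | None = None

    def __post_init__(self) -> None:
        present = [self.self_counts, self.ehr_counts]
        if self.combined_counts is not None:
            present.append(self.combined_counts)
        for sc in present:
            if sc.participant_id != self.participant_id:
                raise ValidationError(
                    f"profile {self.participant_id}: counts belong to "
                    f"{sc.participant_id}"
                )
        if self.self_counts.source != "self_report":
            raise ValidationError("self_counts must have source self_report")
        if self.ehr_counts.source != "ehr":
            raise ValidationError("ehr_counts must have source ehr")
        windows = {sc.window_years for sc in present}
        if len(windows) != 1:
            raise ValidationError(
                f"profile {self.participant_id}: mismatched window_years {windows}"
            )

    @property
    def any_ms_self(self) -> bool:
        return self.self_counts.ms_total > 0

    @property
    def any_ms_ehr(self) -> bool:
        return self.ehr_counts.ms_total > 0

    @property
    def ms_per_year_self(self) -> float:
        return self.self_counts.ms_per_year

    @property
    def ms_per_year_ehr(self) -> float:
        return self.ehr_counts.ms_per_year

    def counts_for(self, source: str) -> SeverityCounts:
        if source == "self_report":
            return self.self_counts
        if source == "ehr":
            return self.ehr_counts
        if source == "combined":
            if self.combined_counts is None:
                raise ValidationError(
                    f"profile {self.participant_id}: combined counts not populated"
                )
            return self.combined_counts
        raise ValidationError(f"unknown source {source!r}")


# ---------------------------------------------------------------------------
# CSV ingestion


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc


def load_questionnaire(path, window_years: float = 3.0) -> list[SeverityCounts]:
    """Read questionnaire severity counts (source ``self_report``) from CSV.

    The file must have exactly the columns ``participant_id`` plus the six
    severity labels. Unknown columns are rejected and empty cells are an
    error (silent zero-imputation would bias agreement downward), as is any
    negative or non-integer count.
    """
    return load_counts(path, source="self_report", window_years=window_years)


def load_counts(path, source: str, window_years: float = 3.0) -> list[SeverityCounts]:
    """Read a per-participant severity-count table for the given channel."""
    df = _read_csv(path)
    expected = {"participant_id", *SEVERITY_LABELS}
    got = set(df.columns)
    unknown = got - expected
    if unknown:
        raise ValidationError(f"{path}: unknown columns {sorted(unknown)}")
    missing = expected - got
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: list[SeverityCounts] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = row["participant_id"]
        if pd.isna(pid) or not str(pid).strip():
            raise ValidationError(f"{path} row {i + 2}: empty participant_id")
        pid = str(pid)
        if pid in seen:
            raise ValidationError(f"{path}: duplicate participant_id {pid!r}")
        seen.add(pid)
        counts: dict[SeverityLevel, int] = {}
        for lvl in SeverityLevel:
            cell = row[lvl.label]
            if pd.isna(cell):
                raise ValidationError(
                    f"{path} row {i + 2}: missing {lvl.label} count for "
                    f"participant {pid}"
                )
            try:
                value = int(str(cell).strip())
            except ValueError:
                raise ValidationError(
                    f"{path} row {i + 2}: non-integer {lvl.label} count "
                    f"{cell!r} for participant {pid}"
                ) from None
            counts[lvl] = _check_int_count(value, f"participant {pid}, {lvl.label}")
        out.append(
            SeverityCounts(
                participant_id=pid,
                source=source,
                counts=counts,
                window_years=window_years,
            )
        )
    return out


def write_counts(counts: Iterable[SeverityCounts], path) -> None:
    """Write severity counts as CSV in the canonical column order."""
    rows = [sc.as_row() for sc in counts]
    df = pd.DataFrame(rows, columns=["participant_id", *SEVERITY_LABELS])
    df.to_csv(path, index=False, lineterminator="\n")


def load_participants(path) -> list[Participant]:
    """Read the participants table (demographics, smoking, cohort label)."""
    df = _read_csv(path)
    expected = [
        "participant_id",
        "age",
        "sex",
        "height_cm",
        "weight_kg",
        "smoking_status",
        "pack_years",
        "cohort",
        "enrollment_date",
    ]
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: list[Participant] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = str(row["participant_id"])
        if pid in seen:
            raise ValidationError(f"{path}: duplicate participant_id {pid!r}")
        seen.add(pid)
        try:
            enrollment = _dt.date.fromisoformat(str(row["enrollment_date"]))
        except ValueError:
            raise ValidationError(
                f"{path} row {i + 2}: bad enrollment_date "
                f"{row['enrollment_date']!r}"
            ) from None
        try:
            out.append(
                Participant(
                    participant_id=pid,
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    height_cm=float(row["height_cm"]),
                    weight_kg=float(row["weight_kg"]),
                    smoking_status=str(row["smoking_status"]),
                    pack_years=float(row["pack_years"]),
                    cohort=str(row["cohort"]),
                    enrollment_date=enrollment,
                )
            )
        except ValueError as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
    return out


def write_participants(participants: Iterable[Participant], path) -> None:
    rows = [
        {
            "participant_id": p.participant_id,
            "age": p.age,
            "sex": p.sex,
            "height_cm": p.height_cm,
            "weight_kg": p.weight_kg,
            "smoking_status": p.smoking_status,
            "pack_years": p.pack_years,
            "cohort": p.cohort,
            "enrollment_date": p.enrollment_date.isoformat(),
        }
        for p in participants
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Cohort summaries


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level tallies for one channel (the shape of a prevalence table).

    ``mean_ms_per_year`` / ``sd_ms_per_year`` are computed among
    participants with at least one exacerbation of any severity and are
    ``None`` when that subset is empty (SD additionally requires >= 2 such
    participants).
    """

    source: str
    n: int
    n_any_exacerbation: int
    n_ms_per_year_ge_1: int
    n_frequent_exacerbator: int  # >= 2 m/s events per year on average
    mean_ms_per_year: float | None
    sd_ms_per_year: float | None
    events_by_severity: Mapping[SeverityLevel, int]
    total_events: int
    total_ms_events: int

    def as_dict(self) -> dict:
        return {
            "source": self.source,
            "n": self.n,
            "n_any_exacerbation": self.n_any_exacerbation,
            "n_ms_per_year_ge_1": self.n_ms_per_year_ge_1,
            "n_frequent_exacerbator": self.n_frequent_exacerbator,
            "mean_ms_per_year": self.mean_ms_per_year,
            "sd_ms_per_year": self.sd_ms_per_year,
            "events_by_severity": {
                lvl.label: self.events_by_severity[lvl] for lvl in SeverityLevel
            },
            "total_events": self.total_events,
            "total_ms_events": self.total_ms_events,
        }


def _summarize_one(source: str, counts: Sequence[SeverityCounts]) -> CohortSummary:
    n = len(counts)
    by_sev = {lvl: sum(sc.counts[lvl] for sc in counts) for lvl in SeverityLevel}
    any_exac = [sc for sc in counts if sc.total > 0]
    rates = np.array([sc.ms_per_year for sc in any_exac], dtype=float)
    mean = float(rates.mean()) if len(rates) else None
    sd = float(rates.std(ddof=1)) if len(rates) >= 2 else None
    return CohortSummary(
        source=source,
        n=n,
        n_any_exacerbation=len(any_exac),
        n_ms_per_year_ge_1=sum(1 for sc in counts if sc.ms_per_year >= 1),
        n_frequent_exacerbator=sum(1 for sc in counts if sc.ms_per_year >= 2),
        mean_ms_per_year=mean,
        sd_ms_per_year=sd,
        events_by_severity=by_sev,
        total_events=sum(by_sev.values()),
        total_ms_events=sum(by_sev[lvl] for lvl in MS_LEVELS),
    )


def summarize_cohort(
    profiles: Sequence[ExacerbationProfile],
) -> dict[str, CohortSummary]:
    """Cohort prevalence/burden summary per source channel.

    For each channel present in the profiles this reports: participants
    with any exacerbation, participants averaging >= 1 and >= 2 m/s events
    per year ("frequent exacerbators"), the mean +/- SD m/s rate among
    those with any exacerbation, and total events per severity level.
    """
    if not profiles:
        raise ValidationError("summarize_cohort: empty profile list")
    out: dict[str, CohortSummary] = {}
    out["self_report"] = _summarize_one(
        "self_report", [p.self_counts for p in profiles]
    )
    out["ehr"] = _summarize_one("ehr", [p.ehr_counts for p in profiles])
    combined = [p.combined_counts for p in profiles if p.combined_counts is not None]
    if len(combined) == len(profiles):
        out["combined"] = _summarize_one("combined", combined)
    return out
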