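"""Rule-based adjudication of EHR encounters into exacerbation episodes.

Each medical encounter (phone call, clinic/urgent-care/ED visit, or
hospital stay) carries documented diagnoses and prescribed medication
classes.  An encounter counts as a candidate AECOPD event only when a
COPD exacerbation is itself documented; co-diagnoses that could explain
the treatment instead (pneumonia, allergic or interstitial lung disease)
require that *both* antibiotics and systemic steroids were prescribed,
otherwise the encounter is attributed to the co-diagnosis and dropped.
Respiratory presentations of other comorbidities (MI, CHF, pulmonary
embolism) never qualify because the exacerbation diagnosis is absent.

Severity is assigned from the care setting and medications: ICU or
intubation -> very severe; hospital admission -> severe; an outpatient
encounter with clinician-prescribed antibiotics/steroids -> moderately
severe; note-documented self-treatment with home-kept antibiotic/steroid
-> moderate; inhaler escalation only -> mild; symptoms without treatment
-> very mild.  The mapping lives in a configurable :class:`RuleTable`.

Candidate events occurring less than one month (default 30 days) apart
are chained into a single episode, so that a relapse or slow-to-resolve
flare is not double counted; the episode severity is the maximum over its
member events.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .core import SeverityCounts, SeverityLevel
from .errors import ConfigError, ValidationError

__all__ = [
    "SETTINGS",
    "DIAGNOSES",
    "MEDICATIONS",
    "EncounterRecord",
    "CandidateEvent",
    "AdjudicatedEpisode",
    "RuleTable",
    "classify_encounter",
    "merge_events",
    "adjudicate",
    "adjudicate_cohort",
    "load_encounters",
    "write_encounters",
    "write_episodes",
]

SETTINGS = (
    "phone",
    "clinic",
    "urgent_care",
    "emergency_department",
    "hospital_admission",
)

DIAGNOSES = (
    "copd_exacerbation",
    "pneumonia",
    "mi",
    "chf",
    "pulmonary_embolism",
    "allergic_lung_disease",
    "interstitial_lung_disease",
    "other",
)

#: Controlled medication classes. ``home_antibiotic_steroid`` denotes
#: note-documented self-treatment with antibiotic/steroid kept at home
#: (no new prescription at the encounter).
MEDICATIONS = (
    "antibiotic",
    "systemic_steroid",
    "home_antibiotic_steroid",
    "inhaler_escalation",
    "other",
)


def _check_codes(values: Iterable[str], vocab: Sequence[str], what: str) -> frozenset:
    out = frozenset(values)
    unknown = out - set(vocab)
    if unknown:
        raise ValidationError(f"unknown {what} code(s): {sorted(unknown)}")
    return out


@dataclass(frozen=True)
class EncounterRecord:
    """A single dated healthcare contact extracted from the EHR."""

    participant_id: str
    date: _dt.date
    setting: str
    icu_or_intubation: bool
    diagnoses: frozenset[str]
    medications: frozenset[str]
    discharge_diagnoses: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValidationError(
                f"participant {self.participant_id}: unknown setting "
                f"{self.setting!r}"
            )
        if self.icu_or_intubation and self.setting != "hospital_admission":
            raise ValidationError(
                f"participant {self.participant_id}: ICU/intubation flag "
                f"requires hospital_admission setting"
            )
        if self.discharge_diagnoses and self.setting != "hospital_admission":
            raise ValidationError(
                f"participant {self.participant_id}: discharge diagnoses only "
                f"apply to hospital admissions"
            )
        object.__setattr__(
            self, "diagnoses", _check_codes(self.diagnoses, DIAGNOSES, "diagnosis")
        )
        object.__setattr__(
            self,
            "medications",
            _check_codes(self.medications, MEDICATIONS, "medication"),
        )
        object.__setattr__(
            self,
            "discharge_diagnoses",
            _check_codes(self.discharge_diagnoses, DIAGNOSES, "discharge diagnosis"),
        )
        if not isinstance(self.date, _dt.date):
            raise ValidationError("encounter date must be a datetime.date")

    @property
    def all_diagnoses(self) -> frozenset[str]:
        """Admission and discharge diagnoses considered jointly."""
        return self.diagnoses | self.discharge_diagnoses


@dataclass(frozen=True)
class CandidateEvent:
    """An encounter accepted by the rule engine as an AECOPD event."""

    participant_id: str
    date: _dt.date
    severity: SeverityLevel
    encounter: EncounterRecord


@dataclass(frozen=True)
class AdjudicatedEpisode:
    """A merged run of candidate events counted as one clinical episode."""

    participant_id: str
    start_date: _dt.date
    end_date: _dt.date
    severity: SeverityLevel
    events: tuple[CandidateEvent, ...]

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValidationError("episode start_date after end_date")
        if not self.events:
            raise ValidationError("episode with no constituent events")


@dataclass(frozen=True)
class RuleTable:
    """Configurable adjudication rules.

    ``outpatient_severity`` is an ordered (medication class -> severity)
    priority list scanned first-match for non-admission encounters; the
    fallback for encounters with none of the listed classes is
    ``outpatient_fallback`` (documented symptoms without treatment).
    """

    excluded_diagnoses: frozenset[str] = frozenset(
        {"mi", "chf", "pulmonary_embolism"}
    )
    pneumonia_required_meds: frozenset[str] = frozenset(
        {"antibiotic", "systemic_steroid"}
    )
    steroid_codiagnoses: frozenset[str] = frozenset(
        {"allergic_lung_disease", "interstitial_lung_disease"}
    )
    steroid_codiagnosis_required_meds: frozenset[str] = frozenset(
        {"antibiotic", "systemic_steroid"}
    )
    outpatient_severity: tuple[tuple[str, SeverityLevel], ...] = (
        ("antibiotic", SeverityLevel.MODERATELY_SEVERE),
        ("systemic_steroid", SeverityLevel.MODERATELY_SEVERE),
        ("home_antibiotic_steroid", SeverityLevel.MODERATE),
        ("inhaler_escalation", SeverityLevel.MILD),
    )
    outpatient_fallback: SeverityLevel = SeverityLevel.VERY_MILD
    merge_window_days: int = 30

    def __post_init__(self) -> None:
        if self.merge_window_days <= 0:
            raise ConfigError("merge_window_days must be a positive integer")
        for med, _ in self.outpatient_severity:
            if med not in MEDICATIONS:
                raise ConfigError(f"rule table: unknown medication class {med!r}")

    def severity_for(self, rec: EncounterRecord) -> SeverityLevel:
        """Severity from (setting, ICU flag, medications); total mapping."""
        if rec.icu_or_intubation:
            return SeverityLevel.VERY_SEVERE
        if rec.setting == "hospital_admission":
            return SeverityLevel.SEVERE
        for med, severity in self.outpatient_severity:
            if med in rec.medications:
                return severity
        return self.outpatient_fallback

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "excluded_diagnoses": sorted(self.excluded_diagnoses),
            "pneumonia_required_meds": sorted(self.pneumonia_required_meds),
            "steroid_codiagnoses": sorted(self.steroid_codiagnoses),
            "steroid_codiagnosis_required_meds": sorted(
                self.steroid_codiagnosis_required_meds
            ),
            "outpatient_severity": [
                [med, sev.label] for med, sev in self.outpatient_severity
            ],
            "outpatient_fallback": self.outpatient_fallback.label,
            "merge_window_days": self.merge_window_days,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RuleTable":
        try:
            return cls(
                excluded_diagnoses=frozenset(data["excluded_diagnoses"]),
                pneumonia_required_meds=frozenset(data["pneumonia_required_meds"]),
                steroid_codiagnoses=frozenset(data["steroid_codiagnoses"]),
                steroid_codiagnosis_required_meds=frozenset(
                    data["steroid_codiagnosis_required_meds"]
                ),
                outpatient_severity=tuple(
                    (med, SeverityLevel.from_label(sev))
                    for med, sev in data["outpatient_severity"]
                ),
                outpatient_fallback=SeverityLevel.from_label(
                    data["outpatient_fallback"]
                ),
                merge_window_days=int(data["merge_window_days"]),
            )
        except KeyError as exc:
            raise ConfigError(f"rule table missing field {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RuleTable":
        try:
            with open(path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        except FileNotFoundError:
            raise ConfigError(f"rule table not found: {path}") from None
        except yaml.YAMLError as exc:
            raise ConfigError(f"rule table {path} is not valid YAML: {exc}") from exc
        if not isinstance(data, Mapping):
            raise ConfigError(f"rule table {path}: expected a mapping")
        return cls.from_dict(data)


def classify_encounter(
    rec: EncounterRecord, rules: RuleTable | None = None
) -> CandidateEvent | None:
    """Apply the adjudication rules to one encounter.

    Returns ``None`` when the encounter does not qualify as an AECOPD
    event: the exacerbation diagnosis is absent (covering pure pneumonia
    and the cardiovascular/embolic mimics), or a pneumonia co-diagnosis
    lacks the required antibiotic-plus-steroid prescription, or a
    steroid-requiring co-diagnosis (allergic/interstitial lung disease)
    lacks the same.
    """
    if rules is None:
        rules = RuleTable()
    dx = rec.all_diagnoses
    if "copd_exacerbation" not in dx:
        return None
    if "pneumonia" in dx and not rules.pneumonia_required_meds <= rec.medications:
        return None
    if dx & rules.steroid_codiagnoses and not (
        rules.steroid_codiagnosis_required_meds <= rec.medications
    ):
        return None
    return CandidateEvent(
        participant_id=rec.participant_id,
        date=rec.date,
        severity=rules.severity_for(rec),
        encounter=rec,
    )


def merge_events(
    events: Sequence[CandidateEvent], merge_window_days: int = 30
) -> list[AdjudicatedEpisode]:
    """Chain candidate events < ``merge_window_days`` apart into episodes.

    Single-linkage over dates: after sorting, consecutive events whose gap
    is strictly less than the window join the same episode (so a long
    relapse chain collapses into one episode even if its extremes are far
    apart).  Episode severity is the maximum member severity; start/end
    are the min/max member dates.  The result is independent of input
    order and idempotent.
    """
    if merge_window_days <= 0:
        raise ConfigError("merge_window_days must be a positive integer")
    if not events:
        return []
    pids = {ev.participant_id for ev in events}
    if len(pids) > 1:
        raise ValidationError(
            f"merge_events: events from multiple participants {sorted(pids)}"
        )
    ordered = sorted(events, key=lambda ev: (ev.date, -int(ev.severity)))
    episodes: list[list[CandidateEvent]] = [[ordered[0]]]
    for ev in ordered[1:]:
        gap = (ev.date - episodes[-1][-1].date).days
        if gap < merge_window_days:
            episodes[-1].append(ev)
        else:
            episodes.append([ev])
    out = [
        AdjudicatedEpisode(
            participant_id=chunk[0].participant_id,
            start_date=min(ev.date for ev in chunk),
            end_date=max(ev.date for ev in chunk),
            severity=max(ev.severity for ev in chunk),
            events=tuple(chunk),
        )
        for chunk in episodes
    ]
    return sorted(out, key=lambda ep: ep.start_date)


def adjudicate(
    records: Sequence[EncounterRecord],
    rules: RuleTable | None = None,
    window: tuple[_dt.date, _dt.date] | None = None,
    window_years: float = 3.0,
    participant_id: str | None = None,
) -> tuple[SeverityCounts, list[AdjudicatedEpisode]]:
    """Classify, merge, and count one participant's encounters.

    Episodes are assigned to the review window by their start date; an
    episode starting before ``window[0]`` or after ``window[1]`` is
    excluded.  ``participant_id`` must be given when ``records`` may be
    empty (so the zero-count result can still be attributed).
    """
    if rules is None:
        rules = RuleTable()
    pids = {rec.participant_id for rec in records}
    if len(pids) > 1:
        raise ValidationError(
            f"adjudicate: records from multiple participants {sorted(pids)}"
        )
    if pids:
        pid = pids.pop()
        if participant_id is not None and participant_id != pid:
            raise ValidationError(
                f"adjudicate: records belong to {pid!r}, not {participant_id!r}"
            )
    elif participant_id is not None:
        pid = participant_id
    else:
        raise ValidationError("adjudicate: no records and no participant_id")

    events = [ev for ev in (classify_encounter(r, rules) for r in records) if ev]
    episodes = merge_events(events, rules.merge_window_days)
    if window is not None:
        start, end = window
        episodes = [ep for ep in episodes if start <= ep.start_date <= end]
    tally = Counter(ep.severity for ep in episodes)
    counts = SeverityCounts(
        participant_id=pid,
        source="ehr",
        counts={lvl: tally.get(lvl, 0) for lvl in SeverityLevel},
        window_years=window_years,
    )
    return counts, episodes


def adjudicate_cohort(
    records: Sequence[EncounterRecord],
    rules: RuleTable | None = None,
    windows: Mapping[str, tuple[_dt.date, _dt.date]] | None = None,
    window_years: float = 3.0,
) -> tuple[dict[str, SeverityCounts], list[AdjudicatedEpisode]]:
    """Adjudicate a multi-participant record set.

    ``windows`` maps participant_id to its review window and also defines
    the cohort: participants present in ``windows`` but without any
    encounter receive all-zero counts.  When ``windows`` is ``None`` the
    cohort is the set of participants appearing in ``records`` and no
    window filtering is applied.
    """
    by_pid: dict[str, list[EncounterRecord]] = {}
    for rec in records:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    cohort = sorted(windows) if windows is not None else sorted(by_pid)
    counts: dict[str, SeverityCounts] = {}
    episodes: list[AdjudicatedEpisode] = []
    for pid in cohort:
        window = windows.get(pid) if windows is not None else None
        sc, eps = adjudicate(
            by_pid.get(pid, []),
            rules=rules,
            window=window,
            window_years=window_years,
            participant_id=pid,
        )
        counts[pid] = sc
        episodes.extend(eps)
    return counts, episodes


# ---------------------------------------------------------------------------
# CSV I/O


def _split_codes(cell: str) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(part.strip() for part in text.split(";") if part.strip())


def load_encounters(path) -> list[EncounterRecord]:
    """Read the encounters CSV (semicolon-joined code sets, 0/1 ICU flag)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    expected = {
        "participant_id",
        "date",
        "setting",
        "icu_or_intubation",
        "diagnoses",
        "medications",
        "discharge_diagnoses",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: list[EncounterRecord] = []
    for i, row in df.iterrows():
        try:
            date = _dt.date.fromisoformat(str(row["date"]))
        except ValueError:
            raise ValidationError(
                f"{path} row {i + 2}: bad date {row['date']!r}"
            ) from None
        icu_raw = str(row["icu_or_intubation"]).strip()
        if icu_raw not in ("0", "1"):
            raise ValidationError(
                f"{path} row {i + 2}: icu_or_intubation must be 0/1, "
                f"got {icu_raw!r}"
            )
        try:
            out.append(
                EncounterRecord(
                    participant_id=str(row["participant_id"]),
                    date=date,
                    setting=str(row["setting"]),
                    icu_or_intubation=icu_raw == "1",
                    diagnoses=_split_codes(row["diagnoses"]),
                    medications=_split_codes(row["medications"]),
                    discharge_diagnoses=_split_codes(row["discharge_diagnoses"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
    return out


def write_encounters(records: Iterable[EncounterRecord], path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "date": r.date.isoformat(),
            "setting": r.setting,
            "icu_or_intubation": int(r.icu_or_intubation),
            "diagnoses": ";".join(sorted(r.diagnoses)),
            "medications": ";".join(sorted(r.medications)),
            "discharge_diagnoses": ";".join(sorted(r.discharge_diagnoses)),
        }
        for r in records
    ]
    columns = [
        "participant_id",
        "date",
        "setting",
        "icu_or_intubation",
        "diagnoses",
        "medications",
        "discharge_diagnoses",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, lineterminator="\n"
    )


def write_episodes(episodes: Iterable[AdjudicatedEpisode], path) -> None:
    rows = [
        {
            "participant_id": ep.participant_id,
            "start_date": ep.start_date.isoformat(),
            "end_date": ep.end_date.isoformat(),
            "severity": ep.severity.label,
        }
        for ep in episodes
    ]
    columns = ["participant_id", "start_date", "end_date", "severity"]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, lineterminator="\n"
    )
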