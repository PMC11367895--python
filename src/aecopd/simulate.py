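"""Synthetic cohort generator and closed-form agreement oracles.

The generative model emulates the latent process behind the two observed
channels.  Each participant experiences a latent number of exacerbation
events over the 3-year window (negative binomial with mean ``mean_events``
and dispersion ``dispersion``; ``inf`` gives Poisson), with iid severities
drawn from a six-level simplex and event dates uniform over the window.
Each event is independently *reported* (enters the questionnaire counts)
with a per-severity probability ``p_report`` and independently
*documented* (emits one EHR encounter) with probability ``p_document`` —
the two mechanisms behind self-report recall loss and care sought outside
the reviewed record system.  Documented events are emitted as encounters
whose setting/diagnoses/medications adjudicate back to exactly the latent
severity, spaced at least one merge window apart so that distinct true
events stay distinct episodes (a relapse mode adds satellite encounters
inside the merge window to exercise episode chaining).

BAL composition is linked to the true m/s burden K through a squashed
linear model: the neutrophil fraction is expit(b0 + b1*K + covariate
terms + Gaussian noise), and the remaining cell types fill the residual mass in
fixed background proportions.

Under a Poisson event model with severity-constant reporting and
documentation probabilities, the population 2x2 cell probabilities have
the closed form used by :func:`analytic_expected_table`:

    P(self=0)      = exp(-lam * p_rep)
    P(ehr=0)       = exp(-lam * p_doc)
    P(self=0,ehr=0)= exp(-lam * (1 - (1-p_rep)(1-p_doc)))

from which the remaining cells follow by inclusion-exclusion and the
population kappa by the usual formula.  :func:`calibrate_to_table` inverts
this map from an observed 2x2 table back to (lam, p_rep, p_doc).
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.special import expit

from .agreement import ContingencyTable2x2
from .association import CELL_TYPES, BALSample, write_bal
from .core import (
    Participant,
    SeverityCounts,
    SeverityLevel,
    write_counts,
    write_participants,
)
from .ehr import EncounterRecord, write_encounters
from .errors import ConfigError, DegenerateTableError

__all__ = [
    "SyntheticCohortConfig",
    "LatentHistory",
    "SyntheticCohort",
    "generate_cohort",
    "ExpectedAgreement",
    "analytic_expected_table",
    "CalibrationResult",
    "calibrate_to_table",
    "generate_association_benchmark",
]

_WINDOW_DAYS = 1095  # 3 x 365

#: Encounter template per severity: (setting, icu flag, medication classes).
_ENCOUNTER_TEMPLATES: dict[SeverityLevel, tuple[str, bool, frozenset[str]]] = {
    SeverityLevel.VERY_MILD: ("phone", False, frozenset()),
    SeverityLevel.MILD: ("phone", False, frozenset({"inhaler_escalation"})),
    SeverityLevel.MODERATE: (
        "clinic",
        False,
        frozenset({"home_antibiotic_steroid"}),
    ),
    SeverityLevel.MODERATELY_SEVERE: (
        "clinic",
        False,
        frozenset({"antibiotic", "systemic_steroid"}),
    ),
    SeverityLevel.SEVERE: (
        "hospital_admission",
        False,
        frozenset({"antibiotic", "systemic_steroid"}),
    ),
    SeverityLevel.VERY_SEVERE: (
        "hospital_admission",
        True,
        frozenset({"antibiotic", "systemic_steroid"}),
    ),
}


def _check_prob_vector(values, name: str, length: int | None = None) -> tuple:
    vec = tuple(float(v) for v in values)
    if length is not None and len(vec) != length:
        raise ConfigError(f"{name} must have {length} entries, got {len(vec)}")
    for v in vec:
        if not (0.0 <= v <= 1.0):
            raise ConfigError(f"{name} entries must be in [0, 1], got {v}")
    return vec


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters of the generative model.

    Event model: ``mean_events`` is the mean total number of exacerbation
    events (all severities) over the window; ``dispersion`` is the
    negative-binomial shape (``math.inf`` for Poisson).  ``severity_probs``
    is the six-level severity simplex; ``p_report`` / ``p_document`` give
    the per-severity Bernoulli probabilities that an event reaches the
    questionnaire / the EHR.  BAL link: neutrophil fraction =
    expit(bal_intercept + bal_slope * K + covariate effects + N(0,
    bal_noise_sd)) with K the true m/s count.  Covariate distributions
    mirror a typical elderly, mostly male, heavy-smoking COPD cohort.
    """

    n_participants: int = 222
    seed: int = 0
    window_years: float = 3.0
    mean_events: float = 1.2
    dispersion: float = 1.0
    severity_probs: tuple = (0.19, 0.17, 0.19, 0.26, 0.15, 0.04)
    p_report: tuple = (0.55, 0.55, 0.47, 0.47, 0.47, 0.47)
    p_document: tuple = (0.05, 0.05, 0.56, 0.56, 0.56, 0.56)
    bal_intercept: float = -2.5
    bal_slope: float = 0.15
    bal_noise_sd: float = 0.5
    bal_covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"current_smoker": 0.25}
    )
    background_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "macrophage": 0.84,
            "lymphocyte": 0.11,
            "eosinophil": 0.01,
            "other": 0.04,
        }
    )
    total_cells_log_mu: float = math.log(1.5e5)
    total_cells_log_sigma: float = 0.5
    age_mean: float = 70.0
    age_sd: float = 7.0
    male_fraction: float = 0.96
    height_mean: float = 176.0
    height_sd: float = 10.0
    weight_mean: float = 86.0
    weight_sd: float = 22.0
    current_smoker_fraction: float = 0.42
    pack_years_log_mu: float = math.log(57.0)
    pack_years_log_sigma: float = 0.55
    enrollment_date: _dt.date = _dt.date(2022, 1, 1)
    cohort_label: str = "COPD"
    merge_window_days: int = 30
    relapse_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        if self.mean_events < 0:
            raise ConfigError("mean_events must be non-negative")
        if not (self.dispersion > 0):
            raise ConfigError("dispersion must be positive (inf for Poisson)")
        if self.bal_noise_sd < 0:
            raise ConfigError("bal_noise_sd must be non-negative")
        if self.window_years != 3.0:
            raise ConfigError("only the 3-year window is supported")
        sev = _check_prob_vector(self.severity_probs, "severity_probs", 6)
        if abs(sum(sev) - 1.0) > 1e-6:
            raise ConfigError(f"severity_probs must sum to 1, got {sum(sev)}")
        object.__setattr__(self, "severity_probs", sev)
        object.__setattr__(
            self, "p_report", _check_prob_vector(self.p_report, "p_report", 6)
        )
        object.__setattr__(
            self,
            "p_document",
            _check_prob_vector(self.p_document, "p_document", 6),
        )
        bg = {k: float(v) for k, v in self.background_fractions.items()}
        unknown = set(bg) - (set(CELL_TYPES) - {"neutrophil"})
        if unknown:
            raise ConfigError(f"background_fractions: unknown cells {unknown}")
        if any(v < 0 for v in bg.values()) or sum(bg.values()) <= 0:
            raise ConfigError("background_fractions must be a positive measure")
        object.__setattr__(self, "background_fractions", bg)
        if not (0 <= self.male_fraction <= 1):
            raise ConfigError("male_fraction must be in [0, 1]")
        if not (0 <= self.current_smoker_fraction <= 1):
            raise ConfigError("current_smoker_fraction must be in [0, 1]")
        if self.merge_window_days <= 0:
            raise ConfigError("merge_window_days must be positive")

    @property
    def ms_mass(self) -> float:
        """Probability that an event is moderate or worse."""
        return sum(self.severity_probs[2:])

    @property
    def lambda_ms(self) -> float:
        """Mean true m/s events per participant over the window."""
        return self.mean_events * self.ms_mass

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "seed": self.seed,
            "window_years": self.window_years,
            "mean_events": self.mean_events,
            "dispersion": "inf" if math.isinf(self.dispersion) else self.dispersion,
            "severity_probs": list(self.severity_probs),
            "p_report": list(self.p_report),
            "p_document": list(self.p_document),
            "bal_intercept": self.bal_intercept,
            "bal_slope": self.bal_slope,
            "bal_noise_sd": self.bal_noise_sd,
            "bal_covariate_effects": dict(self.bal_covariate_effects),
            "background_fractions": dict(self.background_fractions),
            "total_cells_log_mu": self.total_cells_log_mu,
            "total_cells_log_sigma": self.total_cells_log_sigma,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "male_fraction": self.male_fraction,
            "height_mean": self.height_mean,
            "height_sd": self.height_sd,
            "weight_mean": self.weight_mean,
            "weight_sd": self.weight_sd,
            "current_smoker_fraction": self.current_smoker_fraction,
            "pack_years_log_mu": self.pack_years_log_mu,
            "pack_years_log_sigma": self.pack_years_log_sigma,
            "enrollment_date": self.enrollment_date.isoformat(),
            "cohort_label": self.cohort_label,
            "merge_window_days": self.merge_window_days,
            "relapse_mode": self.relapse_mode,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticCohortConfig":
        kwargs = dict(data)
        if "dispersion" in kwargs and kwargs["dispersion"] in ("inf", "Infinity"):
            kwargs["dispersion"] = math.inf
        if "enrollment_date" in kwargs and isinstance(
            kwargs["enrollment_date"], str
        ):
            kwargs["enrollment_date"] = _dt.date.fromisoformat(
                kwargs["enrollment_date"]
            )
        for key in ("severity_probs", "p_report", "p_document"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"bad simulator config: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        except FileNotFoundError:
            raise ConfigError(f"simulator config not found: {path}") from None
        except yaml.YAMLError as exc:
            raise ConfigError(f"config {path} is not valid YAML: {exc}") from exc
        if not isinstance(data, Mapping):
            raise ConfigError(f"config {path}: expected a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class LatentEvent:
    day: int  # offset from window start
    severity: SeverityLevel
    reported: bool
    documented: bool


@dataclass(frozen=True)
class LatentHistory:
    """Ground-truth event history for one synthetic participant."""

    participant_id: str
    events: tuple[LatentEvent, ...]

    @property
    def K(self) -> int:
        """True number of m/s events."""
        return sum(1 for ev in self.events if ev.severity.is_moderate_or_worse)

    @property
    def reported_ms(self) -> int:
        return sum(
            1
            for ev in self.events
            if ev.reported and ev.severity.is_moderate_or_worse
        )

    @property
    def documented_ms(self) -> int:
        return sum(
            1
            for ev in self.events
            if ev.documented and ev.severity.is_moderate_or_worse
        )


@dataclass
class SyntheticCohort:
    """All generated data streams plus the latent truth table."""

    config: SyntheticCohortConfig
    participants: list[Participant]
    questionnaire: list[SeverityCounts]
    encounters: list[EncounterRecord]
    bal: list[BALSample]
    histories: list[LatentHistory]

    @property
    def latent_truth(self) -> pd.DataFrame:
        rows = []
        window_days = _WINDOW_DAYS
        for h in self.histories:
            ms_days = [
                ev.day for ev in h.events if ev.severity.is_moderate_or_worse
            ]
            rows.append(
                {
                    "participant_id": h.participant_id,
                    "K": h.K,
                    "n_events_total": len(h.events),
                    "reported_ms": h.reported_ms,
                    "documented_ms": h.documented_ms,
                    "days_since_last_ms": (
                        float(window_days - max(ms_days)) if ms_days else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "participants": outdir / "participants.csv",
            "questionnaire": outdir / "questionnaire.csv",
            "encounters": outdir / "encounters.csv",
            "bal": outdir / "bal.csv",
            "latent_truth": outdir / "latent_truth.csv",
            "config": outdir / "config.yaml",
        }
        write_participants(self.participants, paths["participants"])
        write_counts(self.questionnaire, paths["questionnaire"])
        write_encounters(self.encounters, paths["encounters"])
        write_bal(self.bal, paths["bal"])
        self.latent_truth.to_csv(
            paths["latent_truth"], index=False, lineterminator="\n"
        )
        self.config.to_yaml(paths["config"])
        return paths


def _draw_event_count(rng: np.random.Generator, mean: float, theta: float) -> int:
    if mean == 0:
        return 0
    if math.isinf(theta):
        return int(rng.poisson(mean))
    return int(rng.negative_binomial(theta, theta / (theta + mean)))


def _spaced_days(
    rng: np.random.Generator, k: int, min_gap: int, window_days: int
) -> np.ndarray:
    """k event-day offsets, pairwise >= min_gap apart, uniform-ish in window."""
    if k == 0:
        return np.array([], dtype=int)
    if k == 1:
        return np.array([int(rng.integers(0, window_days))])
    for _ in range(200):
        days = np.sort(rng.integers(0, window_days, size=k))
        if np.diff(days).min() >= min_gap:
            return days
    # too many events to reject-sample: fall back to even spacing
    spacing = max(1, window_days // k)
    return (np.arange(k) * spacing).astype(int)


def generate_cohort(
    cfg: SyntheticCohortConfig, seed: int | None = None
) -> SyntheticCohort:
    """Draw a full synthetic cohort, reproducible from the seed.

    Reported events produce the questionnaire counts; documented events
    each emit one encounter record built from the severity's template so
    that adjudication recovers exactly the latent severity.  Documented
    event dates are spaced at least one merge window apart (plus the
    relapse offset in relapse mode), so that episode merging does not
    conflate distinct true events.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_participants
    window_days = _WINDOW_DAYS
    window_start = cfg.enrollment_date - _dt.timedelta(days=window_days)
    levels = list(SeverityLevel)
    sev_probs = np.asarray(cfg.severity_probs)
    relapse_offset = 7
    doc_gap = cfg.merge_window_days + (relapse_offset if cfg.relapse_mode else 0)

    # vectorized covariate draws; binary covariates are assigned by exact
    # composition (round(n * fraction), then shuffled) so the realized mix
    # matches the target and small subsets keep both levels represented
    def _exact_binary(frac: float) -> np.ndarray:
        flags = np.zeros(n, dtype=bool)
        flags[: round(n * frac)] = True
        return rng.permutation(flags)

    ages = np.maximum(41.0, rng.normal(cfg.age_mean, cfg.age_sd, size=n)).round(1)
    male = _exact_binary(cfg.male_fraction)
    heights = np.clip(
        rng.normal(cfg.height_mean, cfg.height_sd, size=n), 150, 205
    ).round(1)
    weights = np.clip(
        rng.normal(cfg.weight_mean, cfg.weight_sd, size=n), 45, 180
    ).round(1)
    current = _exact_binary(cfg.current_smoker_fraction)
    pack_years = np.maximum(
        20.0,
        rng.lognormal(cfg.pack_years_log_mu, cfg.pack_years_log_sigma, size=n),
    ).round(1)

    participants: list[Participant] = []
    questionnaire: list[SeverityCounts] = []
    encounters: list[EncounterRecord] = []
    bal_samples: list[BALSample] = []
    histories: list[LatentHistory] = []
    bg_cells = sorted(cfg.background_fractions)
    bg_weights = np.array([cfg.background_fractions[c] for c in bg_cells])
    bg_weights = bg_weights / bg_weights.sum()

    for i in range(n):
        pid = f"S{i + 1:05d}"
        participants.append(
            Participant(
                participant_id=pid,
                age=float(ages[i]),
                sex="male" if male[i] else "female",
                height_cm=float(heights[i]),
                weight_kg=float(weights[i]),
                smoking_status="current" if current[i] else "former",
                pack_years=float(pack_years[i]),
                cohort=cfg.cohort_label,
                enrollment_date=cfg.enrollment_date,
            )
        )

        k_total = _draw_event_count(rng, cfg.mean_events, cfg.dispersion)
        severities = [
            levels[j] for j in rng.choice(6, size=k_total, p=sev_probs)
        ]
        reported = rng.random(k_total) < np.array(
            [cfg.p_report[s - 1] for s in severities]
        )
        documented = rng.random(k_total) < np.array(
            [cfg.p_document[s - 1] for s in severities]
        )
        n_doc = int(documented.sum())
        doc_days = _spaced_days(rng, n_doc, doc_gap, window_days)
        free_days = rng.integers(0, window_days, size=k_total - n_doc)

        events: list[LatentEvent] = []
        di = fi = 0
        for j in range(k_total):
            if documented[j]:
                day = int(doc_days[di])
                di += 1
            else:
                day = int(free_days[fi])
                fi += 1
            events.append(
                LatentEvent(
                    day=day,
                    severity=severities[j],
                    reported=bool(reported[j]),
                    documented=bool(documented[j]),
                )
            )
        histories.append(LatentHistory(participant_id=pid, events=tuple(events)))

        tally = {lvl: 0 for lvl in SeverityLevel}
        for ev in events:
            if ev.reported:
                tally[ev.severity] += 1
        questionnaire.append(
            SeverityCounts(
                participant_id=pid,
                source="self_report",
                counts=tally,
                window_years=cfg.window_years,
            )
        )

        for ev in events:
            if not ev.documented:
                continue
            setting, icu, meds = _ENCOUNTER_TEMPLATES[ev.severity]
            date = window_start + _dt.timedelta(days=ev.day)
            encounters.append(
                EncounterRecord(
                    participant_id=pid,
                    date=date,
                    setting=setting,
                    icu_or_intubation=icu,
                    diagnoses=frozenset({"copd_exacerbation"}),
                    medications=meds,
                )
            )
            if cfg.relapse_mode and ev.severity >= SeverityLevel.MODERATE:
                # satellite encounter inside the merge window: same episode,
                # severity no higher than the index event
                sat_sev = min(ev.severity, SeverityLevel.MODERATELY_SEVERE)
                s_setting, s_icu, s_meds = _ENCOUNTER_TEMPLATES[sat_sev]
                encounters.append(
                    EncounterRecord(
                        participant_id=pid,
                        date=date + _dt.timedelta(days=relapse_offset),
                        setting=s_setting,
                        icu_or_intubation=s_icu,
                        diagnoses=frozenset({"copd_exacerbation"}),
                        medications=s_meds,
                    )
                )

        # BAL composition linked to true m/s burden
        K = histories[-1].K
        eta = cfg.bal_intercept + cfg.bal_slope * K
        for cov, coef in cfg.bal_covariate_effects.items():
            value = {
                "age": ages[i] - cfg.age_mean,
                "sex_male": float(male[i]),
                "height_cm": heights[i] - cfg.height_mean,
                "weight_kg": weights[i] - cfg.weight_mean,
                "current_smoker": float(current[i]),
                "pack_years": pack_years[i] - math.exp(cfg.pack_years_log_mu),
            }.get(cov)
            if value is None:
                raise ConfigError(f"bal_covariate_effects: unknown covariate {cov}")
            eta += coef * value
        neut = float(expit(eta + rng.normal(0.0, cfg.bal_noise_sd)))
        rest = (1.0 - neut) * bg_weights
        fractions = {"neutrophil": neut}
        fractions.update({c: float(v) for c, v in zip(bg_cells, rest)})
        total_cells = float(
            rng.lognormal(cfg.total_cells_log_mu, cfg.total_cells_log_sigma)
        )
        bal_samples.append(
            BALSample(
                participant_id=pid,
                total_cells_per_ml=round(total_cells, 1),
                fractions=fractions,
            )
        )

    return SyntheticCohort(
        config=cfg,
        participants=participants,
        questionnaire=questionnaire,
        encounters=encounters,
        bal=bal_samples,
        histories=histories,
    )


# ---------------------------------------------------------------------------
# Closed-form oracle and calibration


def _cell_probs(lam, p_rep, p_doc):
    """Vectorized Poisson-model cell probabilities (a, b, c, d)."""
    lam = np.asarray(lam, dtype=float)
    p_rep = np.asarray(p_rep, dtype=float)
    p_doc = np.asarray(p_doc, dtype=float)
    p_self0 = np.exp(-lam * p_rep)
    p_ehr0 = np.exp(-lam * p_doc)
    p_both0 = np.exp(-lam * (p_rep + p_doc - p_rep * p_doc))
    a = p_both0
    b = p_ehr0 - p_both0
    c = p_self0 - p_both0
    d = 1.0 - a - b - c
    return a, b, c, d


@dataclass(frozen=True)
class ExpectedAgreement:
    """Population 2x2 cell probabilities and the implied kappa."""

    p_a: float
    p_b: float
    p_c: float
    p_d: float
    kappa: float
    percent_agreement: float
    expected_agreement: float

    @property
    def cells(self) -> dict[str, float]:
        return {"a": self.p_a, "b": self.p_b, "c": self.p_c, "d": self.p_d}


def analytic_expected_table(
    lam: float, p_rep: float, p_doc: float
) -> ExpectedAgreement:
    """Expected 2x2 cell probabilities and population kappa.

    Assumes a Poisson m/s event count with rate ``lam`` over the window
    and independent per-event Bernoulli reporting/documentation channels
    with severity-constant probabilities ``p_rep`` and ``p_doc``.
    """
    if lam < 0:
        raise ConfigError("lam must be non-negative")
    for name, p in (("p_rep", p_rep), ("p_doc", p_doc)):
        if not (0.0 <= p <= 1.0):
            raise ConfigError(f"{name} must be in [0, 1], got {p}")
    a, b, c, d = (float(x) for x in _cell_probs(lam, p_rep, p_doc))
    p_o = a + d
    p_e = (a + b) * (a + c) + (c + d) * (b + d)
    if p_e >= 1.0 - 1e-12:
        raise DegenerateTableError(
            "population kappa undefined: a marginal is degenerate"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return ExpectedAgreement(
        p_a=a,
        p_b=b,
        p_c=c,
        p_d=d,
        kappa=float(kappa),
        percent_agreement=float(p_o),
        expected_agreement=float(p_e),
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted (lam, p_rep, p_doc) plus its implied agreement surface."""

    lam: float
    p_rep: float
    p_doc: float
    expected: ExpectedAgreement
    sse: float
    on_boundary: bool

    def to_config(
        self, base: SyntheticCohortConfig | None = None
    ) -> SyntheticCohortConfig:
        """Simulator config whose m/s channel matches the fitted parameters.

        The fitted ``lam`` is the m/s event rate; it is mapped back to a
        total event rate through the severity simplex.  The Poisson model
        is forced (``dispersion = inf``) because the closed form assumes
        it, and the m/s entries of the channel probability vectors are set
        to the fitted values.
        """
        base = base if base is not None else SyntheticCohortConfig()
        p_report = tuple(base.p_report[:2]) + (self.p_rep,) * 4
        p_document = tuple(base.p_document[:2]) + (self.p_doc,) * 4
        return replace(
            base,
            mean_events=self.lam / base.ms_mass,
            dispersion=math.inf,
            p_report=p_report,
            p_document=p_document,
        )


def calibrate_to_table(
    target: ContingencyTable2x2,
    lam_grid: np.ndarray | None = None,
    p_grid: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit (lam, p_rep, p_doc) to an observed 2x2 table.

    Grid search minimizing the squared distance between the analytic cell
    probabilities and the table's empirical proportions, refined with
    Nelder-Mead.  With three free parameters and three degrees of freedom
    in the table the interior optimum is typically exact; a solution on
    the parameter boundary triggers a warning.
    """
    if min(target.self_yes, target.self_no, target.ehr_yes, target.ehr_no) == 0:
        raise DegenerateTableError("calibration target has a zero marginal")
    n = target.n
    obs = np.array([target.a, target.b, target.c, target.d], dtype=float) / n
    if lam_grid is None:
        lam_grid = np.linspace(0.05, 4.0, 80)
    if p_grid is None:
        p_grid = np.linspace(0.05, 1.0, 40)

    L, R, D = np.meshgrid(lam_grid, p_grid, p_grid, indexing="ij")
    a, b, c, d = _cell_probs(L, R, D)
    sse = (
        (a - obs[0]) ** 2
        + (b - obs[1]) ** 2
        + (c - obs[2]) ** 2
        + (d - obs[3]) ** 2
    )
    best = np.unravel_index(np.argmin(sse), sse.shape)
    x0 = np.array([L[best], R[best], D[best]])

    lo = np.array([1e-6, 1e-6, 1e-6])
    hi = np.array([lam_grid[-1] * 2, 1.0, 1.0])

    def objective(x):
        x = np.clip(x, lo, hi)
        a, b, c, d = _cell_probs(*x)
        return float(
            (a - obs[0]) ** 2
            + (b - obs[1]) ** 2
            + (c - obs[2]) ** 2
            + (d - obs[3]) ** 2
        )

    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14})
    lam, p_rep, p_doc = np.clip(res.x, lo, hi)
    on_boundary = bool(p_rep >= 1.0 - 1e-6 or p_doc >= 1.0 - 1e-6)
    if on_boundary:
        warnings.warn(
            "calibration optimum lies on the probability boundary",
            stacklevel=2,
        )
    return CalibrationResult(
        lam=float(lam),
        p_rep=float(p_rep),
        p_doc=float(p_doc),
        expected=analytic_expected_table(float(lam), float(p_rep), float(p_doc)),
        sse=float(res.fun),
        on_boundary=on_boundary,
    )


# ---------------------------------------------------------------------------
# Regression benchmark generator


def generate_association_benchmark(
    n: int,
    beta_exposure: float,
    seed: int,
    measure: str = "neutrophil_pct",
    noise_sd: float = 1.0,
    covariate_effects: Mapping[str, float] | None = None,
    cfg: SyntheticCohortConfig | None = None,
) -> pd.DataFrame:
    """Regression data with a KNOWN exposure coefficient.

    Covariates and the BAL exposure are drawn from the cohort machinery
    (so the exposure has a realistic skewed distribution), then the
    outcome is constructed as ``beta_exposure * exposure + covariate
    terms + N(0, noise_sd)``.  This is the ground-truth benchmark for
    bias/coverage checks of the regression core: the data generation is
    independent of the fitting path.  ``noise_sd = 0`` gives exact linear
    recovery.
    """
    cfg = cfg if cfg is not None else SyntheticCohortConfig()
    cfg = replace(cfg, n_participants=n, seed=seed)
    cohort = generate_cohort(cfg)
    if covariate_effects is None:
        covariate_effects = {"age": 0.02, "current_smoker": 0.5}
    rows = []
    bal_by_pid = {s.participant_id: s for s in cohort.bal}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1017]))
    for p in cohort.participants:
        exposure = bal_by_pid[p.participant_id].measure(measure)
        cov = {
            "age": p.age,
            "sex_male": 1.0 if p.sex == "male" else 0.0,
            "height_cm": p.height_cm,
            "weight_kg": p.weight_kg,
            "current_smoker": 1.0 if p.smoking_status == "current" else 0.0,
            "pack_years": p.pack_years,
        }
        outcome = beta_exposure * exposure
        for name, coef in covariate_effects.items():
            outcome += coef * cov[name]
        if noise_sd > 0:
            outcome += rng.normal(0.0, noise_sd)
        rows.append({"participant_id": p.participant_id, "outcome": outcome,
                     measure: exposure, **cov})
    return pd.DataFrame(rows).set_index("participant_id")
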