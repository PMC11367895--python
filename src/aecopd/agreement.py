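"""Cross-channel agreement on having had any m/s exacerbation.

Participants are classified binary on each channel (any moderate-to-very-
severe event in the window, yes/no), cross-tabulated into a 2x2 table and
compared by percent agreement and Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed agreement (a+d)/n and p_e the chance agreement from
the marginals.  The standard error uses the simple asymptotic form
sqrt(p_o (1-p_o) / (n (1-p_e)^2)) and the p-value the normal
approximation of kappa/SE under kappa = 0.  A secondary view excludes the
double-negative cell (participants with no m/s event on either channel),
asking how well the channels agree among those with any event at all.

The combined per-participant count takes, at each severity level, the
larger of the self-reported and EHR-documented counts; event-level
matching is impossible because self-report carries no event dates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExacerbationProfile, SeverityCounts, SeverityLevel
from .errors import DegenerateTableError, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "AgreementResult",
    "contingency",
    "cohens_kappa",
    "exclude_double_negative",
    "combine_counts",
    "build_profiles",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 cross-classification of (self-report yes/no, EHR yes/no).

    Cell layout: ``a`` both-no, ``b`` self-yes & EHR-no, ``c`` self-no &
    EHR-yes, ``d`` both-yes.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise ValidationError(f"cell {name} must be an integer")
            if value < 0:
                raise ValidationError(f"cell {name} must be non-negative")
        if self.n == 0:
            raise ValidationError("contingency table is empty (n = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    # marginals ------------------------------------------------------------

    @property
    def self_yes(self) -> int:
        return self.b + self.d

    @property
    def self_no(self) -> int:
        return self.a + self.c

    @property
    def ehr_yes(self) -> int:
        return self.c + self.d

    @property
    def ehr_no(self) -> int:
        return self.a + self.b

    def transpose(self) -> "ContingencyTable2x2":
        """Swap the two raters (self <-> EHR)."""
        return ContingencyTable2x2(a=self.a, b=self.c, c=self.b, d=self.d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.a, self.b], [self.c, self.d]],
            index=pd.Index(["no", "yes"], name="ehr_ms"),
            columns=pd.Index(["no", "yes"], name="self_ms"),
        )

    def as_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d, "n": self.n}


@dataclass(frozen=True)
class AgreementResult:
    """Kappa, its SE, observed/expected agreement and the test p-value."""

    kappa: float
    se_kappa: float
    percent_agreement: float
    expected_agreement: float
    n: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "se_kappa": self.se_kappa,
            "percent_agreement": self.percent_agreement,
            "expected_agreement": self.expected_agreement,
            "n": self.n,
            "p_value": self.p_value,
        }


def contingency(profiles: Sequence[ExacerbationProfile]) -> ContingencyTable2x2:
    """Cross-tabulate participants by (any m/s self-report, any m/s EHR)."""
    if not profiles:
        raise ValidationError("contingency: empty profile list")
    a = b = c = d = 0
    for p in profiles:
        if p.any_ms_self and p.any_ms_ehr:
            d += 1
        elif p.any_ms_self:
            b += 1
        elif p.any_ms_ehr:
            c += 1
        else:
            a += 1
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def cohens_kappa(table: ContingencyTable2x2) -> AgreementResult:
    """Cohen's kappa with asymptotic SE and normal-approximation p-value.

    Raises :class:`DegenerateTableError` when the marginals make the
    expected agreement 1 (both raters constant), where kappa is undefined.
    """
    n = table.n
    p_o = (table.a + table.d) / n
    p_e = (
        table.ehr_no * table.self_no + table.ehr_yes * table.self_yes
    ) / (n * n)
    if p_e >= 1.0:
        raise DegenerateTableError(
            "kappa undefined: degenerate marginals (expected agreement = 1)"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    if se > 0:
        z = kappa / se
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    else:
        # perfect (or perfectly inverse) observed agreement: SE collapses
        p_value = 0.0 if kappa != 0 else 1.0
    return AgreementResult(
        kappa=float(kappa),
        se_kappa=se,
        percent_agreement=float(p_o),
        expected_agreement=float(p_e),
        n=n,
        p_value=p_value,
    )


def exclude_double_negative(table: ContingencyTable2x2) -> ContingencyTable2x2:
    """Drop the both-negative cell, keeping only participants with any m/s
    event on at least one channel."""
    if table.n - table.a == 0:
        raise DegenerateTableError(
            "all participants are double-negative; nothing left to compare"
        )
    return ContingencyTable2x2(a=0, b=table.b, c=table.c, d=table.d)


def combine_counts(
    self_counts: SeverityCounts, ehr_counts: SeverityCounts
) -> SeverityCounts:
    """Per-severity maximum of the two channels (source ``combined``).

    Dates of self-reported events are unknown, so events cannot be matched
    one-to-one across channels; taking the per-level maximum is a lower
    bound on the union of true events.
    """
    if self_counts.participant_id != ehr_counts.participant_id:
        raise ValidationError(
            f"combine_counts: participant mismatch "
            f"{self_counts.participant_id!r} vs {ehr_counts.participant_id!r}"
        )
    if self_counts.window_years != ehr_counts.window_years:
        raise ValidationError("combine_counts: mismatched window_years")
    return SeverityCounts(
        participant_id=self_counts.participant_id,
        source="combined",
        counts={
            lvl: max(self_counts.counts[lvl], ehr_counts.counts[lvl])
            for lvl in SeverityLevel
        },
        window_years=self_counts.window_years,
    )


def build_profiles(
    self_counts: Sequence[SeverityCounts],
    ehr_counts: Sequence[SeverityCounts],
) -> list[ExacerbationProfile]:
    """Pair channels by participant and attach the combined count.

    Participants present on only one channel are dropped (a participant
    without EHR availability is excluded from concordance, not treated as
    zero-EHR).
    """
    self_by_pid = {sc.participant_id: sc for sc in self_counts}
    ehr_by_pid = {sc.participant_id: sc for sc in ehr_counts}
    if len(self_by_pid) != len(self_counts) or len(ehr_by_pid) != len(ehr_counts):
        raise ValidationError("build_profiles: duplicate participant_id")
    shared = sorted(set(self_by_pid) & set(ehr_by_pid))
    return [
        ExacerbationProfile(
            participant_id=pid,
            self_counts=self_by_pid[pid],
            ehr_counts=ehr_by_pid[pid],
            combined_counts=combine_counts(self_by_pid[pid], ehr_by_pid[pid]),
        )
        for pid in shared
    ]
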