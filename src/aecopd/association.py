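"""Association of exacerbation burden with BAL inflammatory cells.

For the bronchoscopy subset, the number of m/s exacerbations over the
window (by self-report, EHR documentation, or both combined) is regressed
by ordinary least squares on one bronchoalveolar-lavage (BAL) measure —
the percentage or the absolute concentration of a cell type — adjusting
for age, sex, height, weight, current-versus-former smoking and smoking
burden (pack-years).  Sex and smoking status enter as binary indicators.
Confidence intervals use estimate +/- 1.96 SE; coefficients from two
models are compared by z = (b1 - b2)/sqrt(se1^2 + se2^2) with a
two-sided normal p-value.

A "per 10%" effect for a percentage exposure is a display-time x10
rescale of the per-1% coefficient, never a refit.

The sensitivity analysis reverses the roles: the BAL measure is regressed
on the time since the last m/s episode (days; all > 6 weeks by study
design, since sampling required a stable baseline) plus the covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import ExacerbationProfile, Participant
from .errors import ValidationError

__all__ = [
    "CELL_TYPES",
    "MEASURES",
    "BALSample",
    "CoefficientEstimate",
    "AssociationModel",
    "COVARIATES",
    "fit_linear_model",
    "fit_association",
    "compare_coefficients",
    "sensitivity_time_since",
    "rescale_per_10pct",
    "load_bal",
    "write_bal",
    "plot_coefficients",
]

CELL_TYPES = ("neutrophil", "lymphocyte", "macrophage", "eosinophil", "other")

#: Supported exposure measures: "<cell>_pct" (percentage of the
#: differential, 0-100) and "<cell>_conc" (cells per mL).
MEASURES = tuple(f"{c}_{kind}" for c in CELL_TYPES for kind in ("pct", "conc"))

#: Adjustment covariate columns in the model design.
COVARIATES = ("age", "sex_male", "height_cm", "weight_kg", "current_smoker",
              "pack_years")

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class BALSample:
    """Differential cell composition of one BAL sample.

    ``fractions`` maps each cell type to its share of counted immune
    cells (must sum to 1); concentrations are fraction x total cell
    concentration (cells/mL).
    """

    participant_id: str
    total_cells_per_ml: float
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not (self.total_cells_per_ml > 0):
            raise ValidationError(
                f"BAL {self.participant_id}: total_cells_per_ml must be positive"
            )
        fr = dict(self.fractions)
        unknown = set(fr) - set(CELL_TYPES)
        if unknown:
            raise ValidationError(
                f"BAL {self.participant_id}: unknown cell types {sorted(unknown)}"
            )
        for cell in CELL_TYPES:
            value = float(fr.get(cell, 0.0))
            if value < 0:
                raise ValidationError(
                    f"BAL {self.participant_id}: negative {cell} fraction"
                )
            fr[cell] = value
        total = sum(fr.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                f"BAL {self.participant_id}: fractions sum to {total}, not 1"
            )
        object.__setattr__(self, "fractions", fr)

    @property
    def concentrations(self) -> dict[str, float]:
        return {
            cell: self.fractions[cell] * self.total_cells_per_ml
            for cell in CELL_TYPES
        }

    def measure(self, name: str) -> float:
        """Value of a ``<cell>_pct`` or ``<cell>_conc`` exposure."""
        if name not in MEASURES:
            raise ValidationError(f"unknown BAL measure {name!r}")
        cell, kind = name.rsplit("_", 1)
        if kind == "pct":
            return self.fractions[cell] * 100.0
        return self.concentrations[cell]


@dataclass(frozen=True)
class CoefficientEstimate:
    """One regression term: point estimate, SE, 95% CI and p-value."""

    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class AssociationModel:
    """A fitted OLS model: outcome ~ exposure + covariates."""

    outcome: str
    exposure: str
    coefficients: tuple[CoefficientEstimate, ...]
    n: int
    r_squared: float

    def coefficient(self, term: str) -> CoefficientEstimate:
        for coef in self.coefficients:
            if coef.term == term:
                return coef
        raise ValidationError(f"term {term!r} not in model for {self.outcome}")

    @property
    def exposure_coefficient(self) -> CoefficientEstimate:
        return self.coefficient(self.exposure)

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "exposure": self.exposure,
            "n": self.n,
            "r_squared": self.r_squared,
            "coefficients": [c.as_dict() for c in self.coefficients],
        }


def fit_linear_model(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = COVARIATES,
    min_n: int = 10,
) -> AssociationModel:
    """OLS of ``outcome`` on ``exposure`` plus ``covariates``.

    This is the regression core shared by :func:`fit_association` and
    :func:`sensitivity_time_since`; rows with any missing value are
    dropped, the design must be full rank and leave positive residual
    degrees of freedom.  Per-term p-values come from the OLS t-statistics;
    the 95% CI is the estimate +/- 1.96 SE convention.
    """
    cols = [outcome, exposure, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"fit_linear_model: missing columns {missing}")
    frame = data[cols].dropna()
    n = len(frame)
    if n < min_n:
        raise ValidationError(
            f"fit_linear_model: only {n} complete cases (need >= {min_n})"
        )
    X = sm.add_constant(frame[[exposure, *covariates]].astype(float),
                        has_constant="add")
    y = frame[outcome].astype(float)
    if n <= X.shape[1]:
        raise ValidationError(
            f"fit_linear_model: n={n} does not exceed {X.shape[1]} model terms"
        )
    rank = int(np.linalg.matrix_rank(X.to_numpy()))
    if rank < X.shape[1]:
        constant_terms = [
            c for c in X.columns[1:] if frame[c].nunique() <= 1
        ]
        detail = (
            f" (constant column(s): {constant_terms})" if constant_terms else ""
        )
        raise ValidationError(
            f"fit_linear_model: design matrix rank deficient{detail}"
        )
    fit = sm.OLS(y, X).fit()
    coefficients = tuple(
        CoefficientEstimate(
            term=term,
            estimate=float(fit.params[term]),
            se=float(fit.bse[term]),
            ci_low=float(fit.params[term] - 1.96 * fit.bse[term]),
            ci_high=float(fit.params[term] + 1.96 * fit.bse[term]),
            p_value=float(fit.pvalues[term]),
        )
        for term in X.columns
    )
    return AssociationModel(
        outcome=outcome,
        exposure=exposure,
        coefficients=coefficients,
        n=n,
        r_squared=float(fit.rsquared),
    )


def _covariate_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": p.participant_id,
            "age": p.age,
            "sex_male": 1.0 if p.sex == "male" else 0.0,
            "height_cm": p.height_cm,
            "weight_kg": p.weight_kg,
            "current_smoker": 1.0 if p.smoking_status == "current" else 0.0,
            "pack_years": p.pack_years,
        }
        for p in participants
    ]
    return pd.DataFrame(rows).set_index("participant_id")


def assemble_analysis_frame(
    participants: Sequence[Participant],
    profiles: Sequence[ExacerbationProfile],
    bal: Sequence[BALSample],
    source: str,
    measure: str,
) -> pd.DataFrame:
    """Merge covariates, m/s count outcome and BAL exposure by participant."""
    if measure not in MEASURES:
        raise ValidationError(f"unknown BAL measure {measure!r}")
    cov = _covariate_frame(participants)
    outcome_name = f"ms_count_{source}"
    counts = pd.Series(
        {p.participant_id: p.counts_for(source).ms_total for p in profiles},
        name=outcome_name,
    )
    exposure = pd.Series(
        {s.participant_id: s.measure(measure) for s in bal}, name=measure
    )
    frame = cov.join(counts, how="inner").join(exposure, how="inner")
    return frame.sort_index()


def fit_association(
    participants: Sequence[Participant],
    profiles: Sequence[ExacerbationProfile],
    bal: Sequence[BALSample],
    source: str = "self_report",
    measure: str = "neutrophil_pct",
    min_n: int = 10,
) -> AssociationModel:
    """OLS of the m/s count (chosen channel) on one BAL measure + covariates.

    Only participants present in all three inputs (covariates, counts and
    BAL) enter the model.
    """
    frame = assemble_analysis_frame(participants, profiles, bal, source, measure)
    return fit_linear_model(
        frame, outcome=f"ms_count_{source}", exposure=measure, min_n=min_n
    )


def compare_coefficients(
    m1: AssociationModel, m2: AssociationModel, term: str
) -> dict[str, float]:
    """z-test of equality of one term across two fitted models.

    z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided normal p-value.
    """
    from scipy import stats

    c1 = m1.coefficient(term)
    c2 = m2.coefficient(term)
    denom = float(np.sqrt(c1.se**2 + c2.se**2))
    if denom == 0:
        raise ValidationError("compare_coefficients: both SEs are zero")
    z = (c1.estimate - c2.estimate) / denom
    return {"z": float(z), "p": float(2.0 * stats.norm.sf(abs(z)))}


def rescale_per_10pct(coef: CoefficientEstimate) -> CoefficientEstimate:
    """Report a per-1% coefficient on the per-10% scale (display only)."""
    return CoefficientEstimate(
        term=f"{coef.term}_per_10pct",
        estimate=coef.estimate * 10.0,
        se=coef.se * 10.0,
        ci_low=coef.ci_low * 10.0,
        ci_high=coef.ci_high * 10.0,
        p_value=coef.p_value,
    )


def sensitivity_time_since(
    participants: Sequence[Participant],
    bal: Sequence[BALSample],
    time_since_days: Mapping[str, float],
    measure: str = "neutrophil_pct",
    min_n: int = 10,
    min_days: float = 42.0,
) -> AssociationModel:
    """OLS of a BAL measure on days since the last m/s episode + covariates.

    All time-since values must exceed ``min_days`` (6 weeks): sampling was
    only performed after full recovery from any recent exacerbation.
    """
    if measure not in MEASURES:
        raise ValidationError(f"unknown BAL measure {measure!r}")
    bad = {pid: t for pid, t in time_since_days.items() if not t > min_days}
    if bad:
        raise ValidationError(
            f"sensitivity_time_since: values must exceed {min_days} days, "
            f"violated for {sorted(bad)}"
        )
    cov = _covariate_frame(participants)
    exposure = pd.Series(dict(time_since_days), name="time_since_days")
    outcome = pd.Series(
        {s.participant_id: s.measure(measure) for s in bal}, name=measure
    )
    frame = cov.join(outcome, how="inner").join(exposure, how="inner").sort_index()
    return fit_linear_model(
        frame, outcome=measure, exposure="time_since_days", min_n=min_n
    )


# ---------------------------------------------------------------------------
# CSV I/O and plotting


def load_bal(path) -> list[BALSample]:
    """Read the BAL differential-count CSV."""
    df = pd.read_csv(path)
    expected = {"participant_id", "total_cells_per_ml"} | {
        f"frac_{c}" for c in CELL_TYPES
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                BALSample(
                    participant_id=str(row["participant_id"]),
                    total_cells_per_ml=float(row["total_cells_per_ml"]),
                    fractions={
                        c: float(row[f"frac_{c}"]) for c in CELL_TYPES
                    },
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
    return out


def write_bal(samples: Sequence[BALSample], path) -> None:
    rows = [
        {
            "participant_id": s.participant_id,
            "total_cells_per_ml": s.total_cells_per_ml,
            **{f"frac_{c}": s.fractions[c] for c in CELL_TYPES},
        }
        for s in samples
    ]
    columns = ["participant_id", "total_cells_per_ml"] + [
        f"frac_{c}" for c in CELL_TYPES
    ]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, lineterminator="\n"
    )


def plot_coefficients(models: Sequence[AssociationModel], path) -> None:
    """Dot-and-whisker plot of the exposure estimates with 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{m.outcome}\n~ {m.exposure}" for m in models]
    estimates = [m.exposure_coefficient.estimate for m in models]
    lows = [m.exposure_coefficient.ci_low for m in models]
    highs = [m.exposure_coefficient.ci_high for m in models]
    y = np.arange(len(models))[::-1]
    fig, ax = plt.subplots(figsize=(6, 1 + 0.8 * len(models)))
    ax.hlines(y, lows, highs, color="tab:blue")
    ax.plot(estimates, y, "o", color="tab:blue")
    ax.axvline(0.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("parameter estimate (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
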