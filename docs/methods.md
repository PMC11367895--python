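# Methods

## Problem and scope

Clinical research on chronic obstructive pulmonary disease (COPD) usually
quantifies acute exacerbations (AECOPD) from a self-report questionnaire,
yet events can also be counted by adjudicating electronic health records
(EHR) — and the two channels disagree. This package implements, as a
reusable pipeline, (i) quantification of exacerbations over a 3-year
window from both channels, (ii) their cross-classification and
chance-corrected agreement, (iii) linear association of exacerbation
burden with bronchoalveolar-lavage (BAL) inflammatory cell composition,
and (iv) a synthetic cohort generator that emulates the latent
event/reporting/documentation process so the full pipeline is exercised
without any patient data.

## Severity taxonomy and dichotomization

Events are graded on a six-level ordinal scale: very mild (no special
treatment), mild (home inhaler escalation only), moderate (antibiotic or
steroid kept at home), moderately severe (clinician-prescribed antibiotic
and/or steroid), severe (hospital admission), very severe (ICU admission
and/or intubation). The main analyses dichotomize at *moderate*: an "m/s"
event is any event at level 3–6. This cut is principled for the EHR
channel: by definition sub-moderate events need no healthcare contact and
may generate no record, so only the m/s count is comparable across
channels. Per-participant m/s rates use the full 3-year window
(`ms_total / 3`); "frequent exacerbator" means an average ≥ 2 m/s events
per year. The ≥ 1/yr and ≥ 2/yr thresholds are window averages, not
every-year requirements. Missing questionnaire cells are errors, never
imputed as zero — silent zeros would deflate the self-report margin and
bias agreement.

## EHR adjudication rules

An encounter qualifies as an AECOPD event only when a COPD exacerbation
is itself among the documented (admission or discharge) diagnoses. Two
attribution guards remove treatment explainable by a co-diagnosis:

* pneumonia co-diagnosis: event only if **both** an antibiotic and a
  systemic steroid were prescribed (pure pneumonia, or pneumonia treated
  with antibiotics alone, is not an exacerbation);
* a steroid-requiring co-diagnosis (allergic or interstitial lung
  disease): event only if both drug classes were prescribed, so the
  steroid alone is attributable to the co-diagnosis.

Cardiovascular and embolic mimics (MI, CHF, pulmonary embolism) never
qualify because the exacerbation diagnosis is absent in those encounters;
the excluded-diagnosis list is retained in the configurable rule table
for vocabulary control.

Severity is a total function of (setting, ICU flag, medications):
ICU/intubation → very severe; hospital admission → severe; outpatient
contact with prescribed antibiotic/steroid → moderately severe;
note-documented self-treatment with home-kept antibiotic/steroid
(medication class `home_antibiotic_steroid`) → moderate; inhaler
escalation only → mild; documented symptoms without treatment → very
mild. The whole mapping ships as a default `RuleTable` and is
configurable via YAML; the extra `home_antibiotic_steroid` medication
code exists so that every severity level has an encounter representation.

**Episode merging.** Candidate events less than one month apart describe
one clinical episode (a relapse or slow-to-resolve flare). "One month" is
fixed at 30 days, measured between nearest event dates, with strict
comparison (a 30-day gap separates episodes) and transitive
(single-linkage) chaining, because a relapse chain is one illness even
when its extremes are far apart; calendar-month arithmetic was rejected
as date-dependent. Episode severity is the maximum over members (an ICU
relapse of a clinic-treated flare is one very severe episode); episodes
are assigned to the 3-year review window by their start date. The window
is exactly 3 years (1095 days) ending at enrollment; partial windows are
rejected.

## Agreement statistics

Participants are classified binary per channel (any m/s event, yes/no)
and cross-tabulated. With cells a (both no), b (self-only), c (EHR-only),
d (both yes) and n = a+b+c+d:

    p_o = (a + d) / n
    p_e = [(a+b)(a+c) + (c+d)(b+d)] / n²
    κ   = (p_o − p_e) / (1 − p_e)
    SE(κ) = sqrt[ p_o (1 − p_o) / ( n (1 − p_e)² ) ]

The SE is the simple asymptotic (delta-method) form; the two-sided
p-value is the normal approximation of κ/SE under κ = 0. Degenerate
marginals (p_e = 1) raise an explicit error. A secondary view removes the
double-negative cell a and recomputes κ on (0, b, c, d): among
participants with at least one m/s event by either method, does the
*other* channel confirm it? This view is typically strongly negative even
when overall agreement is moderate, because within that subset the two
channels partition mostly into disjoint single-channel cases.

The combined per-participant count takes, at each of the six severity
levels, the larger of the self-reported and EHR-documented counts, then
derives `ms_total` from the combined vector. Event-level matching across
channels is impossible (self-report has no event dates), so the per-level
maximum is a conservative lower bound on the union of true events.

## Association models

For the bronchoscopy subset, ordinary least squares regresses the m/s
count (self-report, EHR, or combined channel) on one BAL measure — the
percentage (0–100) or concentration (cells/mL) of neutrophils,
lymphocytes, macrophages or eosinophils — adjusting for age, sex (male
indicator), height, weight, current-vs-former smoking, and pack-years.
Plain OLS is used deliberately (not a count model): the target analysis
is linear, and overdispersion handling is out of scope. Confidence
intervals are estimate ± 1.96·SE (normal convention; the residual-df
t-quantile at the n≈56 scale differs by < 3%); per-term p-values are the
OLS t-tests. Two models' coefficients are compared with
z = (β₁−β₂)/√(SE₁²+SE₂²) and a two-sided normal p-value. "Per 10%"
effects for percentage exposures are a display-time ×10 rescale of the
per-1% coefficient, never a refit. Rank-deficient designs and
insufficient complete cases (< 10) raise errors naming the offending
terms.

The sensitivity analysis reverses direction: the BAL measure is the
outcome and days since the last m/s episode the exposure (plus the same
covariates). All time-since values must exceed 42 days, mirroring the
design rule that sampling required ≥ 6 weeks of stability.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is
validated. Per participant:

* total event count over 3 years ~ NegBin(mean 1.2, dispersion θ = 1;
  θ = ∞ gives Poisson), severities iid from the simplex
  (0.19, 0.17, 0.19, 0.26, 0.15, 0.04) estimated from the self-reported
  event-severity distribution of a published COPD cohort; event dates
  uniform over the window;
* each event is independently *reported* with per-severity probability
  p_report (default 0.55 sub-moderate, 0.47 m/s) and independently
  *documented* with p_document (default 0.05 sub-moderate — mild events
  rarely generate records — and 0.56 m/s). The m/s values and the event
  rate come from the closed-form inversion of a published 2×2 agreement
  table; with θ = 1 and mean 1.2 the model's binary margins are ~26%
  (self) and ~30% (EHR). Independence of the two channels is an explicit
  modelling choice, the simplest mechanism producing discordance in both
  directions; a channel correlation is not modelled;
* documented events emit one encounter each, built from a per-severity
  template (setting/diagnoses/medications) that adjudicates back to
  exactly the latent severity; documented-event dates are rejection-
  sampled ≥ 30 days apart so merging never conflates distinct true
  events. A relapse mode adds satellite encounters 7 days after each
  index event (severity capped at the index) to exercise episode
  chaining without changing episode counts;
* covariates mirror a typical elderly, mostly-male, heavy-smoking COPD
  cohort: age ~ N(70, 7²) truncated at 41, height ~ N(176, 10²), weight
  ~ N(86, 22²), pack-years lognormal with median 57, 96% male, 42%
  current smokers. Binary covariates are assigned by exact composition
  (round(n·fraction), shuffled) so small subsets keep both levels
  represented and regression designs stay full rank;
* the BAL neutrophil fraction is expit(−2.5 + 0.15·K + 0.25·current
  smoker + N(0, 0.5²)) with K the true m/s count (baseline ≈ 8%
  neutrophils); the other cell types fill the remaining mass in fixed
  background proportions (macrophage 0.84, lymphocyte 0.11, eosinophil
  0.01, other 0.04). Consequence: by construction only the neutrophil
  margin carries a positive burden link; the renormalized lymphocyte
  fraction inherits a *negative* compositional association. Real BAL
  data show positive lymphocyte associations, which this squashed-linear
  link with background renormalization deliberately does not attempt to
  reproduce — only the neutrophil margin is modelled mechanistically.

All randomness flows through one `numpy` Generator seeded from the
config; output is byte-identical across runs at a fixed seed.

**Closed-form oracle.** Under Poisson events and severity-constant
channel probabilities, P(self = 0) = exp(−λ·p_rep), P(ehr = 0) =
exp(−λ·p_doc), and P(both 0) = exp(−λ·(1 − (1−p_rep)(1−p_doc)));
the remaining cells follow by inclusion–exclusion and population κ by the
kappa formula. `calibrate_to_table` inverts this map from an observed 2×2
table by vectorized grid search (λ ∈ [0.05, 4], p ∈ [0.05, 1]) refined
with Nelder–Mead; a three-parameter model fitting three free proportions
is exactly identified, so interior solutions reach machine-precision
residuals, and boundary solutions (p → 1) warn.

**What passing tests do and do not show.** The generator validates the
pipeline's bookkeeping (counts, merging, agreement arithmetic, regression
mechanics) under a clean independence model. It does not emulate
free-text notes, cross-system record fragmentation, correlated
reporting/documentation failure, severity misclassification between
channels, or the extra overdispersion of real per-participant event
counts — so passing tests certify the method, not the epidemiology of
any real cohort.

## Numerical and testing choices

* Oracles are independent of the paths they check: episode merging is
  compared against a graph-connected-components clustering; the
  adjudication engine against a straight-line rule-by-rule
  reimplementation; kappa against the `statsmodels` implementation; the
  analytic 2×2 cells against an event-level Monte-Carlo with 10⁶
  participants; regression recovery against data generated under the
  fitted model with known coefficients.
* Problem sizes: the simulator-vs-oracle check runs three (λ, p_rep,
  p_doc) settings at n = 10⁵ through the full
  generate → adjudicate → cross-tabulate pipeline, comparing each cell
  within 3 binomial standard errors; regression bias/coverage uses 500
  cohorts of n = 56 (the bronchoscopy-subset scale), expecting ~95%
  coverage of ±1.96·SE intervals.
* Ties and determinism: events sorted by (date, severity) before
  chaining; all outputs independent of input row order; CSVs written
  with fixed column order and `\n` terminators so round-trips are
  byte-identical.
* Degenerate inputs raise typed errors (`ValidationError`,
  `ConfigError`, `DegenerateTableError`) mapped to CLI exit codes 1/2.

## Known limitations

* The adjudication severity mapping is a declared default, not a
  transcription of any site's operating procedure; it is fully
  configurable via `RuleTable`.
* Whether the sub-month gap should run from symptom onset, encounter, or
  discharge date is unknowable from counts alone; encounter dates are
  used.
* The combined count is a lower bound on the union of true events; a
  matched-event combination would need self-reported event dates.
* OLS on a count outcome ignores overdispersion; published empirical
  regression coefficients for BAL cannot be reproduced without the
  original participant-level data, so the association module is
  validated by recovery/coverage properties instead.
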