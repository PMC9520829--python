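# Methods

This note documents the models and procedures `concare` implements, the
design choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real claims data.

## Study design being emulated

A retrospective incident-cohort design over linked single-payer
administrative tables: physician billing claims, hospital discharge
abstracts, emergency-department (ED) records and a person registry.
Patients aged 35 or older enter the cohort at their first qualifying
COPD diagnosis inside a recruitment window (default 2005-04-01 to
2013-03-31) and are followed for up to five years, censored at death,
loss of provincial coverage (move-out) or the administrative study end
(default 2018-03-31).

### Case definition

A qualifying event is one or more billing claims and/or one or more
hospital discharges (most-responsible diagnosis) carrying a COPD code.
The default ICD-9 set is {491, 492, 496} with ICD-10 {J41, J42, J43,
J44}; matching is prefix-based because administrative codes carry
sub-digits. Some published materials print the ICD-9 set as
"91, 492, 496"; we read "91" as a truncation of 491 (the standard
validated claims triad is 491/492/496) and expose the literal printed
set through the YAML case-definition config for anyone who wants it.
The case-definition *validation* figures sometimes quoted alongside it
(sensitivity 85.0%, specificity 78.4%) are properties of the original
chart-review study and are not recomputed here.

### Exclusions and follow-up

Exclusions are applied in a fixed precedence order, each patient
carrying exactly the first matching reason: invalid identifier
(format: one uppercase letter + seven digits), non-resident, no
insurance coverage at the index date, qualifying history before the
recruitment window (prevalent case), and age under 35 at index.
Patients whose only qualifying events postdate the window are not
candidates at all. Follow-up ends at
`min(index + 5 years, death, coverage end, study end)`, with ties
resolved in that priority order. A two-year pre-index look-back is the
convention for comorbidity ascertainment; the bundled comorbidity
measure (an integer ADG-style score) is carried on the person registry,
so the look-back does not need to be recomputed from claims here.

## Continuity indices

Computed over outpatient claims by the two specialty groups of interest
(family physicians and the respirology group — other specialties are
deliberately not counted), inside `[index, follow-up end)`:

* UPC `= max_j n_j / N` (defined for N ≥ 1),
* COC `= (Σ n_j² − N) / (N (N − 1))` (N ≥ 2) — algebraically the
  without-replacement pair-concordance probability, which is what the
  test oracle enumerates,
* SECON `= Σ 1[provider_i = provider_{i+1}] / (N − 1)` (N ≥ 2).

Same-day claims to the same physician collapse to one visit; same-day
claims to different physicians remain separate visits, ordered
date-then-physician-id (this affects SECON only). Patients with N ≤ 5
are flagged `not_assessed` and excluded from the median computation,
the dichotomization and the models; the median is therefore computed
*after* the few-visits exclusion. Scores at or below the median are
`low` — the convention that makes the low group the weakly larger one.
Predominant provider group is whichever specialty group received
strictly more visits, ties going to the family physician as the
system's default attachment point. Distance to the usual provider (the
max-`n_j` physician, ties by earliest first visit then id) is the
haversine great-circle distance with Earth radius 6371 km.

## Utilization outcomes

All outcome counting is restricted to admissions/visits whose admit or
visit date falls in `[index, follow-up end)`. Overlapping or nested
hospital stays are merged into single episodes before anything is
counted, so a transfer-back cannot register as a same-day readmission.
A 30-day readmission is a non-elective, non-transfer episode admitted
in `(discharge, discharge + 30 days]` of the immediately preceding
episode — inclusive of day 30, exclusive of day 0, pairing only with
the immediately preceding stay (no chaining of one index stay to
several readmissions). "COPD-related" means the most-responsible
diagnosis matches the case-definition sets. ED visits split into
with-admission (unscheduled, linked to a discharge abstract with the
same admit date) and without-admission; a scheduled ED-to-admission
encounter is planned care and is excluded from the ED counts entirely,
which preserves the identity `with + without = all`. Admission counts
include all categories by default ("any cause"); an `unplanned_only`
flag drops elective and transfer stays for sensitivity analyses.

## Descriptive contrasts

Standardized differences: continuous
`d = |m₁ − m₂| / sqrt((s₁² + s₂²)/2)`; binary
`d = |p₁ − p₂| / sqrt((p₁(1−p₁) + p₂(1−p₂))/2)`; multi-category the
Mahalanobis-type distance on the first L−1 categories with the averaged
multinomial covariance (Yang–Dalton construction), which reduces
exactly to the binary formula at L = 2. Zero pooled variance with
differing means returns an infinite-difference sentinel with a warning
rather than an exception. Which multi-category variant the original
analyses of such cohorts use is rarely stated; the choice here is
declared, not inferred, and is pinned by a dual-implementation test.

## Association models

Logistic regressions of four binary outcomes (any admission, any ED
visit, any 30-day readmission, and ≥ 2 readmissions — the
"number of readmissions" row operationalized as a binary contrast so a
single likelihood machinery serves all rows) on the low-continuity
indicator, at three adjustment tiers. Age enters continuously;
socioeconomic status enters as income-quintile dummies (reference
quintile 1) plus the continuous marginalization composite; provider
group as an SP dummy (reference FP). Confidence intervals are Wald
(`exp(β ± 1.96 SE)`) — appropriate at these sample sizes and matching
the symmetric interval widths such studies report. Perfect separation
or non-convergence is flagged on the result object. Patients censored
early (death, move) contribute their observed follow-up to the binary
outcomes with no exposure-time offset, as is standard for this design;
the differential follow-up is visible in the cohort table for anyone
who wants to condition on it.

## Synthetic claims generator

The generator emulates the statistical structure the analysis assumes,
with every arbitrary choice documented here as a stand-in:

* **Visit counts**: `1 + NegBin(size 4, mean 30)` over the five-year
  window, giving the heavy right tail in which about 70% of patients
  draw more than 20 visits (verified against the negative-binomial
  survival function). Censoring then trims realized counts, so the
  observed share above 20 visits is a little lower (~62%).
* **Provider allocation**: each patient has a pool of 7 providers
  (drawn with replacement from the registry; duplicate slots merge).
  Visit weights are symmetric Dirichlet(α = 0.19), visits i.i.d.
  categorical given the weights (Dirichlet-multinomial marginals). The
  expected concentration `E[Σ p_j²] = (1 + α)/(1 + kα)` is 0.51 at the
  defaults, matching the mean COC such cohorts report; α → 0 sends all
  visits to a single provider and large α spreads them uniformly, so
  expected COC is monotone decreasing in α (checked by simulation).
  Weights are sorted descending onto the slots of the designated
  predominant group (specialist with probability 0.058), which leaves
  the index distributions untouched (the weight vector is exchangeable)
  but makes the predominance parameter actually govern realized
  predominance (~94% FP at defaults).
* **Visit dates**: uniform over follow-up, sorted; the first visit sits
  on the diagnosis date and carries a qualifying code. Ground-truth
  UPC/COC/SECON are computed from the realized (censored, collapsed)
  sequence — i.e. the continuity actually experienced during follow-up,
  which is the exposure the design intends — and the true low/high
  category is the median cut of that true COC among patients with more
  than five visits.
* **Outcomes**: a logistic model on standardized covariates (age, sex,
  ADG score, rurality, marginalization composite) plus the true
  low-continuity indicator, whose default coefficient is ln(2.25). The
  same linear predictor, with intercept offsets, drives stand-alone ED
  visits and per-discharge 30-day readmission propensity, so a null
  exposure coefficient nulls all twelve suite odds ratios at once.
  Admission episodes are placed sequentially; readmissions land within
  30 days of the prior discharge and are emergent. Deaths follow an
  exponential hazard (0.035/year) independent of outcomes; a death
  during follow-up is relocated onto the final discharge with
  probability 0.55 so discharge-due-to-death is non-degenerate, and any
  death inside a stay truncates it.
* **Linkage and edge cases**: emergent admissions generate an admitted
  ED record with probability 0.85 (2% flagged scheduled); small
  fractions of persons carry malformed identifiers (0.2%),
  non-residency (0.3%), coverage starting after index (0.2%) and
  pre-window COPD claims (1%), so every exclusion branch is exercised.
  Ages are normal(61.5, 14.6) truncated to [31, 99], letting the
  under-35 exclusion fire.
* **Determinism**: one root seed spawns independent numpy substreams
  per table; identical configs reproduce every table byte-for-byte.

### What the synthetic tests do and do not show

Passing the planted-recovery and calibration tests shows the pipeline
measures what the generator defines — windowing, collapsing,
dichotomization, outcome derivation and model fitting are mutually
consistent and statistically unbiased under the generative model. It
does not validate the generative model against real claims: real visit
processes are bursty rather than uniform in time, provider pools are
geographically structured (the synthetic distance-to-provider
distribution is much wider than real ones, since offices are scattered
uniformly over the map), coding practice varies, and disease severity
confounds continuity and outcomes in ways no planted logistic captures.
UPC and SECON means here (~0.65, ~0.51) bracket rather than match the
published ones — only the COC level was targeted by the α default,
since the dichotomized COC is the analysis exposure.

## Problem sizes and numerical choices

The acceptance-grade checks use 20 replicates of 20,000 patients for
planted-effect recovery (mean adjusted OR within 10% of 2.25; Wald CI
coverage between 0.85 and 0.99) and 3–4 replicates for null calibration
(every |log OR| within 4 SE of 0; at least 43 of 48 nominal-95% CIs
covering 1 — the binomial tolerance implied by checking finitely many
intervals). The covariate-adjusted (Model A) estimate is the recovery
target because the generator's outcome model conditions on those
covariates; the unadjusted marginal OR is attenuated by
non-collapsibility, which is a property of odds ratios, not an error.
Index oracles run exhaustive pair enumeration on 1,000 random sequences
and ordering checks on 10,000. These sizes keep a full run near 90
seconds on one CPU while leaving Monte-Carlo error well inside every
tolerance. Ties in the median cut go to `low`; ties in predominance go
to FP; both are asserted in tests so a refactor cannot silently flip
them.

## Known limitations

No geographic structure in provider choice; no within-group physician
teams (each claim attributes to an individual physician, as in the
source databases); no severity process linking continuity, mortality
and utilization; comorbidity is a supplied integer score, not a claims
grouper; the Ontario-population comparison column of descriptive tables
requires an external reference summary the package does not bundle.
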