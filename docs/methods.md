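# Methods

This note documents the models, parameter choices and numerical
conventions behind `diabtype`, and what the synthetic data do and do not
establish about behaviour on real registries.

## Cohort construction

**Onset definition.** Diabetes onset is the first occurrence of any of:
outpatient HbA1c ≥ 6.5 %, outpatient fasting plasma glucose ≥ 7 mmol/L, a
non-insulin glucose-lowering prescription, or a long-term insulin
prescription (≥ 28 days). Inpatient glucose measurements are ignored so
acute stress hyperglycemia is not mistaken for diabetes; by default
inpatient HbA1c is excluded on the same footing (HbA1c is not an
acute-stress measure, so `OnsetConfig.exclude_inpatient_hba1c=False`
exempts it if desired). Same-day ties take the criterion listed first
(HbA1c > FPG > oral agent > insulin), a purely deterministic convention.

**Gestational exclusion.** Candidate onset events are discarded inside
[delivery − 9 months, delivery + 6 months] for every delivery, and inside
± 9 months of any pregnancy-related encounter (ICD-9 630–676) not already
covered by a delivery window — this second class catches aborted
pregnancies and deliveries outside the system. Delivery codes are matched
by chapter range 72–75, axis-agnostic, because recorded data may carry the
range on either the diagnosis or procedure axis. "Months" are calendar
months with end-of-month clamping (pandas `DateOffset`), not 30-day
blocks; the clinical phrasing is calendrical and the choice only moves
window edges by ≤ 2 days.

**Eligibility.** Onset within the enrolment window (2002-01-01 to
2015-12-31 by default, follow-up through 2016-12-31), age at diagnosis in
[1.5, 100] years (the lower bound excludes neonatal diabetes), binary
reference label. Age is exact day difference / 365.25. Exclusions are
applied in a fixed order (no onset → out of window → age → monogenic or
secondary → missing label) and counted in a ledger that sums to input
minus cohort size.

**Randomization.** The 2:1 derivation/validation split is an independent
per-person Bernoulli draw implemented as a blake2b hash of
`(seed, person_id)` mapped to [0, 1). This makes the assignment a pure
function of seed and identifier: machine-independent, stable under row
reordering, and exactly reproducible, at the cost of a binomially
distributed (not exact) split size. Nothing suggests the original split
was stratified, so ours is not.

## Classification rules

Rule evaluation is factored through a person-level feature frame (code
counts split principal/mixed; windowed prescription indicators for
windows 90/180/365 days and full follow-up). Conventions:

* Code counting runs from diagnosis date through `followup_end`
  (configurable); windowed prescription rules use start dates in the
  closed interval [diagnosis, diagnosis + w].
* Only insulin carries the 28-day duration minimum; other agents qualify
  with any duration.
* Ratio rules with zero type 2 codes are positive iff at least one type 1
  code exists. This is forced by internal consistency of the published
  candidate screen, where "ratio ≥ 0.5" and "at least one type 1 code"
  have identical sensitivity.
* MDI requires a long-acting and a short-acting prescription started
  within `mdi_coinit_days` of each other (default 31 ≈ "the same month"),
  both inside the rule's window. The two published footnotes describing
  co-initiation differ slightly ("same time frame" vs "same month"); the
  parameter reconciles them and both readings are reachable by config.
* "No other glucose-lowering medication" is scoped to the same window as
  the insulin requirement and checks prescriptions on/after diagnosis
  only. Widening the window can therefore *reduce* the positive set for
  these composite rules (more disqualifying co-prescriptions), which is
  why window monotonicity is asserted only for the plain
  "at least one insulin" family.

## Metrics

Exact intervals are Clopper–Pearson via beta quantiles, verified in tests
against an independent tail-sum bisection oracle for all x ≤ n ≤ 60 and
against `statsmodels`' beta method. Kappa uses the standard 2×2 closed
form; the degenerate p_e = 1 case returns 1.0 under perfect agreement.
PPV is reported "undefined" when no true positives were identified even
if false positives exist (matching the published convention for the
TP = 0, FP = 1 cell); `ppv_convention="standard"` instead reports 0/1 = 0
and reserves "undefined" for zero positive calls. Display rounding is
half-up (1 decimal for percentages, 2 for kappa); selection and all
internal comparisons use unrounded values. The moving-average proportion
curve evaluates a centered ±7.5-year window on a unit age grid (grid and
centering are a free choice; the published figures do not state them).

## Selection procedure

Per family (code, prescription), the most sensitive and the most
predictive candidates become A/C and B/D; the four winners are paired
into eight and/or combinations; among the twelve the arg-max by
sensitivity, PPV and kappa give the headline picks. Ties resolve by the
greatest sensitivity + PPV, then candidate order.

One point required a design decision: the published narrative treats the
two most sensitive prescription rules (59 vs 58 true cases) as tied and
applies the sum tie-break, while the code-rule pick is an exact tie. We
formalize this as: the top two candidates by sensitivity are *effectively
tied* when their true-positive counts differ by at most one case
(`near_tie_cases=1`), in which case the head-to-head sum decides. PPV and
kappa picks use exact ties only. This single rule reproduces all four
published single-rule picks and all three headline picks.

## Synthetic registry generator

The generator emulates the event structure the rules consume, under the
study conditions of the source registry's derivation cohort:

* **Types and ages.** T1D fraction 0.8 % (the validation cohort's true
  proportion); age at diagnosis truncated-normal per type, 22.7 (12.6)
  years for T1D and 55.9 (11.4) for T2D on [1.5, 100]; female fraction
  53.3 % / 43.9 %. The implied T1D-proportion-vs-age curve falls from
  ~50 % in childhood toward ~0 % in late adulthood.
* **Coding.** Per-type negative-binomial counts for type 1 and type 2
  codes, quantile-fitted to the published medians/IQRs (T1D: 3 (4) type 1,
  0 (1) type 2; T2D: 1 (3) type 2); the T2D type 1 count is a geometric
  fit to P(≥ 1 code) = 1.4 %. The exact family is a free choice — only
  median/IQR are published. Principal/mixed source is a binomial split
  (0.65 for type 1 codes, 0.5 for type 2), approximating the printed
  principal-code medians.
* **Prescriptions.** Per-type event probabilities default to the
  published conditional frequencies (insulin ever 98.3 %/33.6 %, insulin
  within 90 days 96.7 %/6.1 %, MDI 78.3 %/2.7 %, metformin
  36.7 %/88.6 %, other oral agents 16.7 %/75.7 % for T1D/T2D). A single
  uniform drives the nested insulin chain, so within-90-days ⊆ ever by
  construction; MDI is drawn conditionally on insulin use so its marginal
  is exact; infeasible nestings are rejected at config validation.
* **Severity coupling.** A per-person latent N(0,1) "severity" enters a
  Gaussian copula (ρ = 0.5 by default) for the type-concordant code count
  and the insulin chain. This induces the within-person correlation
  between coding intensity and prescribing that combination rules
  exploit, while copula marginals remain exactly the configured values —
  the joint distribution is not identified by any published quantity, so
  the coupling strength is an explicit modeling choice.
* **Supporting events.** Every person receives an onset-anchoring
  outpatient lab at the diagnosis date (70 % HbA1c / 30 % FPG by
  default); 10 % receive a pre-diagnosis inpatient glucose spike that
  must not trigger onset; 4 % of women receive a delivery ≥ 16 months
  after diagnosis (exercising the gestational machinery without
  disturbing the intended onset); background non-diabetes codes and
  sub-threshold insulin prescriptions are added as noise.

**What passing tests show — and don't.** Parameter recovery and pipeline
tests on this generator establish that the implementation is faithful to
its specification and that the qualitative phenomenology (sensitive but
non-predictive insulin rules at low prevalence, performance falling with
age at diagnosis) emerges from the configured marginals. They do not
establish real-world operating points: real registries have miscoding
correlated with care setting, treatment switching over time, incomplete
capture, and joint code/prescription structure no copula reproduces.
Published operating points are therefore checked through exact
reconstruction (constructive cohorts from the published confusion
matrices) rather than through the stochastic generator.

**Constructive cohorts.** `generate_from_matrix` builds tp+fp+fn+tn
persons from two archetypes: a positive archetype satisfying every
registry rule simultaneously (four type 1 codes, zero type 2, co-initiated
long/short insulin at day 10, no other agents) and a negative archetype
violating them all (one type 2 code, metformin only). Because the rule
algebra is monotone (and/or only), the same pair of archetypes realizes
any requested confusion matrix under any registry rule, which the
round-trip property test verifies for all twelve.

## Problem sizes

The default test suite uses a 4,000-person session-scoped registry for
distributional checks and 50,000 persons for the at-scale recovery and
property suite (one generation shared across tests); the acceptance
script likewise uses 50,000. At 0.8 % prevalence this yields ≈ 400 T1D
cases, enough to resolve every configured probability within the 3-SE
recovery bands. The full suite runs in well under a minute on one core.

## Known limitations

* Renal-function (eGFR-conditioned) rule variants and externally adapted
  algorithms are out of scope; eGFR is carried in the lab schema for
  completeness only.
* Reference labels are taken as given; no chart-review adjudication is
  modeled.
* The generator produces one prescription per drug-class decision rather
  than realistic refill longitudinality; duration fields matter only
  through the ≥ 28-day insulin filter.
* ICD-10 and free-text prescription mapping are not provided.
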