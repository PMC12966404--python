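# Methods

This document records the modeling choices behind `mobiward` precisely
enough to re-derive every number the package produces.

## 1. Day axis and cohort model

All times are integer days anchored at **therapy start = day 0**.
Admission happens at a non-positive offset (0 to −4). Intervals are closed
on both ends; a stay over `[start, end]` costs `end − start + 1` bed-days
(bd).

A `PatientTimeline` records: admission offset; regimen (high-dose
cyclophosphamide, 2 therapy days; etoposide + cyclophosphamide, 3 days;
etoposide alone, 4 days — the regimen fixes the therapy duration);
leukopenia onset/duration; stem cell collection (SCC) start (observed
window day 10–19), duration (1–3 days) and post-collection monitoring
days; adverse events; and covariates. Derived landmarks:

* `therapy_end_day = therapy_duration − 1`
* `scc_end_day = scc_start + scc_duration − 1`
* `discharge_day` — for successful collections, `scc_end + post_scc_days`,
  extended to the last hospitalization-requiring event onset if that is
  later; for failed collections, the last observed landmark (therapy end,
  leukopenia end, last event).

An adverse event is **severe** (SAE) when it requires in-hospital
management (`requires_hospitalization`); CTCAE grade rides along as data.
`first_sae_day` is the earliest hospitalizing onset. A patient is an
**early-SAE** patient when that onset falls in the half-open 72 h window
`[0, 3)` — days 0, 1, 2 — anchored at therapy start (an admission-anchored
variant is available). Event timing is bimodal by construction: onsets
occur in {0, 1, 2} or at day ≥ 5; days 3–4 are a forbidden gap for
hospitalizing events.

Models are pydantic v2, frozen, and validated on construction (regimen ↔
duration coupling, SCC window, leukopenia consistency, germ detection only
for neutropenic fever, unique patient ids).

## 2. Reference cohort from summary marginals

`fixture.default_constraints()` transcribes the published 109-patient
summary: regimen counts (55/44/10), admission offsets (day 0: 8, −1: 93,
−3: 8), leukopenia (100 patients; onset median 7, duration median 4, with
day-level refinement tables), SCC (106 successes over days 10–19, median
13; durations 1–3; post-collection 0–3 days), per-event onset summaries
(fever 59, median 9, range 1–12; transfusion 28, median 11, range 9–14;
renal impairment 12, median 10, range 1–14; nausea/diarrhea 24, median 4,
range 1–16), 26 germ detections, 1 admission-day acute kidney injury,
4 early-SAE patients, 75 patients with ≥ 1 SAE, 65 with CTCAE ≥ 3, and 81
with any adverse event. A validator rejects inconsistent constraint sets.

Three overlap counts are implied by inclusion–exclusion and fixed by the
constraints:

* fever ∩ transfusion = 59 + 28 + 1 − 65 = **23**
  (so |CTCAE ≥ 3| comes out at 65),
* renal impairment inside the CTCAE ≥ 3 union = 65 + 12 − 75 = **2**,
* nausea/diarrhea-only patients = 81 − 75 = **6**.

`onset_multiset` builds a deterministic integer multiset with an exact
count, median, minimum and maximum: pin the extremes once each, add
symmetric below/above pairs cycling through allowed days near the median,
fill the centre with median copies, and verify the result (raising
`InfeasibleConstraints` otherwise). Hospitalizing event types avoid the
forbidden days 3–4. A post-pass moves the required number of below-median
values to day 2 to realize the early-SAE quota without disturbing the
median.

`build_fixture_cohort` lays out patient roles greedily and
deterministically (fever patients in sorted onset order; transfusion
overlap assigned to febrile patients; renal-impairment overlap, the
admission-day AKI, and the "only" groups filled in), rank-matches SCC
start days to each patient's latest SAE onset so no hospitalizing event
postdates discharge, and uses the seed only for quantities the marginals
leave free (regimen/offset placement, post-collection days, germ flags,
covariate values). `verify_marginals` recounts every printed marginal —
including the coarse bins and medians — and reports pass/fail per row.

## 3. Synthetic cohort generator

`GeneratorParams` defaults are the study conditions (n = 109 scaled at
will). Occurrence uses a conditional scheme chosen at design time from the
overlap arithmetic above, so the per-type marginals stay at their stated
values while the union matches the observed any-SAE rate:

1. with probability 0.036 the patient is an early-SAE patient (index
   event fever / renal impairment / AKI at 50/25/25%, onset in {0, 1, 2});
2. otherwise fever occurs with the probability that restores the 0.54
   marginal; transfusion follows at 0.40 given fever, and at the rate that
   restores the 0.26 marginal given no fever; renal impairment occurs at
   0.032 given a prior severe event and at the complementary rate that
   restores the 0.11 marginal otherwise; nausea/diarrhea is independent at
   0.22 (non-hospitalizing).

The implied union is P(≥ 1 SAE) ≈ 0.692. Infeasible parameter
combinations (any implied branch probability outside [0, 1]) are rejected
at construction.

Onset days follow **shifted-binomial** models on the observed closed
supports, with the success probability solved so the distribution's median
equals the observed median; late-stratum severe onsets are clipped to
day ≥ 5, preserving the bimodal gap. Leukopenia, SCC timing, durations,
post-collection days, regimen and admission offsets are drawn from the
corresponding categorical/shifted-binomial models.

Covariates come from distributions typical of a myeloma mobilization
cohort. Two validation hooks are built in:

* **Planted effects** — log-odds slopes on occurrence or linear shifts on
  onset, applied to covariates centered at `COVARIATE_REFERENCE`, so a
  zero slope leaves rates untouched and recovery of a known signal can be
  tested.
* **Longitudinal drift** — day-3/5 lab panels drift from baseline
  (hemoglobin −0.9/−1.7 g/dL, platelets −70/−130 /nL), with extra
  creatinine rise in patients destined for renal impairment and CRP rise
  in patients destined for fever, scaled by `longitudinal_signal`.

Labs are missing completely at random at rate 0.005 per value.

## 4. Bed-day policy simulation

Scenario families (× sub-models X1/X2/X3):

* **current** — the observed course: one interval
  `[admission_offset, discharge_day]`.
* **day5** — admit everyone on day 5 unless an SAE occurred earlier;
  defined for X1/X2.
* **empirical** — admit at the first SAE onset.
* **worst / best** — empirical with every neutropenic fever onset shifted
  one day earlier (clipped at 0) / later.

Sub-model blocks: X1 adds an inpatient therapy block
`[0, therapy_end]`; X1 and X2 add an unconditional SCC block
`[scc_start, scc_end]`; X3 adds the SCC block only when a prior SAE
(onset < SCC start) already caused admission. Event-driven admissions run
to `discharge_day`; elective blocks end at the block end. Early-SAE
patients and failed collections stay fully inpatient in every scenario,
and outpatient-manageable event sets (supplementary variants) clear the
hospitalization requirement of the named event types before interval
construction. Intervals are merged (adjacent intervals coalesce) and
summed; components are split at therapy start and SCC end.

Totals are normalized against the current scenario. Uncertainty: the
percentile bootstrap resamples patients with replacement (default 2000
replicates) and recomputes **both** numerator and reference on each
resample; the 2.5th/97.5th percentiles of the ratio give the 95% CI.
Paired scenario contrasts use the two-sided Wilcoxon signed-rank test on
per-patient bed-days; independent group contrasts use Mann-Whitney U.

## 5. Two-step SAE prediction

Short-horizon complications have a genuine non-occurrence probability, so
instead of a survival model the task is split:

1. **Occurrence** — stratified 5-fold cross-validation; an inner 3-fold
   loop selects hyperparameters from small frozen grids (logistic
   regression, random forest, gradient boosting, XGBoost; a registry
   accepts plug-ins). Class imbalance is handled with balanced class or
   sample weights. Reported per model: accuracy, ROC-AUC and the Matthews
   correlation coefficient (computed from confusion counts; 0 on a zero
   marginal), averaged over outer folds.
2. **Onset** — for patients who develop the event, 3-fold cross-validated
   regression of the first qualifying onset day from admission-day
   features only (elastic net, random forest, gradient boosting, XGBoost),
   reported as MAD and RMSD in days.

Early-SAE patients are excluded from both steps (their admission is
decided clinically, inside the window the model is meant to cover), and
only events at or after day 3 count as positives. Feature sets: `clinical`
(7 admission variables), `mi_extended` (16, adding labs and engineered
features), `longitudinal` (30, adding day-3/5 panels). Engineered
features: CKD-EPI 2021 race-free eGFR and albumin-corrected calcium
(+0.8 mg/dL per g/dL below 4.0; calcium converted from mmol/L at × 4.008).
Missing labs are imputed by the running average over a patient's
admission/day-3/day-5 series, then by population column means.
`select_features_mi` ranks candidate features by quantile-binned mutual
information with the outcome. `TwoStepSAEPredictor` exposes the pair as a
scikit-learn estimator whose decision threshold trades missed admissions
against unnecessary ones.

## 6. Verification

The acceptance suite (`tests/test_acceptance.py`) checks, in order: exact
fixture marginal reproduction; scenario ordering (current ≥ day5 ≥ worst ≥
empirical ≥ best within matched sub-models, X1 ≥ X2 ≥ X3 within families)
and containment of every scenario interval in the observed interval; the
supplementary bound (empirical X3 with fever, transfusion and renal
impairment manageable as outpatient cuts bed-days by more than 90%);
equivalence of `bed_days` with a brute-force day-by-day occupancy count on
200 random small cohorts; ≈95% (±3%) bootstrap CI coverage over 200
replications of n = 109 against the generator-asymptotic fraction;
generator calibration at n = 10,000 (all rates within three binomial
standard deviations, no hospitalizing onsets on days 3–4); and ML sanity
(permuted-label AUC ≈ 0.5, planted-signal AUC > 0.7 at n = 500, MCC
agreement with scikit-learn on 1000 random confusion tables, and onset
MAD at the analytic noise floor σ·√(2/π) on pure-noise targets).
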