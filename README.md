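# mobiward

Ward-resource modeling for chemotherapy-based stem cell mobilization in
multiple myeloma.

Patients mobilized with chemotherapy plus G-CSF before autologous
transplantation are traditionally kept in hospital for the whole course —
roughly two and a half weeks — although most of that time passes without
any medical event. Severe adverse events (SAEs: CTCAE grade ≥ 3 or
requiring in-hospital management) cluster in two windows: a small early
group within 72 h of therapy start, and the main wave from day 5 onward,
with a silent gap over days 3–4. `mobiward` turns that timing structure
into quantitative decision support:

* **Cohort model** (`mobiward.cohort`) — validated, immutable patient
  timelines on a day axis anchored at therapy start (day 0): admission
  offset, regimen, leukopenia, stem cell collection (SCC), adverse events,
  baseline and longitudinal (day 3/5) laboratory covariates.
* **Reference cohort** (`mobiward.fixture`) — a deterministic 109-patient
  cohort reconstructed from published summary marginals (counts, medians,
  ranges, bin tables). Every marginal is reproduced exactly and re-checked
  by `verify_marginals`; the cohort is rebuilt from the constraint set at
  runtime rather than shipped as data.
* **Synthetic cohorts** (`mobiward.generator`) — a parametric generator
  whose defaults reproduce the reference cohort's event rates and onset
  distributions at scale, with optional planted covariate effects for
  method validation, lab drift linked to upcoming events, and configurable
  missingness.
* **Bed-day simulation** (`mobiward.bedsim`) — counterfactual admission
  policies (admit at first SAE, admit all on day 5, one-day
  pessimistic/optimistic onset shifts) crossed with sub-models keeping
  therapy and/or collection inpatient, plus outpatient-manageable event
  variants. Results are normalized against the observed full inpatient
  course with percentile-bootstrap confidence intervals and
  Wilcoxon/Mann-Whitney comparisons.
* **SAE prediction** (`mobiward.prediction`) — a two-step framework:
  cross-validated occurrence classification (accuracy, ROC-AUC, Matthews
  correlation; nested hyperparameter selection; class weighting) followed
  by onset-day regression (MAD/RMSD) for predicted-positive patients, with
  CKD-EPI 2021 eGFR, albumin-corrected calcium, and mutual-information
  feature ranking. `TwoStepSAEPredictor` packages both steps behind the
  scikit-learn estimator protocol.
* **CLI** (`mobiward.cli`) — `mobiward build-fixture / generate / simulate
  / predict / report / run-all`.

## Quickstart

```python
import mobiward as mw

# deterministic reference cohort, checked against its published marginals
cohort = mw.build_fixture_cohort(seed=0)
assert mw.verify_marginals(cohort).passed

# bed-day scenario grid with bootstrap 95% CIs
suite = mw.scenario_suite(cohort, n_boot=2000, seed=0)
print(suite[["scenario", "total_bd", "fraction", "ci_low", "ci_high"]])

# synthetic cohort at scale
big = mw.sample_cohort(mw.GeneratorParams(n_patients=10_000, seed=1))

# two-step SAE prediction
X, y, onsets = mw.make_ml_dataset(big, endpoint="any_sae", feature_set="clinical")
for report in mw.run_classification(X, y, seed=0):
    print(report.model_name, report.mean_roc_auc, report.mean_mcc)
est = mw.TwoStepSAEPredictor(threshold=0.5).fit(X, y, onsets)
```

Or from the shell:

```bash
mobiward build-fixture --out fixture.json
mobiward simulate fixture.json --n-boot 2000
mobiward generate --out synth.json --n 1000 --seed 1
mobiward predict synth.json --endpoint any_sae --feature-set mi_extended
mobiward run-all --out-dir results/ --source synthetic --n 500
```

## Scenario grid

| Label | Admission trigger | Fever-onset assumption | Therapy / SCC |
|-------|-------------------|------------------------|----------------|
| Current | full inpatient course | observed | inpatient |
| S51/S52 | day 5 (or earlier SAE) | observed | X1 / X2 |
| SW1/SW2 | first SAE | one day earlier | X1 / X2 |
| SE1–SE3 | first SAE | observed | X1 / X2 / X3 |
| SB1–SB3 | first SAE | one day later | X1 / X2 / X3 |

Sub-models: X1 keeps therapy and collection inpatient, X2 moves therapy
outpatient, X3 also moves collection outpatient unless an SAE already led
to admission. Early-SAE patients stay fully inpatient in every scenario.

## Testing

```bash
pytest -q                 # full suite, including acceptance criteria
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per release criterion (exact
fixture marginals, scenario ordering and interval containment, the >90%
outpatient-management bound, brute-force occupancy oracle equivalence,
bootstrap CI coverage, generator calibration at n = 10,000, and ML sanity
checks). See `docs/methods.md` for the underlying methodology and
`docs/cohort_schema.md` for the on-disk formats.
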