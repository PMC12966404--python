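# Cohort file formats

`mobiward.io` reads and writes cohorts in two lossless layouts. Round
trips preserve every field: `read_cohort(write_cohort(c)) == c`.

## JSON (single file)

The JSON layout mirrors the pydantic models:

```json
{
  "provenance": "fixture | synthetic | user",
  "seed": 0,
  "patients": [
    {
      "patient_id": "F001",
      "admission_offset": -1,
      "regimen": "cyclo_4000 | etoposide_cyclo | etoposide_alone",
      "therapy_duration_days": 2,
      "leukopenia_onset_day": 7,
      "leukopenia_duration_days": 4,
      "scc_start_day": 13,
      "scc_duration_days": 1,
      "scc_success": true,
      "post_scc_days": 1,
      "events": [
        {
          "event_type": "neutropenic_fever | mild_renal_impairment | transfusion | nausea_diarrhea | aki",
          "onset_day": 9,
          "ctcae_grade": 3,
          "requires_hospitalization": true,
          "germ_detected": true
        }
      ],
      "covariates": {
        "age_years": 63.0,
        "sex": "M | F",
        "creatinine_mg_dl": 0.9,
        "ldh_u_l": 210.0,
        "hemoglobin_g_dl": 11.2,
        "platelets_per_nl": 240.0,
        "crp_mg_l": 5.1,
        "calcium_mmol_l": 2.35,
        "albumin_g_dl": 4.1,
        "prior_ce_therapy": false,
        "prior_lines": 1,
        "full_dose_flag": true,
        "cyclo_flag": true,
        "ce_flag": false,
        "etoposide_flag": false,
        "gcsf_dose_flag": false,
        "longitudinal": {"3": {"crp_mg_l": 12.0}, "5": {"crp_mg_l": 30.0}}
      }
    }
  ]
}
```

Notes:

* All day fields are integers on the axis therapy start = day 0;
  `admission_offset` ∈ [−4, 0]; `onset_day` ∈ [−4, 30].
* `null` marks a missing lab value; `germ_detected` is only defined for
  neutropenic fever; `longitudinal` keys are restricted to days 3 and 5.
* Failed collections have `scc_success = false` and null SCC fields.

## CSV (linked pair)

`write_cohort(c, "cohort", format="csv")` produces
`cohort.patients.csv` and `cohort.events.csv`, keyed by `patient_id`.

`patients.csv` starts with a comment line carrying cohort metadata:

```
# mobiward-cohort provenance=synthetic seed=1
```

followed by one wide row per patient:

| column | type | notes |
|---|---|---|
| `patient_id` | str | unique |
| `admission_offset` | int | ≤ 0 |
| `regimen` | str | enum value |
| `therapy_duration_days` | int | fixed by regimen |
| `leukopenia_onset_day`, `leukopenia_duration_days` | int or empty | |
| `scc_start_day`, `scc_duration_days` | int or empty | |
| `scc_success` | 0/1 | |
| `post_scc_days` | int | |
| `age_years` | float | |
| `sex` | M/F | |
| `creatinine_mg_dl` … `albumin_g_dl` | float or empty | 7 lab columns |
| `prior_ce_therapy` … `gcsf_dose_flag` | 0/1 | 6 flag columns |
| `prior_lines` | int | |
| `day3_*`, `day5_*` | float or empty | longitudinal labs, 7 each |

`events.csv` is long, one row per adverse event:

| column | type |
|---|---|
| `patient_id` | str (must exist in the patients table) |
| `event_type` | enum value |
| `onset_day` | int |
| `ctcae_grade` | int or empty |
| `requires_hospitalization` | 0/1 |
| `germ_detected` | 0/1 or empty |

Readers validate the full schema: missing columns raise
`CohortSchemaError`, events referencing unknown patients or any timeline
invariant violation raise `CohortValidationError` naming the patient.
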