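"""Readers and writers for cohort files.

Two on-disk layouts are supported:

* **JSON** — a single file holding the whole cohort (schema mirrors the
  pydantic models; see ``docs/cohort_schema.md``).
* **CSV** — a linked pair ``<stem>.patients.csv`` / ``<stem>.events.csv``
  keyed by ``patient_id`` (UTF-8, comma-separated).  The patients table is
  wide (covariates flattened, longitudinal labs as ``day3_*`` / ``day5_*``
  columns); the events table is long.  Cohort-level provenance and seed
  ride in a comment line at the top of the patients file.

Round trips are lossless at field level: ``read_cohort(write_cohort(c)) == c``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import pandas as pd

from .cohort import (
    LAB_FIELDS,
    AdverseEventRecord,
    Cohort,
    CohortValidationError,
    CovariatePanel,
    LabPanel,
    PatientTimeline,
    Provenance,
    validate_patient,
)

__all__ = ["read_cohort", "write_cohort", "CohortSchemaError", "csv_pair_paths"]

_META_PREFIX = "# mobiward-cohort"

_PATIENT_INT_OPTIONAL = (
    "leukopenia_onset_day",
    "leukopenia_duration_days",
    "scc_start_day",
    "scc_duration_days",
)
_PATIENT_BOOL = ("scc_success",)
_COV_BOOL = (
    "prior_ce_therapy",
    "full_dose_flag",
    "cyclo_flag",
    "ce_flag",
    "etoposide_flag",
    "gcsf_dose_flag",
)

_PATIENT_COLUMNS = (
    ["patient_id", "admission_offset", "regimen", "therapy_duration_days"]
    + list(_PATIENT_INT_OPTIONAL)
    + ["scc_success", "post_scc_days", "age_years", "sex"]
    + list(LAB_FIELDS)
    + list(_COV_BOOL)
    + ["prior_lines"]
    + [f"day{d}_{f}" for d in (3, 5) for f in LAB_FIELDS]
)

_EVENT_COLUMNS = [
    "patient_id",
    "event_type",
    "onset_day",
    "ctcae_grade",
    "requires_hospitalization",
    "germ_detected",
]


class CohortSchemaError(ValueError):
    """A required column or file is missing from a cohort table."""


def csv_pair_paths(path: str | Path) -> tuple[Path, Path]:
    """Return the (patients, events) file pair for a CSV cohort stem."""
    stem = Path(path)
    if stem.suffix == ".csv":
        stem = stem.with_suffix("")
    return stem.with_suffix(".patients.csv"), stem.with_suffix(".events.csv")


# ---------------------------------------------------------------------------
# writing


def _flatten_patient(p: PatientTimeline) -> dict:
    row: dict = {
        "patient_id": p.patient_id,
        "admission_offset": p.admission_offset,
        "regimen": p.regimen.value,
        "therapy_duration_days": p.therapy_duration_days,
        "scc_success": int(p.scc_success),
        "post_scc_days": p.post_scc_days,
    }
    for f in _PATIENT_INT_OPTIONAL:
        row[f] = getattr(p, f)
    cov = p.covariates
    row["age_years"] = cov.age_years
    row["sex"] = cov.sex.value
    for f in LAB_FIELDS:
        row[f] = getattr(cov, f)
    for f in _COV_BOOL:
        row[f] = int(getattr(cov, f))
    row["prior_lines"] = cov.prior_lines
    for day in (3, 5):
        panel = cov.longitudinal.get(day)
        for f in LAB_FIELDS:
            row[f"day{day}_{f}"] = getattr(panel, f) if panel is not None else None
    return row


def write_cohort(cohort: Cohort, path: str | Path, format: str = "json") -> None:
    """Persist a cohort as JSON or as the CSV pair."""
    path = Path(path)
    if format == "json":
        payload = cohort.model_dump(mode="json")
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    ppath, epath = csv_pair_paths(path)
    pat = pd.DataFrame([_flatten_patient(p) for p in cohort.patients], columns=_PATIENT_COLUMNS)
    ev_rows = []
    for p in cohort.patients:
        for e in p.events:
            ev_rows.append(
                {
                    "patient_id": p.patient_id,
                    "event_type": e.event_type.value,
                    "onset_day": e.onset_day,
                    "ctcae_grade": e.ctcae_grade,
                    "requires_hospitalization": int(e.requires_hospitalization),
                    "germ_detected": None if e.germ_detected is None else int(e.germ_detected),
                }
            )
    ev = pd.DataFrame(ev_rows, columns=_EVENT_COLUMNS)

    meta = f"{_META_PREFIX} provenance={cohort.provenance.value} seed={cohort.seed}\n"
    with open(ppath, "w", encoding="utf-8", newline="") as fh:
        fh.write(meta)
        pat.to_csv(fh, index=False)
    ev.to_csv(epath, index=False)


# ---------------------------------------------------------------------------
# reading


def _cell(value):
    """Normalize a pandas cell to a plain python value (NaN -> None)."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if pd.isna(value):
        return None
    return value


def _opt_int(value) -> Optional[int]:
    v = _cell(value)
    return None if v is None else int(v)


def _opt_float(value) -> Optional[float]:
    v = _cell(value)
    return None if v is None else float(v)


def _require_columns(df: pd.DataFrame, needed, table: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{table} table is missing column(s): {missing}")


def _row_to_patient(row: pd.Series, events: list[AdverseEventRecord]) -> PatientTimeline:
    longitudinal = {}
    for day in (3, 5):
        vals = {f: _opt_float(row[f"day{day}_{f}"]) for f in LAB_FIELDS}
        if any(v is not None for v in vals.values()):
            longitudinal[day] = LabPanel(**vals)
    cov = CovariatePanel(
        age_years=float(row["age_years"]),
        sex=row["sex"],
        prior_lines=int(row["prior_lines"]),
        longitudinal=longitudinal,
        **{f: _opt_float(row[f]) for f in LAB_FIELDS},
        **{f: bool(int(row[f])) for f in _COV_BOOL},
    )
    data = {
        "patient_id": str(row["patient_id"]),
        "admission_offset": int(row["admission_offset"]),
        "regimen": row["regimen"],
        "therapy_duration_days": int(row["therapy_duration_days"]),
        "scc_success": bool(int(row["scc_success"])),
        "post_scc_days": int(row["post_scc_days"]),
        "events": events,
        "covariates": cov,
    }
    for f in _PATIENT_INT_OPTIONAL:
        data[f] = _opt_int(row[f])
    return validate_patient(data)


def _read_csv_pair(path: Path) -> Cohort:
    ppath, epath = csv_pair_paths(path)
    for f in (ppath, epath):
        if not f.exists():
            raise FileNotFoundError(f)

    provenance, seed = Provenance.user, None
    with open(ppath, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith(_META_PREFIX):
        for token in first[len(_META_PREFIX):].split():
            key, _, val = token.partition("=")
            if key == "provenance":
                provenance = Provenance(val)
            elif key == "seed" and val != "None":
                seed = int(val)

    pat = pd.read_csv(ppath, comment="#", dtype={"patient_id": str})
    ev = pd.read_csv(epath, dtype={"patient_id": str})
    _require_columns(pat, _PATIENT_COLUMNS, "patients")
    _require_columns(ev, _EVENT_COLUMNS, "events")

    events_by_pid: dict[str, list[AdverseEventRecord]] = {}
    for _, row in ev.iterrows():
        germ = _opt_int(row["germ_detected"])
        rec = AdverseEventRecord(
            event_type=row["event_type"],
            onset_day=int(row["onset_day"]),
            ctcae_grade=_opt_int(row["ctcae_grade"]),
            requires_hospitalization=bool(int(row["requires_hospitalization"])),
            germ_detected=None if germ is None else bool(germ),
        )
        events_by_pid.setdefault(str(row["patient_id"]), []).append(rec)

    unknown = set(events_by_pid) - set(pat["patient_id"].astype(str))
    if unknown:
        raise CohortValidationError(f"events reference unknown patient_ids: {sorted(unknown)}")

    patients = [
        _row_to_patient(row, events_by_pid.get(str(row["patient_id"]), []))
        for _, row in pat.iterrows()
    ]
    return Cohort(patients=patients, provenance=provenance, seed=seed)


def read_cohort(path: str | Path, format: Optional[str] = None) -> Cohort:
    """Load and validate a cohort from disk.

    ``format`` defaults to "json" for ``*.json`` paths and "csv" otherwise.
    Raises :class:`CohortSchemaError` for missing columns and
    :class:`~mobiward.cohort.CohortValidationError` (naming the patient)
    for invariant violations.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        if "patients" not in payload:
            raise CohortSchemaError("JSON cohort lacks a 'patients' field")
        patients = [validate_patient(p) for p in payload["patients"]]
        return Cohort(
            patients=patients,
            provenance=payload.get("provenance", "user"),
            seed=payload.get("seed"),
        )
    if format == "csv":
        return _read_csv_pair(path)
    raise ValueError(f"unknown format {format!r}")
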