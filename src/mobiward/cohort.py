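"""Domain model for stem-cell-mobilization patient timelines.

Every patient course lives on an integer day axis anchored at the start of
mobilization chemotherapy (day 0).  Admission happens at a non-positive
offset, leukopenia and stem-cell collection (SCC) follow during the second
week, and adverse events carry their onset day on the same axis.  Severe
adverse events (SAEs) are events requiring in-hospital management (CTCAE
grade >= 3 or an explicit hospitalization trigger such as neutropenic fever,
creatinine > 1.2 mg/dL with IV-fluid support, or transfusion need).

No operation in this package accepts calendar dates.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "EventType",
    "Regimen",
    "Sex",
    "Provenance",
    "AdverseEventRecord",
    "LabPanel",
    "CovariatePanel",
    "PatientTimeline",
    "Cohort",
    "CohortValidationError",
    "REGIMEN_DURATION_DAYS",
    "first_sae_day",
    "is_early_sae",
]

#: Therapy duration implied by each mobilization regimen (days of infusion).
REGIMEN_DURATION_DAYS = {
    "cyclo_4000": 2,
    "etoposide_cyclo": 3,
    "etoposide_alone": 4,
}

#: Names of the laboratory analytes carried at baseline and on days 3/5.
LAB_FIELDS = (
    "creatinine_mg_dl",
    "ldh_u_l",
    "hemoglobin_g_dl",
    "platelets_per_nl",
    "crp_mg_l",
    "calcium_mmol_l",
    "albumin_g_dl",
)


class EventType(str, enum.Enum):
    neutropenic_fever = "neutropenic_fever"
    mild_renal_impairment = "mild_renal_impairment"
    transfusion = "transfusion"
    nausea_diarrhea = "nausea_diarrhea"
    aki = "aki"


class Regimen(str, enum.Enum):
    cyclo_4000 = "cyclo_4000"
    etoposide_cyclo = "etoposide_cyclo"
    etoposide_alone = "etoposide_alone"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Provenance(str, enum.Enum):
    fixture = "fixture"
    synthetic = "synthetic"
    user = "user"


class CohortValidationError(ValueError):
    """Invariant violation, annotated with the offending patient id."""


class AdverseEventRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    event_type: EventType
    onset_day: int = Field(ge=-4, le=30)
    ctcae_grade: Optional[int] = Field(default=None, ge=1, le=5)
    requires_hospitalization: bool = False
    germ_detected: Optional[bool] = None  # fever only

    @model_validator(mode="after")
    def _germ_only_for_fever(self) -> "AdverseEventRecord":
        if self.germ_detected is not None and self.event_type is not EventType.neutropenic_fever:
            raise ValueError("germ_detected is only defined for neutropenic fever events")
        return self


class LabPanel(BaseModel):
    """One panel of blood values; ``None`` marks a missing measurement."""

    model_config = ConfigDict(frozen=True)

    creatinine_mg_dl: Optional[float] = Field(default=None, gt=0)
    ldh_u_l: Optional[float] = Field(default=None, gt=0)
    hemoglobin_g_dl: Optional[float] = Field(default=None, gt=0)
    platelets_per_nl: Optional[float] = Field(default=None, gt=0)
    crp_mg_l: Optional[float] = Field(default=None, gt=0)
    calcium_mmol_l: Optional[float] = Field(default=None, gt=0)
    albumin_g_dl: Optional[float] = Field(default=None, gt=0)


class CovariatePanel(BaseModel):
    model_config = ConfigDict(frozen=True)

    age_years: float = Field(gt=0)
    sex: Sex
    creatinine_mg_dl: Optional[float] = Field(default=None, gt=0)
    ldh_u_l: Optional[float] = Field(default=None, gt=0)
    hemoglobin_g_dl: Optional[float] = Field(default=None, gt=0)
    platelets_per_nl: Optional[float] = Field(default=None, gt=0)
    crp_mg_l: Optional[float] = Field(default=None, gt=0)
    calcium_mmol_l: Optional[float] = Field(default=None, gt=0)
    albumin_g_dl: Optional[float] = Field(default=None, gt=0)
    prior_ce_therapy: bool = False
    prior_lines: int = Field(default=1, ge=0)
    full_dose_flag: bool = False
    cyclo_flag: bool = False
    ce_flag: bool = False
    etoposide_flag: bool = False
    gcsf_dose_flag: bool = False
    #: day (3 or 5) -> longitudinal blood panel
    longitudinal: dict[int, LabPanel] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _longitudinal_days(self) -> "CovariatePanel":
        bad = set(self.longitudinal) - {3, 5}
        if bad:
            raise ValueError(f"longitudinal panels only defined for days 3 and 5, got {sorted(bad)}")
        return self


class PatientTimeline(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    admission_offset: int = Field(le=0, ge=-4)
    regimen: Regimen
    therapy_duration_days: int = Field(ge=2, le=4)
    leukopenia_onset_day: Optional[int] = Field(default=None, ge=0)
    leukopenia_duration_days: Optional[int] = Field(default=None, ge=1)
    scc_start_day: Optional[int] = Field(default=None, ge=0)
    scc_duration_days: Optional[int] = Field(default=None, ge=1, le=3)
    scc_success: bool = False
    post_scc_days: int = Field(default=0, ge=0)
    events: tuple[AdverseEventRecord, ...] = ()
    covariates: CovariatePanel

    @model_validator(mode="after")
    def _invariants(self) -> "PatientTimeline":
        expected = REGIMEN_DURATION_DAYS[self.regimen.value]
        if self.therapy_duration_days != expected:
            raise ValueError(
                f"regimen {self.regimen.value} implies therapy_duration_days={expected}, "
                f"got {self.therapy_duration_days}"
            )
        if self.scc_success:
            if self.scc_start_day is None:
                raise ValueError("scc_success requires scc_start_day")
            if not 10 <= self.scc_start_day <= 19:
                raise ValueError(
                    f"scc_start_day {self.scc_start_day} outside the observed window [10, 19]"
                )
        if self.leukopenia_duration_days is not None and self.leukopenia_onset_day is None:
            raise ValueError("leukopenia_duration_days present without leukopenia_onset_day")
        return self

    # -- derived day-axis landmarks -------------------------------------

    @property
    def therapy_end_day(self) -> int:
        return self.therapy_duration_days - 1

    @property
    def scc_end_day(self) -> Optional[int]:
        if self.scc_start_day is None or self.scc_duration_days is None:
            return None
        return self.scc_start_day + self.scc_duration_days - 1

    @property
    def leukopenia_end_day(self) -> Optional[int]:
        if self.leukopenia_onset_day is None:
            return None
        return self.leukopenia_onset_day + (self.leukopenia_duration_days or 1) - 1

    @property
    def discharge_day(self) -> int:
        """Last observed inpatient day under the full inpatient course.

        Successful collections: SCC end plus the observed post-collection
        days, extended if a hospitalizing event occurred even later.  Failed
        collections: the last observed landmark (therapy end, leukopenia
        end, last event).
        """
        hosp_onsets = [e.onset_day for e in self.events if e.requires_hospitalization]
        if self.scc_end_day is not None:
            end = self.scc_end_day + self.post_scc_days
        else:
            end = self.therapy_end_day
            if self.leukopenia_end_day is not None:
                end = max(end, self.leukopenia_end_day)
            if self.events:
                end = max(end, max(e.onset_day for e in self.events))
        if hosp_onsets:
            end = max(end, max(hosp_onsets))
        return end


class Cohort(BaseModel):
    model_config = ConfigDict(frozen=True)

    patients: tuple[PatientTimeline, ...] = Field(min_length=1)
    provenance: Provenance = Provenance.user
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _unique_ids(self) -> "Cohort":
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids: {dupes}")
        return self

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def first_sae_day(patient: PatientTimeline) -> Optional[int]:
    """Onset day of the first hospitalization-requiring adverse event.

    Returns ``None`` when the patient never required event-driven
    hospitalization.  Invariant to the ordering of the event list.
    """
    days = [e.onset_day for e in patient.events if e.requires_hospitalization]
    return min(days) if days else None


def is_early_sae(
    patient: PatientTimeline,
    window_days: int = 3,
    anchor: str = "therapy_start",
) -> bool:
    """Whether the first SAE fell inside the early (72 h) window.

    The window is half-open on integer days: with the default
    ``window_days=3`` anchored at therapy start, onset days 0, 1 and 2
    count as early.  ``anchor="admission"`` instead measures the window
    from the admission day (onset day minus admission offset), for centers
    admitting more than a day before therapy.
    """
    day = first_sae_day(patient)
    if day is None:
        return False
    if anchor == "therapy_start":
        rel = day
    elif anchor == "admission":
        rel = day - patient.admission_offset
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return rel < window_days


def validate_patient(data: dict) -> PatientTimeline:
    """Build a PatientTimeline, re-raising with the patient id attached."""
    pid = data.get("patient_id", "<missing id>")
    try:
        return PatientTimeline.model_validate(data)
    except (ValidationError, ValueError) as exc:
        raise CohortValidationError(f"patient {pid!r}: {exc}") from exc
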