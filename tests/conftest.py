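import pytest

from mobiward.cohort import (
    AdverseEventRecord,
    CovariatePanel,
    EventType,
    PatientTimeline,
)
from mobiward.fixture import build_fixture_cohort
from mobiward.generator import GeneratorParams, sample_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_fixture_cohort(seed=0)


@pytest.fixture(scope="session")
def synth_cohort():
    return sample_cohort(GeneratorParams(n_patients=300, seed=3))


def make_patient(
    patient_id="P1",
    admission_offset=-1,
    regimen="cyclo_4000",
    therapy_duration_days=2,
    events=(),
    scc_start_day=12,
    scc_duration_days=1,
    scc_success=True,
    post_scc_days=1,
    **kwargs,
):
    """A small valid patient timeline for hand-built test cases."""
    return PatientTimeline(
        patient_id=patient_id,
        admission_offset=admission_offset,
        regimen=regimen,
        therapy_duration_days=therapy_duration_days,
        leukopenia_onset_day=kwargs.pop("leukopenia_onset_day", 7),
        leukopenia_duration_days=kwargs.pop("leukopenia_duration_days", 4),
        scc_start_day=scc_start_day,
        scc_duration_days=scc_duration_days,
        scc_success=scc_success,
        post_scc_days=post_scc_days,
        events=tuple(events),
        covariates=kwargs.pop("covariates", CovariatePanel(age_years=60, sex="M")),
        **kwargs,
    )


def sae(day, event_type=EventType.neutropenic_fever, grade=3, **kw):
    return AdverseEventRecord(
        event_type=event_type, onset_day=day, ctcae_grade=grade,
        requires_hospitalization=True, **kw,
    )
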