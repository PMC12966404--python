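"""Hospital bed-day simulation of admission policies for mobilization courses.

Each patient timeline is mapped through a *scenario* — an admission policy —
to a set of hospitalization intervals on the day axis, and bed-days (bd; one
bed occupied by one patient for one day) are aggregated with a component
breakdown and bootstrap confidence intervals.

Scenario families
-----------------
``current``
    The observed full inpatient course: one interval from admission to
    discharge.  Serves as the normalization reference.
``day5``
    Outpatient start with a fixed admission on day 5 after therapy start
    for everyone who has not had an early (72 h) severe event — the policy
    enabled by the bimodal onset gap.  A severe event before day 5 admits
    at its onset.
``empirical`` / ``worst`` / ``best``
    Admission at the first severe-event onset, with the neutropenic-fever
    onset distribution used as observed, shifted one day earlier, or one
    day later, respectively.  Only the onset moves; the event *rates* and
    the early-SAE / kidney-injury / transfusion quotas stay fixed.

Sub-models: ``X1`` keeps therapy administration inpatient (a block covering
the infusion days), ``X2`` moves therapy out, and both keep stem-cell
collection (SCC) inpatient regardless of severe events; ``X3`` performs the
collection as an outpatient procedure unless the patient was already
hospitalized before it.

Conventions: intervals are closed on integer days, with length
``end - start + 1`` (admission and discharge days both occupy a bed).
Early-SAE patients and failed collections follow the observed inpatient
course in every scenario.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, EventType, PatientTimeline, first_sae_day, is_early_sae

__all__ = [
    "ScenarioSpec",
    "HospitalizationIntervals",
    "BedDayResult",
    "SCENARIO_LABELS",
    "scenario_from_label",
    "apply_scenario_events",
    "hospitalization_intervals",
    "bed_days",
    "normalize",
    "bootstrap_ci",
    "compare_scenarios",
    "compare_groups",
    "scenario_suite",
]

_FAMILIES = ("current", "day5", "worst", "empirical", "best")
_NF_SHIFT = {"worst": -1, "best": +1}

#: The published scenario grid: family x sub-model.
SCENARIO_LABELS = ("Current", "S51", "S52", "SW1", "SW2",
                   "SE1", "SE2", "SE3", "SB1", "SB2", "SB3")

_LABEL_FAMILY = {"S5": "day5", "SW": "worst", "SE": "empirical", "SB": "best"}


@dataclass(frozen=True)
class ScenarioSpec:
    family: str
    submodel: Optional[str] = None  # "X1" | "X2" | "X3"; None for current
    outpatient_manageable: frozenset[EventType] = frozenset()
    label: str = ""

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown scenario family {self.family!r}")
        if self.family == "current":
            if self.submodel is not None or self.outpatient_manageable:
                raise ValueError("the current (observed) scenario takes no sub-model "
                                 "or outpatient-management flags")
        else:
            if self.submodel not in ("X1", "X2", "X3"):
                raise ValueError(f"sub-model must be X1/X2/X3, got {self.submodel!r}")
            if self.family == "day5" and self.submodel == "X3":
                raise ValueError("the day-5 admission family is defined for X1/X2 only")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.family == "current":
            return "Current"
        prefix = {v: k for k, v in _LABEL_FAMILY.items()}[self.family]
        lab = prefix + self.submodel[-1]
        if self.outpatient_manageable:
            lab += "+out[" + ",".join(sorted(e.value for e in self.outpatient_manageable)) + "]"
        return lab

    @property
    def nf_shift_days(self) -> int:
        return _NF_SHIFT.get(self.family, 0)

    @property
    def fixed_admission_day(self) -> Optional[int]:
        return 5 if self.family == "day5" else None


def scenario_from_label(label: str, outpatient: Sequence[EventType] = ()) -> ScenarioSpec:
    """Parse a grid label ("Current", "SE2", "SB3", ...) into a spec."""
    if label.lower() == "current":
        return ScenarioSpec(family="current")
    family = _LABEL_FAMILY.get(label[:2].upper())
    if family is None or len(label) != 3 or label[2] not in "123":
        raise ValueError(f"unknown scenario label {label!r}")
    return ScenarioSpec(
        family=family,
        submodel=f"X{label[2]}",
        outpatient_manageable=frozenset(EventType(e) for e in outpatient),
    )


@dataclass(frozen=True)
class HospitalizationIntervals:
    """Merged, sorted closed day intervals and the policy trigger."""

    intervals: tuple[tuple[int, int], ...]
    trigger: str  # full_inpatient | early_sae | sae | day5_policy | scc_block | therapy_block | none

    @property
    def bed_days(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass
class BedDayResult:
    label: str
    total_bd: int
    component_bd: dict[str, int]
    per_patient_bd: list[int]
    normalized_fraction: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if sum(self.component_bd.values()) != self.total_bd:
            raise ValueError("component bed-days do not sum to the total")


# ---------------------------------------------------------------------------
# per-patient policy


def apply_scenario_events(patient: PatientTimeline, spec: ScenarioSpec) -> PatientTimeline:
    """Return a copy with the scenario's event modifications applied.

    Fever onsets shift by the family's one-day assumption (clipped at
    day 0); events flagged outpatient-manageable lose their
    hospitalization requirement.  All other events — and the entire
    timeline of early-SAE patients, whose quota every scenario holds
    constant — are untouched.
    """
    if spec.family == "current" or is_early_sae(patient):
        return patient
    if spec.nf_shift_days == 0 and not spec.outpatient_manageable:
        return patient
    new_events = []
    for e in patient.events:
        changes = {}
        if e.event_type is EventType.neutropenic_fever and spec.nf_shift_days:
            changes["onset_day"] = max(0, e.onset_day + spec.nf_shift_days)
        if e.event_type in spec.outpatient_manageable:
            changes["requires_hospitalization"] = False
        new_events.append(e.model_copy(update=changes) if changes else e)
    return patient.model_copy(update={"events": tuple(new_events)})


def _merge(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return tuple(out)


def hospitalization_intervals(patient: PatientTimeline, spec: ScenarioSpec) -> HospitalizationIntervals:
    """Map one (scenario-modified) timeline to hospitalization intervals."""
    t_end = patient.discharge_day
    full = ((patient.admission_offset, t_end),)

    if spec.family == "current":
        return HospitalizationIntervals(intervals=full, trigger="full_inpatient")
    if is_early_sae(patient):
        return HospitalizationIntervals(intervals=full, trigger="early_sae")
    if not patient.scc_success:
        # failed collections have no described outpatient pathway
        return HospitalizationIntervals(intervals=full, trigger="full_inpatient")

    t_sae = first_sae_day(patient)
    t_scc = patient.scc_start_day
    scc_end = patient.scc_end_day

    intervals: list[tuple[int, int]] = []
    trigger = "none"
    if t_sae is not None:
        intervals.append((t_sae, max(t_sae, t_end)))
        trigger = "sae"
    if spec.fixed_admission_day is not None and (t_sae is None or t_sae > spec.fixed_admission_day):
        intervals.append((spec.fixed_admission_day, t_end))
        trigger = "day5_policy"

    # sub-model inpatient blocks for therapy administration and collection
    if spec.submodel == "X1":
        intervals.append((0, patient.therapy_end_day))
        if trigger == "none":
            trigger = "therapy_block"
    scc_block = (t_scc, scc_end) if t_scc is not None else None
    if scc_block is not None:
        if spec.submodel in ("X1", "X2"):
            intervals.append(scc_block)
            if trigger == "none":
                trigger = "scc_block"
        elif spec.submodel == "X3" and t_sae is not None and t_sae < t_scc:
            intervals.append(scc_block)

    # post-collection days accrue only through the admission intervals above,
    # which run to discharge; elective therapy/SCC blocks end at the block end,
    # so a patient whose bed at SCC end is elective-only leaves at SCC end.
    return HospitalizationIntervals(intervals=_merge(intervals), trigger=trigger)


# ---------------------------------------------------------------------------
# aggregation


def _components(patient: PatientTimeline, iv: HospitalizationIntervals) -> tuple[int, int, int]:
    """Split one patient's bed-days at therapy start and SCC end."""
    scc_end = patient.scc_end_day
    pre = mid = post = 0
    for s, e in iv.intervals:
        for d in range(s, e + 1):
            if d < 0:
                pre += 1
            elif scc_end is not None and d > scc_end:
                post += 1
            else:
                mid += 1
    return pre, mid, post


def bed_days(cohort: Cohort, spec: ScenarioSpec) -> BedDayResult:
    """Total and per-patient bed-days for one scenario on a cohort."""
    per_patient, pre_t, mid_t, post_t = [], 0, 0, 0
    for p in cohort.patients:
        mod = apply_scenario_events(p, spec)
        iv = hospitalization_intervals(mod, spec)
        per_patient.append(iv.bed_days)
        pre, mid, post = _components(mod, iv)
        pre_t, mid_t, post_t = pre_t + pre, mid_t + mid, post_t + post
    return BedDayResult(
        label=spec.label,
        total_bd=sum(per_patient),
        component_bd={"pre_therapy": pre_t, "therapy_to_scc": mid_t, "post_scc": post_t},
        per_patient_bd=per_patient,
    )


def normalize(result: BedDayResult, reference_current: BedDayResult) -> BedDayResult:
    """Fill in the bed-day fraction relative to the observed inpatient course."""
    if reference_current.total_bd <= 0:
        raise ValueError("reference scenario has zero bed-days")
    out = dataclasses.replace(result)
    out.normalized_fraction = result.total_bd / reference_current.total_bd
    return out


def bootstrap_ci(
    cohort: Cohort,
    spec: ScenarioSpec,
    n_boot: int = 2000,
    seed: int = 0,
    reference: Optional[ScenarioSpec] = None,
) -> tuple[float, float]:
    """Percentile 95% CI of the normalized bed-day fraction.

    Patients are resampled with replacement; the reference (observed
    inpatient) total is recomputed on the same resample in each replicate.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    reference = reference or ScenarioSpec(family="current")
    a = np.asarray(bed_days(cohort, spec).per_patient_bd, dtype=float)
    c = np.asarray(bed_days(cohort, reference).per_patient_bd, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(a), size=(n_boot, len(a)))
    denom = c[idx].sum(axis=1)
    denom[denom == 0] = np.nan
    fracs = a[idx].sum(axis=1) / denom
    lo, hi = np.nanpercentile(fracs, [2.5, 97.5])
    return float(lo), float(hi)


def compare_scenarios(cohort: Cohort, spec_a: ScenarioSpec, spec_b: ScenarioSpec) -> dict:
    """Paired two-sided Wilcoxon signed-rank test on per-patient bed-days."""
    a = np.asarray(bed_days(cohort, spec_a).per_patient_bd, dtype=float)
    b = np.asarray(bed_days(cohort, spec_b).per_patient_bd, dtype=float)
    diff = a - b
    if np.all(diff == 0):
        statistic, pvalue = 0.0, 1.0
    else:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    return {
        "test": "wilcoxon_signed_rank",
        "statistic": statistic,
        "p_value": pvalue,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n": len(a),
    }


def compare_groups(bd_group_a: Sequence[float], bd_group_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U for independent groups (e.g. early vs rest)."""
    res = stats.mannwhitneyu(bd_group_a, bd_group_b, alternative="two-sided")
    return {
        "test": "mann_whitney_u",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_a": float(np.median(bd_group_a)),
        "median_b": float(np.median(bd_group_b)),
    }


def scenario_suite(
    cohort: Cohort,
    n_boot: int = 2000,
    seed: int = 0,
    extra_scenarios: Sequence[ScenarioSpec] = (),
) -> pd.DataFrame:
    """Evaluate the full scenario grid (plus any supplementary variants).

    Returns a tidy table with one row per scenario: total and component
    bed-days, the fraction normalized against the observed course, and the
    bootstrap 95% CI of that fraction.
    """
    specs = [scenario_from_label(lab) for lab in SCENARIO_LABELS]
    specs.extend(extra_scenarios)
    reference = bed_days(cohort, specs[0])
    rows = []
    for spec in specs:
        res = normalize(bed_days(cohort, spec), reference)
        lo, hi = bootstrap_ci(cohort, spec, n_boot=n_boot, seed=seed)
        rows.append({
            "scenario": spec.label,
            "family": spec.family,
            "submodel": spec.submodel or "-",
            "total_bd": res.total_bd,
            "pre_therapy_bd": res.component_bd["pre_therapy"],
            "therapy_to_scc_bd": res.component_bd["therapy_to_scc"],
            "post_scc_bd": res.component_bd["post_scc"],
            "fraction": res.normalized_fraction,
            "ci_low": lo,
            "ci_high": hi,
        })
    return pd.DataFrame(rows)
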