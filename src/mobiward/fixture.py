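"""Deterministic reconstruction of the study cohort from published marginals.

Patient-level data for the mobilization cohort are not public; what is
published is a set of marginal summaries (cohort size, regimen counts,
per-event patient counts, onset medians and ranges, leukopenia and
collection timing bins, SAE counts).  This module transcribes those
marginals into a :class:`MarginalConstraints` object and builds a concrete
109-patient cohort that satisfies every one of them **exactly**, so the
bed-day simulator and reporting code can run against a realistic-shaped,
fully reproducible stand-in.

The joint structure (which patients co-experience which events, who gets
which collection date) is under-determined by the marginals.  Assignment is
greedy and deterministic: patients are laid out in a fixed role order
(fever patients first, then transfusion-only, the kidney-injury patient,
renal-impairment-only, nausea/diarrhea-only, event-free), overlaps are
sized so the any-SAE and CTCAE>=3 unions come out exactly, and collection
dates are rank-matched to each patient's latest severe-event onset so that
no inpatient-triggering event postdates discharge.  Realism beyond the
marginals is the job of :mod:`mobiward.generator`, not of this fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .cohort import (
    AdverseEventRecord,
    Cohort,
    EventType,
    PatientTimeline,
    Provenance,
    first_sae_day,
    is_early_sae,
)
from .generator import sample_covariate_panels

__all__ = [
    "OnsetSummary",
    "MarginalConstraints",
    "InfeasibleConstraints",
    "default_constraints",
    "build_fixture_cohort",
    "verify_marginals",
    "MarginalReport",
]


class InfeasibleConstraints(ValueError):
    """The requested marginal combination cannot be realized."""


class OnsetSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    count: int
    median: float
    min: int
    max: int

    @model_validator(mode="after")
    def _ordered(self) -> "OnsetSummary":
        if not self.min <= self.median <= self.max:
            raise ValueError(f"onset summary not ordered: {self}")
        return self


class MarginalConstraints(BaseModel):
    """Printed cohort marginals plus the day-level refinements used to meet them.

    The ``*_days`` maps are day -> patient count.  They are a deterministic
    refinement of the published bins; the published bins and medians are
    derived from them and re-checked by :func:`verify_marginals`.
    """

    model_config = ConfigDict(frozen=True)

    cohort_size: int
    regimen_counts: dict[str, int]
    admission_offset_days: dict[int, int]  # offset (<= 0) -> count
    leukopenia_absent: int
    leukopenia_onset_days: dict[int, int]
    leukopenia_duration_days: dict[int, int]
    scc_start_days: dict[int, int]
    scc_duration_counts: dict[int, int]
    scc_success_count: int
    scc_failed_count: int
    post_scc_day_counts: dict[int, int]
    event_onsets: dict[str, OnsetSummary]  # event_type value -> summary
    germ_detection_count: int
    aki_at_admission: int
    early_sae_count: int
    any_sae_count: int
    ctcae3_count: int
    any_ae_count: int
    sae_forbidden_days: tuple[int, ...] = (3, 4)
    late_onset_floor_day: int = 5

    @model_validator(mode="after")
    def _consistent(self) -> "MarginalConstraints":
        n = self.cohort_size

        def check(cond: bool, msg: str) -> None:
            if not cond:
                raise InfeasibleConstraints(msg)

        check(n > 0, "cohort_size must be positive")
        check(sum(self.regimen_counts.values()) == n, "regimen counts must sum to cohort size")
        check(sum(self.admission_offset_days.values()) == n,
              "admission offset counts must sum to cohort size")
        n_leuk = sum(self.leukopenia_onset_days.values())
        check(n_leuk + self.leukopenia_absent == n,
              "leukopenia onset counts + absent must sum to cohort size")
        check(sum(self.leukopenia_duration_days.values()) == n_leuk,
              "leukopenia duration counts must cover every leukopenic patient")
        check(self.scc_success_count + self.scc_failed_count == n,
              "SCC success + failed must sum to cohort size")
        check(sum(self.scc_start_days.values()) == self.scc_success_count,
              "SCC start-day counts must sum to the success count")
        check(sum(self.scc_duration_counts.values()) == self.scc_success_count,
              "SCC duration counts must sum to the success count")
        check(sum(self.post_scc_day_counts.values()) == self.scc_success_count,
              "post-SCC day counts must sum to the success count")
        for name, s in self.event_onsets.items():
            check(s.count <= n, f"event {name} count exceeds cohort size")
        check(self.tr_overlap >= 0, "CTCAE>=3 count too small for fever+transfusion+AKI counts")
        check(self.tr_overlap <= min(self._nf.count, self._tr.count),
              "CTCAE>=3 count too large: implied fever/transfusion overlap infeasible")
        check(self.mri_overlap >= 0, "any-SAE count too small for CTCAE>=3 + renal counts")
        check(self.mri_overlap <= self._mri.count,
              "any-SAE count too large: implied renal overlap infeasible")
        check(0 <= self.nausea_only <= self._nd.count,
              "any-AE count incompatible with SAE and nausea/diarrhea counts")
        check(self.any_sae_count <= n and self.ctcae3_count <= self.any_sae_count,
              "SAE / CTCAE>=3 counts out of order")
        check(self.germ_detection_count <= self._nf.count,
              "germ detections exceed fever count")
        return self

    # -- implied overlap sizes ------------------------------------------

    @property
    def _nf(self) -> OnsetSummary:
        return self.event_onsets[EventType.neutropenic_fever.value]

    @property
    def _tr(self) -> OnsetSummary:
        return self.event_onsets[EventType.transfusion.value]

    @property
    def _mri(self) -> OnsetSummary:
        return self.event_onsets[EventType.mild_renal_impairment.value]

    @property
    def _nd(self) -> OnsetSummary:
        return self.event_onsets[EventType.nausea_diarrhea.value]

    @property
    def tr_overlap(self) -> int:
        """Transfusion patients who also have fever (fixes |CTCAE>=3|)."""
        return self._nf.count + self._tr.count + self.aki_at_admission - self.ctcae3_count

    @property
    def mri_overlap(self) -> int:
        """Renal-impairment patients inside the CTCAE>=3 union (fixes |any SAE|)."""
        return self.ctcae3_count + self._mri.count - self.any_sae_count

    @property
    def nausea_only(self) -> int:
        return self.any_ae_count - self.any_sae_count


def default_constraints() -> MarginalConstraints:
    """Constraint set transcribed from the published cohort summary (N = 109).

    Coarse printed bins (admission 0-1 d: 101 / 2-4 d: 8; leukopenia onset
    6-8 d: 91 / >=9 d: 9 / none: 9, median 7; duration 1-3: 33 / 4-5: 52 /
    6-8: 15, median 4; collection interval 10-12: 36 / 13-15: 57 /
    16-19: 13 / failed: 3, median 13) are refined here to day resolution;
    the refinement reproduces the printed medians and quartiles.
    """
    return MarginalConstraints(
        cohort_size=109,
        regimen_counts={"cyclo_4000": 55, "etoposide_cyclo": 44, "etoposide_alone": 10},
        admission_offset_days={0: 8, -1: 93, -3: 8},
        leukopenia_absent=9,
        leukopenia_onset_days={6: 24, 7: 40, 8: 27, 9: 6, 10: 3},
        leukopenia_duration_days={1: 5, 2: 10, 3: 18, 4: 30, 5: 22, 6: 8, 7: 4, 8: 3},
        scc_start_days={10: 6, 11: 10, 12: 20, 13: 30, 14: 17, 15: 10, 16: 6, 17: 4, 18: 2, 19: 1},
        scc_duration_counts={1: 77, 2: 27, 3: 2},
        scc_success_count=106,
        scc_failed_count=3,
        post_scc_day_counts={0: 2, 1: 60, 2: 35, 3: 9},
        event_onsets={
            EventType.neutropenic_fever.value: OnsetSummary(count=59, median=9, min=1, max=12),
            EventType.transfusion.value: OnsetSummary(count=28, median=11, min=9, max=14),
            EventType.mild_renal_impairment.value: OnsetSummary(count=12, median=10, min=1, max=14),
            EventType.nausea_diarrhea.value: OnsetSummary(count=24, median=4, min=1, max=16),
        },
        germ_detection_count=26,
        aki_at_admission=1,
        early_sae_count=4,
        any_sae_count=75,
        ctcae3_count=65,
        any_ae_count=81,
    )


# ---------------------------------------------------------------------------
# onset multiset construction


def onset_multiset(
    summary: OnsetSummary,
    forbidden: Sequence[int] = (),
    rare_below: Optional[int] = None,
) -> list[int]:
    """A deterministic integer multiset with the requested count/median/range.

    Construction: pin the extremes once each, then add symmetric
    below/above pairs cycling through the allowed day values near the
    median, and fill the centre with median copies.  ``forbidden`` days are
    never used; days below ``rare_below`` (other than the pinned minimum)
    are avoided, which keeps severe-event onsets out of the early window
    except for the explicit minimum.
    """
    n, med, lo, hi = summary.count, summary.median, summary.min, summary.max
    if n == 0:
        return []
    if med != int(med):
        raise InfeasibleConstraints(f"non-integer target median {med} is not constructible")
    med = int(med)
    if n == 1:
        if not lo == med == hi:
            raise InfeasibleConstraints(f"single value cannot attain min {lo} / max {hi}")
        return [med]
    forbidden = set(forbidden)
    if med in forbidden or lo in forbidden or hi in forbidden:
        raise InfeasibleConstraints("median or extremes fall on forbidden days")

    need_lo = 1 if lo < med else 0
    need_hi = 1 if hi > med else 0
    cap = (n - 1) // 2 if n % 2 else n // 2 - 1
    if need_lo > cap or need_hi > cap:
        raise InfeasibleConstraints(f"n={n} too small for median {med} with range [{lo}, {hi}]")

    below_cycle = [
        d for d in range(med - 1, lo - 1, -1)
        if d not in forbidden and (rare_below is None or d >= rare_below)
    ]
    above_cycle = [d for d in range(med + 1, hi + 1) if d not in forbidden]

    t = cap if (below_cycle or need_lo) and (above_cycle or need_hi) else 0
    below = [lo] * need_lo
    above = [hi] * need_hi
    i = 0
    while len(below) < t and below_cycle:
        below.append(below_cycle[i % len(below_cycle)])
        i += 1
    i = 0
    while len(above) < t and above_cycle:
        above.append(above_cycle[i % len(above_cycle)])
        i += 1
    # keep the median exact: equal mass strictly below and above
    k = min(len(below), len(above))
    below, above = below[:k], above[:k]
    vals = sorted(below + above + [med] * (n - 2 * k))
    if (min(vals), max(vals), float(np.median(vals))) != (lo, hi, float(summary.median)):
        raise InfeasibleConstraints(
            f"no constructible multiset for n={n}, median={med}, range=[{lo}, {hi}]"
        )
    return vals


def _shift_values_to_early(
    values: list[int], n_moves: int, early_day: int, floor: int
) -> list[int]:
    """Move ``n_moves`` below-median values to ``early_day`` (for early-SAE slots)."""
    values = sorted(values)
    med = float(np.median(values))
    for _ in range(n_moves):
        candidates = [v for v in values if floor <= v < med]
        if not candidates:
            raise InfeasibleConstraints("cannot realize the requested early-SAE count")
        values.remove(min(candidates))
        values.append(early_day)
    return sorted(values)


# ---------------------------------------------------------------------------
# cohort assembly


def _expand(day_counts: dict[int, int]) -> list[int]:
    out: list[int] = []
    for day in sorted(day_counts):
        out.extend([day] * day_counts[day])
    return out


def build_fixture_cohort(
    constraints: Optional[MarginalConstraints] = None, seed: int = 0
) -> Cohort:
    """Build the deterministic fixture cohort satisfying every marginal exactly.

    The same ``(constraints, seed)`` always yields a byte-identical cohort.
    The seed only permutes quantities the marginals leave free (regimen and
    admission-offset placement, post-collection days, germ-detection flags,
    covariate values); all constrained quantities are laid out
    deterministically regardless of seed.
    """
    c = constraints or default_constraints()
    rng = np.random.default_rng(seed)
    n = c.cohort_size
    gap = c.sae_forbidden_days
    floor = c.late_onset_floor_day

    nf_s, tr_s, mri_s, nd_s = c._nf, c._tr, c._mri, c._nd
    nf_vals = onset_multiset(nf_s, forbidden=gap, rare_below=floor)
    tr_vals = onset_multiset(tr_s, forbidden=gap, rare_below=floor)
    mri_vals = onset_multiset(mri_s, forbidden=gap, rare_below=floor)
    nd_vals = onset_multiset(nd_s)

    early_window = 3
    implied_early = (
        c.aki_at_admission
        + sum(1 for v in nf_vals if v < early_window)
        + sum(1 for v in tr_vals if v < early_window)
        + sum(1 for v in mri_vals if v < early_window)
    )
    if implied_early > c.early_sae_count:
        raise InfeasibleConstraints(
            f"onset minima already imply {implied_early} early SAEs "
            f"(> target {c.early_sae_count})"
        )
    if implied_early < c.early_sae_count:
        nf_vals = _shift_values_to_early(
            nf_vals, c.early_sae_count - implied_early, early_day=2, floor=floor
        )

    # --- role layout ----------------------------------------------------
    n_nf = nf_s.count
    early_nf = sum(1 for v in nf_vals if v < early_window)
    tr_overlap, mri_overlap = c.tr_overlap, c.mri_overlap
    tr_only = tr_s.count - tr_overlap
    mri_early_vals = [v for v in mri_vals if v < early_window]
    mri_late_vals = [v for v in mri_vals if v >= early_window]
    mri_only = mri_s.count - mri_overlap
    nd_only = c.nausea_only
    nd_overlap = nd_s.count - nd_only

    if early_nf + mri_overlap > n_nf:
        raise InfeasibleConstraints("fever count too small for implied overlaps")
    if nd_overlap > n_nf - early_nf - mri_overlap:
        raise InfeasibleConstraints(
            "nausea/diarrhea overlap exceeds available non-early fever patients"
        )

    idx_aki = n_nf + tr_only
    idx_mri_only0 = idx_aki + c.aki_at_admission
    idx_nd_only0 = idx_mri_only0 + mri_only
    n_roles = idx_nd_only0 + nd_only
    if n_roles > n:
        raise InfeasibleConstraints("event patient roles exceed cohort size")

    events: list[list[AdverseEventRecord]] = [[] for _ in range(n)]

    germ = np.zeros(n_nf, dtype=bool)
    germ[rng.choice(n_nf, size=c.germ_detection_count, replace=False)] = True
    for i, onset in enumerate(nf_vals):
        events[i].append(
            AdverseEventRecord(
                event_type=EventType.neutropenic_fever,
                onset_day=onset,
                ctcae_grade=3,
                requires_hospitalization=True,
                germ_detected=bool(germ[i]),
            )
        )

    tr_targets = list(range(early_nf, early_nf + tr_overlap)) + list(range(n_nf, n_nf + tr_only))
    for i, onset in zip(tr_targets, tr_vals):
        events[i].append(
            AdverseEventRecord(
                event_type=EventType.transfusion,
                onset_day=onset,
                ctcae_grade=3,
                requires_hospitalization=True,
            )
        )

    for k in range(c.aki_at_admission):
        events[idx_aki + k].append(
            AdverseEventRecord(
                event_type=EventType.aki,
                onset_day=0,
                ctcae_grade=3,
                requires_hospitalization=True,
            )
        )

    mri_targets = (
        list(range(idx_mri_only0, idx_mri_only0 + len(mri_early_vals)))
        + list(range(early_nf, early_nf + mri_overlap))
        + list(range(idx_mri_only0 + len(mri_early_vals), idx_mri_only0 + mri_only))
    )
    for i, onset in zip(mri_targets, mri_early_vals + mri_late_vals):
        events[i].append(
            AdverseEventRecord(
                event_type=EventType.mild_renal_impairment,
                onset_day=onset,
                ctcae_grade=2,
                requires_hospitalization=True,
            )
        )

    nd_start = early_nf + mri_overlap
    nd_targets = list(range(nd_start, nd_start + nd_overlap)) + list(
        range(idx_nd_only0, idx_nd_only0 + nd_only)
    )
    for i, onset in zip(nd_targets, nd_vals):
        events[i].append(
            AdverseEventRecord(
                event_type=EventType.nausea_diarrhea,
                onset_day=onset,
                ctcae_grade=2,
                requires_hospitalization=False,
            )
        )

    # --- timeline scaffolding -------------------------------------------
    regimens = np.array(
        sum(([r] * k for r, k in sorted(c.regimen_counts.items())), []), dtype=object
    )
    rng.shuffle(regimens)
    offsets = np.array(_expand(c.admission_offset_days))
    rng.shuffle(offsets)

    failed = set(range(n - c.scc_failed_count, n))

    # leukopenia: absent for event-free, non-failed patients (chosen from the end)
    event_free = [i for i in range(n) if not events[i] and i not in failed]
    if len(event_free) < c.leukopenia_absent:
        event_free = [i for i in range(n) if i not in failed and not any(
            e.requires_hospitalization for e in events[i])]
    if len(event_free) < c.leukopenia_absent:
        raise InfeasibleConstraints("not enough non-failed patients without events "
                                    "to host leukopenia absence")
    no_leuk = set(event_free[-c.leukopenia_absent:])
    leuk_patients = [i for i in range(n) if i not in no_leuk]
    leuk_onsets = _expand(c.leukopenia_onset_days)
    leuk_durs = _expand(c.leukopenia_duration_days)

    # SCC: rank-match start days to each patient's latest severe-event onset
    success = [i for i in range(n) if i not in failed]
    needed = {
        i: max((e.onset_day for e in events[i] if e.requires_hospitalization), default=0)
        for i in success
    }
    order = sorted(success, key=lambda i: (needed[i], i))
    scc_starts = _expand(c.scc_start_days)
    scc_durs = _expand(c.scc_duration_counts)
    scc_start_by, scc_dur_by = {}, {}
    for i, start, dur in zip(order, scc_starts, scc_durs):
        scc_start_by[i], scc_dur_by[i] = start, dur

    post = np.array(_expand(c.post_scc_day_counts))
    rng.shuffle(post)
    post_by = dict(zip(success, post.tolist()))

    # --- covariates (free quantities; event-linked drift for realism) ----
    mri_flag = np.array([any(e.event_type is EventType.mild_renal_impairment
                             for e in ev) for ev in events])
    nf_flag = np.array([any(e.event_type is EventType.neutropenic_fever
                            for e in ev) for ev in events])
    panels = sample_covariate_panels(
        rng, regimens=[str(r) for r in regimens], mri_flags=mri_flag, nf_flags=nf_flag
    )

    patients = []
    for i in range(n):
        is_ok = i not in failed
        patients.append(
            PatientTimeline(
                patient_id=f"P{i + 1:03d}",
                admission_offset=int(offsets[i]),
                regimen=str(regimens[i]),
                therapy_duration_days={"cyclo_4000": 2, "etoposide_cyclo": 3,
                                       "etoposide_alone": 4}[str(regimens[i])],
                leukopenia_onset_day=None if i in no_leuk else leuk_onsets[leuk_patients.index(i)],
                leukopenia_duration_days=None if i in no_leuk else leuk_durs[leuk_patients.index(i)],
                scc_start_day=scc_start_by.get(i),
                scc_duration_days=scc_dur_by.get(i),
                scc_success=is_ok,
                post_scc_days=post_by.get(i, 0),
                events=sorted(events[i], key=lambda e: (e.onset_day, e.event_type.value)),
                covariates=panels[i],
            )
        )

    cohort = Cohort(patients=patients, provenance=Provenance.fixture, seed=seed)

    n_early = sum(is_early_sae(p) for p in cohort.patients)
    if n_early != c.early_sae_count:
        raise InfeasibleConstraints(
            f"constructed cohort has {n_early} early-SAE patients, target {c.early_sae_count}"
        )
    return cohort


# ---------------------------------------------------------------------------
# verification


@dataclass
class MarginalReport:
    rows: list[dict] = field(default_factory=list)

    def add(self, name: str, expected, observed) -> None:
        self.rows.append(
            {"constraint": name, "expected": expected, "observed": observed,
             "passed": expected == observed}
        )

    @property
    def passed(self) -> bool:
        return all(r["passed"] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def failures(self) -> list[dict]:
        return [r for r in self.rows if not r["passed"]]


def _bin_count(values, lo, hi) -> int:
    return sum(1 for v in values if lo <= v <= hi)


def verify_marginals(cohort: Cohort, constraints: Optional[MarginalConstraints] = None) -> MarginalReport:
    """Recount every published marginal on a cohort; pass/fail per constraint."""
    c = constraints or default_constraints()
    rep = MarginalReport()
    pats = list(cohort.patients)
    rep.add("cohort_size", c.cohort_size, len(pats))

    for reg, cnt in sorted(c.regimen_counts.items()):
        rep.add(f"regimen[{reg}]", cnt, sum(1 for p in pats if p.regimen.value == reg))

    gaps = [-p.admission_offset for p in pats]
    rep.add("admission_gap[0-1]", sum(v for k, v in c.admission_offset_days.items() if -1 <= k <= 0),
            _bin_count(gaps, 0, 1))
    rep.add("admission_gap[2-4]", sum(v for k, v in c.admission_offset_days.items() if k <= -2),
            _bin_count(gaps, 2, 4))

    leuk_on = [p.leukopenia_onset_day for p in pats if p.leukopenia_onset_day is not None]
    rep.add("leukopenia_count", c.cohort_size - c.leukopenia_absent, len(leuk_on))
    rep.add("leukopenia_onset[6-8]",
            sum(v for k, v in c.leukopenia_onset_days.items() if 6 <= k <= 8),
            _bin_count(leuk_on, 6, 8))
    rep.add("leukopenia_onset[>=9]",
            sum(v for k, v in c.leukopenia_onset_days.items() if k >= 9),
            sum(1 for v in leuk_on if v >= 9))
    rep.add("leukopenia_onset_median", float(np.median(_expand(c.leukopenia_onset_days))),
            float(np.median(leuk_on)) if leuk_on else None)
    leuk_dur = [p.leukopenia_duration_days for p in pats if p.leukopenia_duration_days is not None]
    for lo, hi in ((1, 3), (4, 5), (6, 8)):
        rep.add(f"leukopenia_duration[{lo}-{hi}]",
                sum(v for k, v in c.leukopenia_duration_days.items() if lo <= k <= hi),
                _bin_count(leuk_dur, lo, hi))
    rep.add("leukopenia_duration_median", float(np.median(_expand(c.leukopenia_duration_days))),
            float(np.median(leuk_dur)) if leuk_dur else None)

    scc = [p.scc_start_day for p in pats if p.scc_success]
    rep.add("scc_success", c.scc_success_count, sum(1 for p in pats if p.scc_success))
    for lo, hi in ((10, 12), (13, 15), (16, 19)):
        rep.add(f"scc_interval[{lo}-{hi}]",
                sum(v for k, v in c.scc_start_days.items() if lo <= k <= hi),
                _bin_count(scc, lo, hi))
    rep.add("scc_interval_median", float(np.median(_expand(c.scc_start_days))),
            float(np.median(scc)) if scc else None)
    for d, cnt in sorted(c.scc_duration_counts.items()):
        rep.add(f"scc_duration[{d}]", cnt,
                sum(1 for p in pats if p.scc_success and p.scc_duration_days == d))

    for etype, summary in c.event_onsets.items():
        onsets = []
        for p in pats:
            days = [e.onset_day for e in p.events if e.event_type.value == etype]
            if days:
                onsets.append(min(days))
        rep.add(f"{etype}_patients", summary.count, len(onsets))
        if onsets:
            rep.add(f"{etype}_onset_median", summary.median, float(np.median(onsets)))
            rep.add(f"{etype}_onset_min", summary.min, min(onsets))
            rep.add(f"{etype}_onset_max", summary.max, max(onsets))

    germ = sum(
        1 for p in pats
        if any(e.event_type is EventType.neutropenic_fever and e.germ_detected for e in p.events)
    )
    rep.add("germ_detection", c.germ_detection_count, germ)
    rep.add("aki_patients", c.aki_at_admission,
            sum(1 for p in pats if any(e.event_type is EventType.aki for e in p.events)))
    rep.add("any_sae", c.any_sae_count, sum(1 for p in pats if first_sae_day(p) is not None))
    rep.add("ctcae3", c.ctcae3_count,
            sum(1 for p in pats if any((e.ctcae_grade or 0) >= 3 for e in p.events)))
    rep.add("any_ae", c.any_ae_count, sum(1 for p in pats if p.events))
    rep.add("early_sae", c.early_sae_count, sum(1 for p in pats if is_early_sae(p)))
    return rep
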