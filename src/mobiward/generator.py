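"""Parametric synthetic-cohort generator.

Emulates the statistical structure of a chemotherapy-based mobilization
cohort: a small early-complication stratum (first severe event within
72 h of therapy start), a late stratum whose severe events start no
earlier than day 5 (the bimodal onset profile the admission-policy
simulations exploit), per-event occurrence probabilities with the positive
co-occurrence observed clinically, integer onset days drawn from shifted
binomial laws tuned to the published medians and ranges, leukopenia and
collection timing, and baseline plus day-3/5 laboratory panels with
event-linked longitudinal drift.

Covariate-outcome effects can be *planted* (log-odds slopes on occurrence,
linear day shifts on onset) so that recovery of known signal by the
prediction framework can be tested.  With an empty effect specification,
outcomes are independent of covariates.

The generator is a pure function of its parameters: the same
``GeneratorParams`` (including seed) always produces the identical cohort.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import binom

from .cohort import (
    LAB_FIELDS,
    AdverseEventRecord,
    Cohort,
    CovariatePanel,
    EventType,
    LabPanel,
    PatientTimeline,
    Provenance,
    first_sae_day,
    is_early_sae,
)

__all__ = [
    "OnsetModel",
    "PlantedEffect",
    "GeneratorParams",
    "sample_cohort",
    "sample_covariate_panels",
    "make_ml_dataset",
    "COVARIATE_REFERENCE",
]

_ENDPOINT_EVENT = {
    "fever": EventType.neutropenic_fever,
    "mri": EventType.mild_renal_impairment,
    "transfusion": EventType.transfusion,
}

#: Centering values for planted effects (distribution locations of the
#: default covariate models), so a slope of zero leaves rates untouched.
COVARIATE_REFERENCE = {
    "age_years": 63.0,
    "creatinine_mg_dl": 0.92,
    "ldh_u_l": 220.0,
    "hemoglobin_g_dl": 11.5,
    "platelets_per_nl": 230.0,
    "crp_mg_l": 6.9,
    "calcium_mmol_l": 2.35,
    "albumin_g_dl": 4.0,
    "prior_lines": 1.3,
}


class OnsetModel(BaseModel):
    """Shifted-binomial law for integer onset days on a closed support.

    The number of trials is ``high - low`` and the success probability is
    tuned so the distribution's median equals ``median`` — a discrete,
    bounded, two-parameter family.
    """

    model_config = ConfigDict(frozen=True)

    low: int = Field(ge=0, le=19)
    high: int = Field(ge=0, le=30)
    median: int

    @model_validator(mode="after")
    def _ordered(self) -> "OnsetModel":
        if not self.low <= self.median <= self.high:
            raise ValueError(f"onset model not ordered: {self}")
        return self

    def clipped(self, floor: int) -> "OnsetModel":
        """Restrict the support to days >= ``floor`` (late-stratum draws)."""
        lo = max(self.low, floor)
        if lo > self.high:
            raise ValueError(f"empty onset support after clipping at day {floor}")
        return OnsetModel(low=lo, high=self.high, median=max(self.median, lo))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        trials = self.high - self.low
        if trials == 0:
            return np.full(size, self.low)
        p = _binom_p_for_median(trials, self.median - self.low)
        return self.low + rng.binomial(trials, p, size=size)


@lru_cache(maxsize=None)
def _binom_p_for_median(trials: int, target: int) -> float:
    """Success probability making median(Binomial(trials, p)) == target."""
    grid = np.linspace(0.02, 0.98, 481)
    medians = binom.ppf(0.5, trials, grid)
    hits = grid[medians == target]
    if hits.size:
        return float(hits[hits.size // 2])
    return float(grid[np.argmin(np.abs(medians - target))])


class PlantedEffect(BaseModel):
    """A known covariate-outcome association injected into the generator.

    ``target`` is an endpoint name ("fever", "mri", "transfusion") for a
    log-odds slope on occurrence, or ``"<endpoint>_onset"`` for a linear
    shift (days per covariate unit) of the onset day.
    """

    model_config = ConfigDict(frozen=True)

    covariate: str
    target: str
    slope: float

    @model_validator(mode="after")
    def _known(self) -> "PlantedEffect":
        if self.covariate not in COVARIATE_REFERENCE:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        base = self.target.removesuffix("_onset")
        if base not in _ENDPOINT_EVENT:
            raise ValueError(f"unknown effect target {self.target!r}")
        if not math.isfinite(self.slope):
            raise ValueError("effect slope must be finite")
        return self


class GeneratorParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=109, ge=1)
    seed: int = 0

    early_sae_prob: float = Field(default=0.036, ge=0, le=1)
    #: probability an early patient's index event is fever / renal / AKI
    early_type_probs: dict[str, float] = Field(
        default_factory=lambda: {"neutropenic_fever": 0.5, "mild_renal_impairment": 0.25, "aki": 0.25}
    )

    #: marginal per-patient probabilities of each event type
    event_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "neutropenic_fever": 0.54,
            "transfusion": 0.26,
            "mild_renal_impairment": 0.11,
            "nausea_diarrhea": 0.22,
        }
    )
    #: co-occurrence structure: transfusions cluster in febrile patients and
    #: renal impairment is rare once another severe event is present
    transfusion_prob_given_fever: float = Field(default=0.40, ge=0, le=1)
    mri_prob_given_other_sae: float = Field(default=0.032, ge=0, le=1)

    onset_models: dict[str, OnsetModel] = Field(
        default_factory=lambda: {
            "neutropenic_fever": OnsetModel(low=1, high=12, median=9),
            "transfusion": OnsetModel(low=9, high=14, median=11),
            "mild_renal_impairment": OnsetModel(low=1, high=14, median=10),
            "nausea_diarrhea": OnsetModel(low=1, high=16, median=4),
        }
    )
    late_onset_floor_day: int = Field(default=5, ge=3)
    germ_detection_prob: float = Field(default=0.44, ge=0, le=1)

    leukopenia_prob: float = Field(default=100 / 109, ge=0, le=1)
    leukopenia_onset_model: OnsetModel = OnsetModel(low=6, high=10, median=7)
    leukopenia_duration_model: OnsetModel = OnsetModel(low=1, high=8, median=4)

    scc_success_prob: float = Field(default=106 / 109, ge=0, le=1)
    scc_interval_model: OnsetModel = OnsetModel(low=10, high=19, median=13)
    scc_duration_probs: dict[int, float] = Field(
        default_factory=lambda: {1: 77 / 106, 2: 27 / 106, 3: 2 / 106}
    )
    post_scc_day_probs: dict[int, float] = Field(
        default_factory=lambda: {0: 2 / 106, 1: 60 / 106, 2: 35 / 106, 3: 9 / 106}
    )

    regimen_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "cyclo_4000": 55 / 109,
            "etoposide_cyclo": 44 / 109,
            "etoposide_alone": 10 / 109,
        }
    )
    admission_offset_probs: dict[int, float] = Field(
        default_factory=lambda: {0: 8 / 109, -1: 93 / 109, -3: 8 / 109}
    )

    effect_spec: tuple[PlantedEffect, ...] = ()
    missingness_rate: float = Field(default=0.005, ge=0, le=0.5)
    #: scales the event-linked longitudinal drift (0 removes the signal)
    longitudinal_signal: float = 1.0

    @model_validator(mode="after")
    def _valid(self) -> "GeneratorParams":
        for name, p in self.event_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"event probability {name}={p} outside [0, 1]")
        self._conditional_probs()  # raises if the association structure is infeasible
        return self

    def _conditional_probs(self) -> dict[str, float]:
        """Branch probabilities reproducing the marginal rates and overlap."""
        pe = self.early_sae_prob
        et = self.early_type_probs
        p_nf = self.event_probs["neutropenic_fever"]
        p_tr = self.event_probs["transfusion"]
        p_mri = self.event_probs["mild_renal_impairment"]

        def _check(name: str, v: float) -> float:
            if not 0 <= v <= 1:
                raise ValueError(
                    f"association structure infeasible: implied {name}={v:.4f} outside [0, 1]"
                )
            return v

        nf = _check("P(fever | late stratum)",
                    (p_nf - pe * et.get("neutropenic_fever", 0)) / (1 - pe) if pe < 1 else 0.0)
        tr_marg = _check("P(transfusion | late stratum)", p_tr / (1 - pe) if pe < 1 else 0.0)
        tr_nf = self.transfusion_prob_given_fever
        tr_not = _check(
            "P(transfusion | no fever)",
            (tr_marg - nf * tr_nf) / (1 - nf) if nf < 1 else 0.0,
        )
        mri_marg = _check(
            "P(renal | late stratum)",
            (p_mri - pe * et.get("mild_renal_impairment", 0)) / (1 - pe) if pe < 1 else 0.0,
        )
        p_prior = nf + (1 - nf) * tr_not
        mri_sae = self.mri_prob_given_other_sae
        mri_none = _check(
            "P(renal | no prior severe event)",
            (mri_marg - p_prior * mri_sae) / (1 - p_prior) if p_prior < 1 else 0.0,
        )
        return {
            "nf": nf,
            "tr_given_nf": tr_nf,
            "tr_given_not": tr_not,
            "mri_given_sae": mri_sae,
            "mri_given_none": mri_none,
        }


# ---------------------------------------------------------------------------
# covariates


def _logit(p: np.ndarray | float) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_baseline(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Baseline covariates of a myeloma mobilization cohort (vectorized)."""
    return {
        "age_years": np.clip(np.round(rng.normal(63, 9, n)), 40, 83),
        "sex_male": rng.random(n) < 0.63,
        "creatinine_mg_dl": np.round(rng.lognormal(math.log(0.9), 0.22, n), 2),
        "ldh_u_l": np.round(np.clip(rng.normal(220, 50, n), 80, None), 0),
        "hemoglobin_g_dl": np.round(np.clip(rng.normal(11.5, 1.4, n), 6.5, 17.5), 1),
        "platelets_per_nl": np.round(np.clip(rng.normal(230, 70, n), 30, None), 0),
        "crp_mg_l": np.round(rng.lognormal(math.log(5), 0.8, n), 1),
        "calcium_mmol_l": np.round(np.clip(rng.normal(2.35, 0.12, n), 1.8, 3.2), 2),
        "albumin_g_dl": np.round(np.clip(rng.normal(4.0, 0.35, n), 2.2, 5.5), 2),
        "prior_ce_therapy": rng.random(n) < 0.4,
        "prior_lines": 1 + rng.poisson(0.3, n),
        "gcsf_dose_flag": rng.random(n) < 0.5,
    }


def sample_covariate_panels(
    rng: np.random.Generator,
    regimens: Sequence[str],
    mri_flags: np.ndarray,
    nf_flags: np.ndarray,
    baseline: Optional[dict[str, np.ndarray]] = None,
    missingness_rate: float = 0.005,
    longitudinal_signal: float = 1.0,
) -> list[CovariatePanel]:
    """Assemble covariate panels with day-3/5 follow-up labs.

    Longitudinal values follow an order-1 autoregressive drift around the
    admission value: hemoglobin and platelets decline toward the nadir,
    creatinine drifts upward in patients heading for renal impairment, and
    CRP rises in patients heading for neutropenic fever.  ``longitudinal_signal``
    scales the event-linked component; at 0 the follow-up labs are pure
    noise around baseline.  Missingness is completely at random.
    """
    n = len(regimens)
    base = baseline if baseline is not None else _draw_baseline(rng, n)
    s = longitudinal_signal
    mri_flags = np.asarray(mri_flags, dtype=bool)
    nf_flags = np.asarray(nf_flags, dtype=bool)

    drift = {
        "hemoglobin_g_dl": (-0.9 * s, -1.7 * s, 0.4, 6.0),
        "platelets_per_nl": (-70 * s, -130 * s, 20.0, 10.0),
        "ldh_u_l": (0.0, 0.0, 15.0, 80.0),
        "calcium_mmol_l": (0.0, 0.0, 0.05, 1.7),
        "albumin_g_dl": (0.0, -0.15 * s, 0.15, 2.0),
    }
    day_panels: dict[int, dict[str, np.ndarray]] = {}
    for day, frac in ((3, 1.0), (5, 2.0)):
        vals: dict[str, np.ndarray] = {}
        for f, (d3, d5, sd, lo) in drift.items():
            shift = d3 if day == 3 else d5
            vals[f] = np.clip(base[f] + shift + rng.normal(0, sd, n), lo, None)
        creat_shift = np.where(mri_flags, (0.15 if day == 3 else 0.40) * s, 0.0)
        vals["creatinine_mg_dl"] = np.clip(
            base["creatinine_mg_dl"] + creat_shift + rng.normal(0, 0.05, n), 0.3, None
        )
        crp_shift = np.where(nf_flags, (8.0 if day == 3 else 30.0) * s, 0.0)
        vals["crp_mg_l"] = np.clip(
            base["crp_mg_l"] + crp_shift + rng.normal(0, 2.0, n), 0.2, None
        )
        day_panels[day] = {f: np.round(v, 2) for f, v in vals.items()}

    miss = rng.random((n, len(LAB_FIELDS) * 3)) < missingness_rate

    panels = []
    for i in range(n):
        reg = regimens[i]
        labs = {}
        for j, f in enumerate(LAB_FIELDS):
            labs[f] = None if miss[i, j] else float(base[f][i])
        longitudinal = {}
        for k, day in enumerate((3, 5)):
            pv = {}
            for j, f in enumerate(LAB_FIELDS):
                col = len(LAB_FIELDS) * (k + 1) + j
                pv[f] = None if miss[i, col] else float(day_panels[day][f][i])
            longitudinal[day] = LabPanel(**pv)
        panels.append(
            CovariatePanel(
                age_years=float(base["age_years"][i]),
                sex="M" if base["sex_male"][i] else "F",
                prior_ce_therapy=bool(base["prior_ce_therapy"][i]),
                prior_lines=int(base["prior_lines"][i]),
                full_dose_flag=reg == "cyclo_4000",
                cyclo_flag=reg in ("cyclo_4000", "etoposide_cyclo"),
                ce_flag=reg == "etoposide_cyclo",
                etoposide_flag=reg in ("etoposide_cyclo", "etoposide_alone"),
                gcsf_dose_flag=bool(base["gcsf_dose_flag"][i]),
                longitudinal=longitudinal,
                **labs,
            )
        )
    return panels


# ---------------------------------------------------------------------------
# cohort sampling


def _effect_eta(
    params: GeneratorParams, base: dict[str, np.ndarray], target: str, n: int
) -> np.ndarray:
    """Summed planted linear predictor contribution for one target."""
    eta = np.zeros(n)
    for eff in params.effect_spec:
        if eff.target == target:
            x = np.asarray(base[eff.covariate], dtype=float)
            eta += eff.slope * (x - COVARIATE_REFERENCE[eff.covariate])
    return eta


def sample_cohort(params: GeneratorParams) -> Cohort:
    """Draw a full synthetic cohort from the generator model."""
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    cond = params._conditional_probs()
    floor = params.late_onset_floor_day

    regs = list(params.regimen_probs)
    regimen = rng.choice(regs, size=n, p=[params.regimen_probs[r] for r in regs])
    offs = sorted(params.admission_offset_probs)
    offsets = rng.choice(offs, size=n, p=[params.admission_offset_probs[o] for o in offs])

    base = _draw_baseline(rng, n)

    early = rng.random(n) < params.early_sae_prob
    etypes = list(params.early_type_probs)
    early_type = rng.choice(etypes, size=n, p=[params.early_type_probs[t] for t in etypes])
    early_onset = rng.integers(0, 3, size=n)

    # occurrence with co-occurrence structure + planted effects (late stratum)
    p_nf = _sigmoid(_logit(cond["nf"]) + _effect_eta(params, base, "fever", n))
    nf = (~early) & (rng.random(n) < p_nf)
    eta_tr = _effect_eta(params, base, "transfusion", n)
    p_tr = np.where(
        nf,
        _sigmoid(_logit(cond["tr_given_nf"]) + eta_tr),
        _sigmoid(_logit(cond["tr_given_not"]) + eta_tr),
    )
    tr = (~early) & (rng.random(n) < p_tr)
    eta_mri = _effect_eta(params, base, "mri", n)
    p_mri = np.where(
        nf | tr,
        _sigmoid(_logit(cond["mri_given_sae"]) + eta_mri),
        _sigmoid(_logit(cond["mri_given_none"]) + eta_mri),
    )
    mri = (~early) & (rng.random(n) < p_mri)
    nd = rng.random(n) < params.event_probs["nausea_diarrhea"]

    def _onsets(name: str, endpoint: str) -> np.ndarray:
        model = params.onset_models[name].clipped(floor)
        raw = model.draw(rng, n).astype(float)
        raw += _effect_eta(params, base, f"{endpoint}_onset", n)
        return np.clip(np.round(raw), model.low, model.high).astype(int)

    nf_onset = _onsets("neutropenic_fever", "fever")
    tr_onset = _onsets("transfusion", "transfusion")
    mri_onset = _onsets("mild_renal_impairment", "mri")
    nd_model = params.onset_models["nausea_diarrhea"]
    nd_onset = nd_model.draw(rng, n)
    germ = rng.random(n) < params.germ_detection_prob

    leuk = rng.random(n) < params.leukopenia_prob
    leuk_onset = params.leukopenia_onset_model.draw(rng, n)
    leuk_dur = params.leukopenia_duration_model.draw(rng, n)

    ok = rng.random(n) < params.scc_success_prob
    scc_start = params.scc_interval_model.draw(rng, n)
    durs = sorted(params.scc_duration_probs)
    scc_dur = rng.choice(durs, size=n, p=[params.scc_duration_probs[d] for d in durs])
    posts = sorted(params.post_scc_day_probs)
    post = rng.choice(posts, size=n, p=[params.post_scc_day_probs[p_] for p_ in posts])

    mri_any = mri | (early & (early_type == "mild_renal_impairment"))
    nf_any = nf | (early & (early_type == "neutropenic_fever"))
    panels = sample_covariate_panels(
        rng,
        regimens=[str(r) for r in regimen],
        mri_flags=mri_any,
        nf_flags=nf_any,
        baseline=base,
        missingness_rate=params.missingness_rate,
        longitudinal_signal=params.longitudinal_signal,
    )

    dur_by_reg = {"cyclo_4000": 2, "etoposide_cyclo": 3, "etoposide_alone": 4}
    patients = []
    for i in range(n):
        events: list[AdverseEventRecord] = []
        if early[i]:
            t = early_type[i]
            if t == "aki":
                events.append(AdverseEventRecord(
                    event_type=EventType.aki, onset_day=0, ctcae_grade=3,
                    requires_hospitalization=True))
            elif t == "mild_renal_impairment":
                events.append(AdverseEventRecord(
                    event_type=EventType.mild_renal_impairment,
                    onset_day=int(early_onset[i]), ctcae_grade=2,
                    requires_hospitalization=True))
            else:
                events.append(AdverseEventRecord(
                    event_type=EventType.neutropenic_fever,
                    onset_day=int(early_onset[i]), ctcae_grade=3,
                    requires_hospitalization=True, germ_detected=bool(germ[i])))
        if nf[i]:
            events.append(AdverseEventRecord(
                event_type=EventType.neutropenic_fever, onset_day=int(nf_onset[i]),
                ctcae_grade=3, requires_hospitalization=True,
                germ_detected=bool(germ[i])))
        if tr[i]:
            events.append(AdverseEventRecord(
                event_type=EventType.transfusion, onset_day=int(tr_onset[i]),
                ctcae_grade=3, requires_hospitalization=True))
        if mri[i]:
            events.append(AdverseEventRecord(
                event_type=EventType.mild_renal_impairment, onset_day=int(mri_onset[i]),
                ctcae_grade=2, requires_hospitalization=True))
        if nd[i]:
            events.append(AdverseEventRecord(
                event_type=EventType.nausea_diarrhea, onset_day=int(nd_onset[i]),
                ctcae_grade=2, requires_hospitalization=False))
        events.sort(key=lambda e: (e.onset_day, e.event_type.value))

        patients.append(PatientTimeline(
            patient_id=f"S{i + 1:05d}",
            admission_offset=int(offsets[i]),
            regimen=str(regimen[i]),
            therapy_duration_days=dur_by_reg[str(regimen[i])],
            leukopenia_onset_day=int(leuk_onset[i]) if leuk[i] else None,
            leukopenia_duration_days=int(leuk_dur[i]) if leuk[i] else None,
            scc_start_day=int(scc_start[i]) if ok[i] else None,
            scc_duration_days=int(scc_dur[i]) if ok[i] else None,
            scc_success=bool(ok[i]),
            post_scc_days=int(post[i]) if ok[i] else 0,
            events=events,
            covariates=panels[i],
        ))
    return Cohort(patients=patients, provenance=Provenance.synthetic, seed=params.seed)


# ---------------------------------------------------------------------------
# ML dataset extraction


FeatureSet = Literal["clinical", "mi_extended", "longitudinal"]
Endpoint = Literal["any_sae", "mri", "fever", "transfusion"]


def make_ml_dataset(
    cohort: Cohort,
    endpoint: Endpoint,
    feature_set: FeatureSet = "clinical",
    early_window_days: int = 3,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Feature matrix, binary labels, and onset targets for one endpoint.

    Only severe events starting at or after the early window qualify as
    positives, and patients whose first severe event fell *inside* the
    window are excluded entirely (their admission is decided clinically,
    not by a model).  Onset targets are the first qualifying onset day for
    positives and NaN otherwise.  Features are imputed (running average
    over a patient's lab series, population mean otherwise).
    """
    if endpoint not in ("any_sae", "mri", "fever", "transfusion"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if feature_set not in ("clinical", "mi_extended", "longitudinal"):
        raise ValueError(f"unknown feature_set {feature_set!r}")

    from .prediction import corrected_calcium, egfr_ckdepi_2021, impute_labs

    rows, labels, onsets = [], [], []
    for p in cohort.patients:
        if is_early_sae(p, window_days=early_window_days):
            continue
        if endpoint == "any_sae":
            qual = [e.onset_day for e in p.events
                    if e.requires_hospitalization and e.onset_day >= early_window_days]
        else:
            etype = _ENDPOINT_EVENT[endpoint]
            qual = [e.onset_day for e in p.events
                    if e.event_type is etype and e.requires_hospitalization
                    and e.onset_day >= early_window_days]
        labels.append(1 if qual else 0)
        onsets.append(float(min(qual)) if qual else np.nan)

        cov = p.covariates
        row = {"age_years": cov.age_years, "sex_male": 1.0 if cov.sex.value == "M" else 0.0}
        for f in LAB_FIELDS:
            row[f] = getattr(cov, f)
        for day in (3, 5):
            panel = cov.longitudinal.get(day)
            for f in LAB_FIELDS:
                row[f"day{day}_{f}"] = getattr(panel, f) if panel is not None else None
        row.update(
            prior_ce_therapy=float(cov.prior_ce_therapy),
            prior_lines=float(cov.prior_lines),
            full_dose_flag=float(cov.full_dose_flag),
            cyclo_flag=float(cov.cyclo_flag),
            ce_flag=float(cov.ce_flag),
            etoposide_flag=float(cov.etoposide_flag),
            gcsf_dose_flag=float(cov.gcsf_dose_flag),
        )
        rows.append(row)

    raw = pd.DataFrame(rows).astype(float)
    raw = impute_labs(raw)
    raw["egfr_ml_min"] = [
        egfr_ckdepi_2021(cr, age, "M" if male else "F")
        for cr, age, male in zip(raw["creatinine_mg_dl"], raw["age_years"], raw["sex_male"])
    ]
    raw["corrected_calcium_mg_dl"] = [
        corrected_calcium(ca * 4.008, alb)  # mmol/L -> mg/dL before correcting
        for ca, alb in zip(raw["calcium_mmol_l"], raw["albumin_g_dl"])
    ]

    clinical = ["age_years", "egfr_ml_min", "ldh_u_l", "hemoglobin_g_dl",
                "platelets_per_nl", "prior_ce_therapy", "prior_lines"]
    mi_extra = ["sex_male", "crp_mg_l", "corrected_calcium_mg_dl", "creatinine_mg_dl",
                "full_dose_flag", "cyclo_flag", "ce_flag", "etoposide_flag", "gcsf_dose_flag"]
    longi = [f"day{d}_{f}" for d in (3, 5) for f in LAB_FIELDS]
    columns = {"clinical": clinical,
               "mi_extended": clinical + mi_extra,
               "longitudinal": clinical + mi_extra + longi}[feature_set]
    X = raw[columns].copy()
    return X, np.asarray(labels, dtype=int), np.asarray(onsets, dtype=float)
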