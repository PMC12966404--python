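import numpy as np
import pytest
from pydantic import ValidationError

from mobiward.cohort import EventType, Provenance, first_sae_day, is_early_sae
from mobiward.generator import (
    COVARIATE_REFERENCE,
    GeneratorParams,
    OnsetModel,
    PlantedEffect,
    make_ml_dataset,
    sample_cohort,
)


class TestOnsetModel:
    def test_draws_stay_on_support_and_hit_median(self):
        rng = np.random.default_rng(0)
        model = OnsetModel(low=1, high=12, median=9)
        draws = model.draw(rng, 4000)
        assert draws.min() >= 1 and draws.max() <= 12
        assert float(np.median(draws)) == 9

    def test_clipped_floor(self):
        rng = np.random.default_rng(0)
        model = OnsetModel(low=1, high=12, median=9).clipped(5)
        draws = model.draw(rng, 2000)
        assert draws.min() >= 5
        assert float(np.median(draws)) == 9

    def test_degenerate_support(self):
        rng = np.random.default_rng(0)
        model = OnsetModel(low=7, high=7, median=7)
        assert (model.draw(rng, 10) == 7).all()


class TestGeneratorParams:
    def test_defaults_valid(self):
        GeneratorParams()

    def test_infeasible_association_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            GeneratorParams(transfusion_prob_given_fever=0.9,
                            event_probs={"neutropenic_fever": 0.54,
                                         "transfusion": 0.10,
                                         "mild_renal_impairment": 0.11,
                                         "nausea_diarrhea": 0.22})

    def test_bad_probability_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorParams(event_probs={"neutropenic_fever": 1.4,
                                         "transfusion": 0.26,
                                         "mild_renal_impairment": 0.11,
                                         "nausea_diarrhea": 0.22})


class TestSampleCohort:
    def test_reproducible(self):
        params = GeneratorParams(n_patients=50, seed=11)
        assert sample_cohort(params) == sample_cohort(params)

    def test_shape_and_provenance(self, synth_cohort):
        assert len(synth_cohort) == 300
        assert synth_cohort.provenance is Provenance.synthetic
        assert synth_cohort.seed == 3
        assert len({p.patient_id for p in synth_cohort.patients}) == 300

    def test_bimodal_gap(self, synth_cohort):
        hosp = [e.onset_day for p in synth_cohort.patients for e in p.events
                if e.requires_hospitalization]
        assert all(d in (0, 1, 2) or d >= 5 for d in hosp)

    def test_early_events_match_flag(self, synth_cohort):
        for p in synth_cohort.patients:
            day = first_sae_day(p)
            assert is_early_sae(p) == (day is not None and day < 3)

    def test_transfusions_cluster_in_febrile_patients(self):
        cohort = sample_cohort(GeneratorParams(n_patients=3000, seed=8))
        has = {t: np.array([any(e.event_type is t for e in p.events)
                            for p in cohort.patients])
               for t in (EventType.neutropenic_fever, EventType.transfusion)}
        nf, tr = has[EventType.neutropenic_fever], has[EventType.transfusion]
        p_tr_nf = tr[nf].mean()
        p_tr_not = tr[~nf].mean()
        assert p_tr_nf > p_tr_not + 0.1

    def test_longitudinal_drift_direction(self, synth_cohort):
        base, day5 = [], []
        for p in synth_cohort.patients:
            panel = p.covariates.longitudinal.get(5)
            if panel is None or panel.hemoglobin_g_dl is None:
                continue
            if p.covariates.hemoglobin_g_dl is None:
                continue
            base.append(p.covariates.hemoglobin_g_dl)
            day5.append(panel.hemoglobin_g_dl)
        assert np.mean(day5) < np.mean(base) - 0.5

    def test_missingness_rate(self):
        cohort = sample_cohort(GeneratorParams(n_patients=2000, seed=9))
        total = missing = 0
        for p in cohort.patients:
            for f in ("creatinine_mg_dl", "ldh_u_l", "hemoglobin_g_dl",
                      "platelets_per_nl", "crp_mg_l", "calcium_mmol_l",
                      "albumin_g_dl"):
                total += 1
                missing += getattr(p.covariates, f) is None
        rate = missing / total
        assert 0.001 < rate < 0.012


class TestMakeMLDataset:
    def test_excludes_early_patients(self, synth_cohort):
        X, y, t = make_ml_dataset(synth_cohort, "any_sae")
        n_early = sum(1 for p in synth_cohort.patients if is_early_sae(p))
        assert len(X) == len(synth_cohort) - n_early

    def test_labels_and_onsets_consistent(self, synth_cohort):
        X, y, t = make_ml_dataset(synth_cohort, "any_sae")
        assert set(np.unique(y)) <= {0, 1}
        assert np.all(np.isnan(t[y == 0]))
        assert np.all(t[y == 1] >= 3)
        assert not X.isna().any().any()

    def test_feature_set_shapes(self, synth_cohort):
        for name, n_cols in (("clinical", 7), ("mi_extended", 16),
                             ("longitudinal", 30)):
            X, _, _ = make_ml_dataset(synth_cohort, "any_sae", feature_set=name)
            assert X.shape[1] == n_cols

    def test_engineered_features_present(self, synth_cohort):
        X, _, _ = make_ml_dataset(synth_cohort, "fever", feature_set="mi_extended")
        assert "egfr_ml_min" in X.columns
        assert "corrected_calcium_mg_dl" in X.columns

    def test_unknown_endpoint(self, synth_cohort):
        with pytest.raises(ValueError, match="endpoint"):
            make_ml_dataset(synth_cohort, "aki")


class TestPlantedEffects:
    def test_occurrence_effect_raises_rate_with_covariate(self):
        eff = (PlantedEffect(covariate="age_years", target="fever", slope=0.2),)
        cohort = sample_cohort(GeneratorParams(n_patients=3000, seed=12,
                                               effect_spec=eff))
        ages, fevers = [], []
        for p in cohort.patients:
            ages.append(p.covariates.age_years)
            fevers.append(any(e.event_type is EventType.neutropenic_fever
                              for e in p.events))
        ages, fevers = np.array(ages), np.array(fevers)
        ref = COVARIATE_REFERENCE["age_years"]
        assert fevers[ages > ref + 5].mean() > fevers[ages < ref - 5].mean() + 0.1

    def test_onset_effect_shifts_timing(self):
        eff = (PlantedEffect(covariate="age_years", target="fever_onset", slope=0.15),)
        cohort = sample_cohort(GeneratorParams(n_patients=4000, seed=13,
                                               effect_spec=eff))
        old_days, young_days = [], []
        ref = COVARIATE_REFERENCE["age_years"]
        for p in cohort.patients:
            if is_early_sae(p):
                continue
            for e in p.events:
                if e.event_type is EventType.neutropenic_fever and e.onset_day >= 5:
                    (old_days if p.covariates.age_years > ref + 5
                     else young_days if p.covariates.age_years < ref - 5
                     else []).append(e.onset_day)
        assert np.mean(old_days) > np.mean(young_days) + 0.4
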