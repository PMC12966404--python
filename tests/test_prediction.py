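import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from mobiward.generator import GeneratorParams, make_ml_dataset, sample_cohort
from mobiward.prediction import (
    TwoStepSAEPredictor,
    classifier_registry,
    corrected_calcium,
    egfr_ckdepi_2021,
    impute_labs,
    mcc,
    register_classifier,
    run_classification,
    run_onset_regression,
    select_features_mi,
    two_step_predict,
)


class TestClinicalTransforms:
    # hand-computed from the published CKD-EPI 2021 coefficients
    @pytest.mark.parametrize("creat,age,sex,expected", [
        (1.0, 60, "M", 86.1626),
        (0.8, 50, "F", 89.7074),
        (0.5, 70, "F", 100.8359),
    ])
    def test_egfr_oracle(self, creat, age, sex, expected):
        assert egfr_ckdepi_2021(creat, age, sex) == pytest.approx(expected, abs=1e-3)

    def test_egfr_monotone_in_creatinine(self):
        vals = [egfr_ckdepi_2021(c, 60, "M") for c in (0.6, 0.9, 1.2, 2.0)]
        assert vals == sorted(vals, reverse=True)

    def test_egfr_domain(self):
        with pytest.raises(ValueError):
            egfr_ckdepi_2021(0.0, 60, "M")

    def test_corrected_calcium(self):
        assert corrected_calcium(9.0, 3.0) == pytest.approx(9.8)
        assert corrected_calcium(9.0, 4.0) == pytest.approx(9.0)
        with pytest.raises(ValueError):
            corrected_calcium(9.0, -1.0)


class TestImputeLabs:
    def test_running_average_over_series(self):
        df = pd.DataFrame({
            "crp_mg_l": [10.0, np.nan],
            "day3_crp_mg_l": [np.nan, 20.0],
            "day5_crp_mg_l": [30.0, 40.0],
        })
        out = impute_labs(df)
        assert out.loc[0, "day3_crp_mg_l"] == pytest.approx(20.0)  # mean(10, 30)
        assert out.loc[1, "crp_mg_l"] == pytest.approx(30.0)  # mean(20, 40)

    def test_population_mean_fallback(self):
        df = pd.DataFrame({"age_years": [50.0, np.nan, 70.0]})
        out = impute_labs(df)
        assert out.loc[1, "age_years"] == pytest.approx(60.0)

    def test_all_missing_column_named(self):
        df = pd.DataFrame({"ldh_u_l": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="ldh_u_l"):
            impute_labs(df)

    def test_no_nans_remain(self, synth_cohort):
        X, _, _ = make_ml_dataset(synth_cohort, "any_sae", feature_set="longitudinal")
        assert not X.isna().any().any()


class TestFeatureSelection:
    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 600
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({
            "signal": y + rng.normal(0, 0.3, n),
            "noise_a": rng.normal(0, 1, n),
            "noise_b": rng.normal(0, 1, n),
        })
        ranked = select_features_mi(df, y)
        assert ranked[0] == "signal"

    def test_base_set_first_and_top_k(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        out = select_features_mi(df, y, base_set=("d",), top_k=2)
        assert out[0] == "d" and len(out) == 3
        assert "d" not in out[1:]

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 300)
        df = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        assert select_features_mi(df, y) == select_features_mi(df, y)


class TestMCC:
    def test_matches_sklearn_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            if tp + tn + fp + fn == 0:
                continue
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            assert mcc(tp, tn, fp, fn) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_zero_marginal(self):
        assert mcc(0, 10, 0, 5) == 0.0

    def test_perfect_and_inverted(self):
        assert mcc(10, 10, 0, 0) == pytest.approx(1.0)
        assert mcc(0, 0, 10, 10) == pytest.approx(-1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(-1, 1, 1, 1)


@pytest.fixture(scope="module")
def ml_data(synth_cohort):
    return make_ml_dataset(synth_cohort, "any_sae", feature_set="clinical")


class TestRunClassification:
    def test_report_shape_and_determinism(self, ml_data):
        X, y, _ = ml_data
        r1 = run_classification(X, y, models=("logreg",), seed=0)[0]
        r2 = run_classification(X, y, models=("logreg",), seed=0)[0]
        assert len(r1.fold_accuracy) == 5
        assert r1.fold_roc_auc == r2.fold_roc_auc
        assert 0.0 <= r1.mean_accuracy <= 1.0
        assert -1.0 <= r1.mean_mcc <= 1.0

    def test_single_class_rejected(self, ml_data):
        X, y, _ = ml_data
        with pytest.raises(ValueError, match="both classes"):
            run_classification(X, np.ones_like(y))

    def test_unknown_model(self, ml_data):
        X, y, _ = ml_data
        with pytest.raises(ValueError, match="unknown classifier"):
            run_classification(X, y, models=("nonexistent",))

    def test_registry_plugin(self, ml_data):
        from sklearn.tree import DecisionTreeClassifier

        register_classifier("stump", lambda seed: DecisionTreeClassifier(
            max_depth=1, random_state=seed))
        assert "stump" in classifier_registry()
        X, y, _ = ml_data
        report = run_classification(X, y, models=("stump",), seed=0)[0]
        assert len(report.fold_mcc) == 5

    def test_to_frame(self, ml_data):
        X, y, _ = ml_data
        frame = run_classification(X, y, models=("logreg",), seed=0)[0].to_frame()
        assert set(frame["metric"]) == {"accuracy", "roc_auc", "mcc"}
        assert len(frame) == 15


class TestRunOnsetRegression:
    def test_reports(self, ml_data):
        X, _, t = ml_data
        reports = run_onset_regression(X, t, models=("elastic_net",), seed=0)
        r = reports[0]
        assert r.mad_days > 0 and r.rmsd_days >= r.mad_days
        assert len(r.fold_mad) == 3

    def test_too_few_positives(self, ml_data):
        X, _, _ = ml_data
        t = np.full(len(X), np.nan)
        t[0] = 9.0
        with pytest.raises(ValueError, match="positive"):
            run_onset_regression(X, t)


class TestTwoStep:
    def test_fit_predict_cycle(self, ml_data):
        X, y, t = ml_data
        est = TwoStepSAEPredictor(threshold=0.5, seed=0).fit(X, y, t)
        proba = est.predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        onset = est.predict(X)
        flagged = proba[:, 1] >= 0.5
        assert np.all(np.isnan(onset[~flagged]))
        assert np.all(~np.isnan(onset[flagged]))

    def test_threshold_extremes(self, ml_data):
        X, y, t = ml_data
        est = TwoStepSAEPredictor(seed=0).fit(X, y, t)
        proba, onset = two_step_predict(est.classifier_, est.regressor_, X,
                                        threshold=1.1)
        assert np.all(np.isnan(onset))
        _, onset = two_step_predict(est.classifier_, est.regressor_, X,
                                    threshold=0.0)
        assert not np.any(np.isnan(onset))

    def test_requires_onsets(self, ml_data):
        X, y, _ = ml_data
        with pytest.raises(ValueError, match="onset_days"):
            TwoStepSAEPredictor().fit(X, y)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = TwoStepSAEPredictor(threshold=0.3)
        assert clone(est).get_params()["threshold"] == 0.3
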