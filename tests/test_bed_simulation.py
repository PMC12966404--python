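import numpy as np
import pytest

from mobiward.bedsim import (
    SCENARIO_LABELS,
    ScenarioSpec,
    apply_scenario_events,
    bed_days,
    bootstrap_ci,
    compare_groups,
    compare_scenarios,
    hospitalization_intervals,
    normalize,
    scenario_from_label,
    scenario_suite,
)
from mobiward.cohort import Cohort, EventType
from mobiward.generator import GeneratorParams, sample_cohort

from conftest import make_patient, sae


def one_patient_cohort(patient):
    return Cohort(patients=[patient])


def occupancy_oracle(patient, spec):
    """Naive day-by-day bed count over the full plausible day range."""
    mod = apply_scenario_events(patient, spec)
    iv = hospitalization_intervals(mod, spec).intervals
    return sum(1 for day in range(-4, 41)
               if any(s <= day <= e for s, e in iv))


class TestScenarioSpec:
    def test_current_takes_no_submodel(self):
        with pytest.raises(ValueError):
            ScenarioSpec(family="current", submodel="X1")

    def test_day5_rejects_x3(self):
        with pytest.raises(ValueError):
            ScenarioSpec(family="day5", submodel="X3")

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            ScenarioSpec(family="optimistic", submodel="X1")

    def test_label_parsing(self):
        assert scenario_from_label("Current").family == "current"
        spec = scenario_from_label("SE2")
        assert (spec.family, spec.submodel) == ("empirical", "X2")
        spec = scenario_from_label("SB3")
        assert (spec.family, spec.submodel) == ("best", "X3")
        with pytest.raises(ValueError):
            scenario_from_label("SQ9")


class TestEventModification:
    def test_worst_shifts_fever_earlier(self):
        p = make_patient(events=[sae(9)])
        mod = apply_scenario_events(p, scenario_from_label("SW2"))
        assert mod.events[0].onset_day == 8

    def test_best_shifts_fever_later(self):
        p = make_patient(events=[sae(9)])
        mod = apply_scenario_events(p, scenario_from_label("SB2"))
        assert mod.events[0].onset_day == 10

    def test_empirical_leaves_onsets(self):
        p = make_patient(events=[sae(9)])
        mod = apply_scenario_events(p, scenario_from_label("SE2"))
        assert mod.events[0].onset_day == 9

    def test_early_patients_untouched(self):
        p = make_patient(events=[sae(1)])
        for label in SCENARIO_LABELS[1:]:
            assert apply_scenario_events(p, scenario_from_label(label)) == p

    def test_outpatient_manageable_clears_hospitalization(self):
        p = make_patient(events=[sae(11, EventType.transfusion)])
        spec = scenario_from_label("SE3", outpatient=[EventType.transfusion])
        mod = apply_scenario_events(p, spec)
        assert not mod.events[0].requires_hospitalization

    def test_non_fever_onsets_never_shift(self):
        p = make_patient(events=[sae(11, EventType.transfusion)])
        mod = apply_scenario_events(p, scenario_from_label("SW2"))
        assert mod.events[0].onset_day == 11


class TestHandComputedBedDays:
    """One patient: admitted day -1, 2-day therapy, SCC day 12 (1 day), one
    post-collection day => discharge day 13."""

    def test_current_full_course(self):
        c = one_patient_cohort(make_patient(events=[sae(9)]))
        res = bed_days(c, scenario_from_label("Current"))
        assert res.total_bd == 15  # days -1..13

    def test_empirical_x2_with_fever_day9(self):
        c = one_patient_cohort(make_patient(events=[sae(9)]))
        res = bed_days(c, scenario_from_label("SE2"))
        assert res.total_bd == 5  # days 9..13

    def test_day5_x2_without_sae(self):
        c = one_patient_cohort(make_patient())
        res = bed_days(c, scenario_from_label("S52"))
        assert res.total_bd == 9  # days 5..13

    def test_day5_x1_adds_therapy_block(self):
        c = one_patient_cohort(make_patient())
        res = bed_days(c, scenario_from_label("S51"))
        assert res.total_bd == 11  # therapy days 0..1 plus days 5..13

    def test_worst_and_best_shift_by_one_day(self):
        c = one_patient_cohort(make_patient(events=[sae(9)]))
        assert bed_days(c, scenario_from_label("SW2")).total_bd == 6
        assert bed_days(c, scenario_from_label("SB2")).total_bd == 4

    def test_x3_without_sae_stays_outpatient(self):
        c = one_patient_cohort(make_patient())
        assert bed_days(c, scenario_from_label("SE3")).total_bd == 0

    def test_x3_with_prior_sae_keeps_scc_inpatient(self):
        c = one_patient_cohort(make_patient(events=[sae(9)]))
        assert bed_days(c, scenario_from_label("SE3")).total_bd == 5

    def test_components_sum_to_total(self, fixture_cohort):
        for label in SCENARIO_LABELS:
            res = bed_days(fixture_cohort, scenario_from_label(label))
            assert sum(res.component_bd.values()) == res.total_bd
            assert sum(res.per_patient_bd) == res.total_bd


class TestOracleEquivalence:
    def test_small_random_cohorts(self):
        labels = list(SCENARIO_LABELS)
        for seed in range(30):
            k = 1 + seed % 5
            cohort = sample_cohort(GeneratorParams(n_patients=k, seed=1000 + seed))
            label = labels[seed % len(labels)]
            spec = scenario_from_label(label)
            expected = [occupancy_oracle(p, spec) for p in cohort.patients]
            res = bed_days(cohort, spec)
            assert res.per_patient_bd == expected


class TestStatistics:
    def test_normalize(self, fixture_cohort):
        cur = bed_days(fixture_cohort, scenario_from_label("Current"))
        res = normalize(bed_days(fixture_cohort, scenario_from_label("SE2")), cur)
        assert res.normalized_fraction == pytest.approx(res.total_bd / cur.total_bd)
        with pytest.raises(ValueError):
            empty = bed_days(
                one_patient_cohort(make_patient()), scenario_from_label("SE3"))
            normalize(cur, empty)

    def test_bootstrap_ci_reproducible_and_ordered(self, fixture_cohort):
        lo1, hi1 = bootstrap_ci(fixture_cohort, scenario_from_label("SE2"),
                                n_boot=300, seed=5)
        lo2, hi2 = bootstrap_ci(fixture_cohort, scenario_from_label("SE2"),
                                n_boot=300, seed=5)
        assert (lo1, hi1) == (lo2, hi2)
        assert lo1 < hi1
        cur = bed_days(fixture_cohort, scenario_from_label("Current"))
        frac = normalize(
            bed_days(fixture_cohort, scenario_from_label("SE2")), cur
        ).normalized_fraction
        assert lo1 < frac < hi1

    def test_identical_scenarios_not_significant(self, fixture_cohort):
        out = compare_scenarios(fixture_cohort, scenario_from_label("SE2"),
                                scenario_from_label("SE2"))
        assert out["p_value"] == 1.0

    def test_different_scenarios_significant(self, fixture_cohort):
        out = compare_scenarios(fixture_cohort, scenario_from_label("Current"),
                                scenario_from_label("SE2"))
        assert out["p_value"] < 1e-6

    def test_compare_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 2, 80)
        b = rng.normal(13, 2, 80)
        assert compare_groups(a, b)["p_value"] < 1e-4
        assert compare_groups(a, a)["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_scenario_suite_table(self, fixture_cohort):
        suite = scenario_suite(fixture_cohort, n_boot=50, seed=0)
        assert list(suite["scenario"]) == list(SCENARIO_LABELS)
        assert suite.loc[0, "fraction"] == 1.0
        assert (suite["fraction"] <= 1.0 + 1e-12).all()
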