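import numpy as np
import pandas as pd
import pytest

from carbsafe.trial import (
    MEAL_PLAN,
    CarbCountingTrial,
    TrialConfig,
    analyze_outcomes,
    build_schedule,
    run_experiment,
)


@pytest.fixture(scope="module")
def mini_patients(calibrated_roster):
    wanted = {"Adult#1", "Child#4"}
    return [p for p in calibrated_roster if p.id in wanted]


@pytest.fixture(scope="module")
def mini_results(mini_patients):
    config = TrialConfig(days=3, experiments=("E0", "E1", "E8"), master_seed=5, n_resamples=500)
    return CarbCountingTrial(mini_patients, config).run()


class TestBuildSchedule:
    def test_adult_single_day(self):
        slots = build_schedule("adult", 1)
        assert [s.cho_true for s in slots] == [30, 45, 30, 45, 15]
        assert [s.clock for s in slots] == ["08:00", "12:00", "16:00", "20:00", "00:00"]
        assert [s.t_min for s in slots] == [0, 240, 480, 720, 960]

    def test_child_90_days_total_grams(self):
        slots = build_schedule("child", 90)
        assert len(slots) == 450
        assert sum(s.cho_true for s in slots) == 90 * 135

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            build_schedule("adult", 0)
        with pytest.raises(ValueError):
            build_schedule("martian", 1)


class TestConfigValidation:
    def test_control_is_mandatory(self):
        with pytest.raises(ValueError):
            TrialConfig(experiments=("E1", "E2"))

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(experiments=("E0", "E11"))

    def test_days_must_be_positive(self):
        with pytest.raises(ValueError):
            TrialConfig(days=0)


class TestRunExperiment:
    def test_meal_count_conservation(self, mini_patients):
        config = TrialConfig(days=4, experiments=("E0", "E8"), master_seed=1)
        for experiment in config.experiments:
            _, _, events = run_experiment(mini_patients[0], experiment, config)
            assert len(events) == 4 * 5

    def test_control_has_no_errors(self, mini_patients):
        config = TrialConfig(days=2, experiments=("E0",), master_seed=1)
        _, _, events = run_experiment(mini_patients[0], "E0", config)
        assert all(ev.delta_cho == 0.0 for ev in events)
        assert all(ev.cho_estimated == ev.cho_true for ev in events)

    def test_boluses_follow_the_calculator(self, mini_patients):
        patient = mini_patients[0]
        config = TrialConfig(days=2, experiments=("E0", "E8"), master_seed=3)
        _, _, events = run_experiment(patient, "E8", config)
        for ev in events:
            expected = max(
                0.0,
                ev.cho_estimated / patient.therapy.icr
                + (ev.g_preprandial - 100.0) / patient.therapy.isf,
            )
            assert ev.bolus == pytest.approx(expected)

    def test_uncalibrated_patient_rejected(self, roster):
        with pytest.raises(ValueError):
            run_experiment(roster[0], "E0", TrialConfig(days=1))

    def test_deterministic(self, mini_patients):
        config = TrialConfig(days=2, master_seed=11)
        a, _, _ = run_experiment(mini_patients[1], "E4", config)
        b, _, _ = run_experiment(mini_patients[1], "E4", config)
        assert a == b


class TestTrialResults:
    def test_outcome_table_shape(self, mini_results):
        assert len(mini_results.outcomes) == 2 * 3
        assert set(mini_results.outcomes.experiment) == {"E0", "E1", "E8"}
        assert set(mini_results.outcomes.columns) >= {
            "patient_id", "cohort", "experiment", "tir", "tar", "tbr",
        }

    def test_meal_log_shape_and_control_rows(self, mini_results):
        log = mini_results.meal_log
        assert len(log) == 2 * 3 * 15
        control = log[log.experiment == "E0"]
        assert (control.delta_cho == 0.0).all()
        assert (control.cho_estimated == control.cho_true).all()

    def test_comparisons_cover_non_control_experiments(self, mini_results):
        comp = mini_results.comparisons
        assert set(comp.experiment) == {"E1", "E8"}
        assert set(comp.stratum) <= {"tir_100", "tir_90"}
        assert (comp.ci_low <= comp.mean_diff + 1e-12).all()
        assert (comp.mean_diff <= comp.ci_high + 1e-12).all()

    def test_summary_mentions_experiments(self, mini_results):
        text = mini_results.summary()
        assert "E8" in text and "2 patients" in text

    def test_control_only_trial_has_no_comparisons(self, mini_patients):
        config = TrialConfig(days=1, experiments=("E0",), master_seed=2)
        res = CarbCountingTrial(mini_patients, config).run()
        assert res.comparisons.empty
        assert len(res.outcomes) == 2

    def test_save_writes_expected_files(self, mini_results, tmp_path):
        mini_results.save(tmp_path, figures=False)
        for name in ("metrics.csv", "comparisons.csv", "meal_log.csv", "manifest.json"):
            assert (tmp_path / name).exists()
        back = pd.read_csv(tmp_path / "metrics.csv")
        assert len(back) == len(mini_results.outcomes)


class TestAnalyzeOutcomes:
    def test_exclusion_and_strata_on_synthetic_table(self):
        rows = []
        for pid, tir0 in [("a", 100.0), ("b", 95.0), ("c", 80.0)]:
            for exp, shift in [("E0", 0.0), ("E1", -2.0)]:
                tir = tir0 + shift
                rows.append(
                    {
                        "patient_id": pid, "cohort": "adult", "experiment": exp,
                        "tir": tir, "tar": 100.0 - tir, "tbr": 0.0,
                        "pct_below_50": 0.0, "pct_above_300": 0.0,
                    }
                )
        config = TrialConfig(days=1, experiments=("E0", "E1"), master_seed=0, n_resamples=200)
        comp = analyze_outcomes(pd.DataFrame(rows), config)
        tir90 = comp[(comp.stratum == "tir_90") & (comp.metric == "tir")]
        assert (tir90.n_subjects == 2).all()  # subject c excluded
        assert tir90.mean_diff.iloc[0] == pytest.approx(-2.0)


class TestFullStudyPattern:
    """Qualitative pattern of the full 90-day study on the reference roster."""

    def chain_shifts(self, results, chain):
        outcomes = results.outcomes
        control = outcomes[outcomes.experiment == "E0"].set_index("patient_id")["tir"]
        retained = sorted(results.strata["retained"])
        shifts = []
        for experiment in chain:
            exp = outcomes[outcomes.experiment == experiment].set_index("patient_id")
            shifts.append(float(np.abs(exp.loc[retained, "tir"] - control.loc[retained]).mean()))
        return shifts

    @pytest.mark.parametrize(
        "chain", [("E2", "E4", "E6", "E8"), ("E3", "E5", "E7", "E9")],
        ids=["underestimation", "overestimation"],
    )
    def test_degradation_grows_along_error_chains(self, full_results, chain):
        shifts = self.chain_shifts(full_results, chain)
        inversions = [max(0.0, a - b) for a, b in zip(shifts, shifts[1:])]
        violating = [v for v in inversions if v > 0.0]
        assert len(violating) <= 1
        assert all(v <= 0.5 for v in violating), (chain, shifts)

    def test_every_cell_logs_450_meals(self, full_results):
        per_cell = full_results.meal_log.groupby(["patient_id", "experiment"]).size()
        assert (per_cell == 450).all()
        assert len(per_cell) == 33 * 10
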