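import numpy as np
import pytest
from dataclasses import replace

from carbsafe.dosing import TherapyParams
from carbsafe.simulator import (
    CalibrationError,
    GlucoseTrace,
    TEMPLATE_PARAMS,
    calibrate_patient,
    measure_isf,
    measure_meal_recovery,
    simulate_response,
    steady_state_basal,
)

ADULT_MEAN = TherapyParams(icr=15.9, isf=42.2)


@pytest.fixture(scope="module")
def adult_params():
    return calibrate_patient(ADULT_MEAN, basal_rate=1.2, reference_meal=45.0, peak_target=179.5)


class TestSimulateResponse:
    def test_equilibrium_is_flat(self, adult_params):
        basal = adult_params.basal_equilibrium_rate
        trace = simulate_response(adult_params, basal, [], [], 1440, adult_params.g_b)
        assert np.max(np.abs(trace.g - adult_params.g_b)) < 1.0

    def test_cgm_grid_has_288_samples_per_day(self, adult_params):
        basal = adult_params.basal_equilibrium_rate
        for days in (1, 3):
            trace = simulate_response(adult_params, basal, [], [], days * 1440, 100.0)
            assert len(trace) == days * 288

    def test_exact_meal_dosing_returns_to_target(self, adult_params):
        basal = adult_params.basal_equilibrium_rate
        trace = simulate_response(
            adult_params, basal, [(0.0, 45.0)], [(0.0, 45.0 / ADULT_MEAN.icr)], 1440, 100.0
        )
        window = trace.g[(trace.t >= 120) & (trace.t <= 180)]
        # the trajectory must come back to target inside the 2-3 h window
        assert np.min(np.abs(window - 100.0)) <= 15.0
        assert trace.g[trace.t == 150][0] == pytest.approx(100.0, abs=15.0)

    def test_larger_bolus_lowers_glucose_pointwise(self, adult_params):
        basal = adult_params.basal_equilibrium_rate
        meal = [(0.0, 45.0)]
        small = simulate_response(adult_params, basal, meal, [(0.0, 2.0)], 720, 100.0)
        large = simulate_response(adult_params, basal, meal, [(0.0, 3.0)], 720, 100.0)
        assert np.all(large.g <= small.g + 1e-9)

    def test_meal_mass_conservation(self):
        # with glucose effectiveness and insulin action turned to ~zero, the
        # terminal glucose rise times the distribution volume must equal the
        # bioavailable meal mass
        inert = replace(TEMPLATE_PARAMS, p1=1e-9, si=1e-12)
        basal = inert.basal_equilibrium_rate
        trace = simulate_response(inert, basal, [(0.0, 50.0)], [], 2880, 100.0)
        absorbed = (trace.g[-1] - 100.0) * inert.v_g
        assert absorbed == pytest.approx(50.0 * 1000.0 * inert.bioavail, rel=0.01)

    def test_bad_horizon_rejected(self, adult_params):
        with pytest.raises(ValueError):
            simulate_response(adult_params, 1.2, [], [], 7, 100.0)
        with pytest.raises(ValueError):
            simulate_response(adult_params, 1.2, [(2000.0, 30.0)], [], 1440, 100.0)


class TestGlucoseTrace:
    def test_grid_must_be_uniform_5min(self):
        with pytest.raises(ValueError):
            GlucoseTrace(t=np.array([0.0, 5.0, 11.0]), g=np.array([100.0, 100.0, 100.0]))

    def test_nonpositive_glucose_rejected(self):
        with pytest.raises(ValueError):
            GlucoseTrace(t=np.array([0.0, 5.0]), g=np.array([100.0, -1.0]))


class TestCalibration:
    def test_realizes_assigned_isf(self, adult_params):
        measured = measure_isf(adult_params, dose=30.0 / ADULT_MEAN.isf)
        assert measured == pytest.approx(ADULT_MEAN.isf, rel=0.02)

    def test_exact_dose_recovery_and_peak_anchor(self, adult_params):
        g150, peak = measure_meal_recovery(adult_params, ADULT_MEAN, grams=45.0)
        assert g150 == pytest.approx(100.0, abs=2.0)
        assert peak == pytest.approx(179.5, abs=0.5)

    def test_deterministic(self):
        a = calibrate_patient(ADULT_MEAN, basal_rate=1.2)
        b = calibrate_patient(ADULT_MEAN, basal_rate=1.2)
        assert a == b

    def test_insulin_gain_tracks_sensitivity_factor(self):
        # a more insulin-sensitive patient (larger ISF) needs a larger
        # per-unit action gain for the same realized drop per unit
        lo = calibrate_patient(TherapyParams(15.9, 42.2), basal_rate=1.2)
        hi = calibrate_patient(TherapyParams(15.9, 84.4), basal_rate=1.2)
        assert hi.si > lo.si

    def test_fidelity_across_roster(self, calibrated_roster):
        from carbsafe.trial import MEAL_PLAN

        for p in calibrated_roster:
            measured = measure_isf(p.model_params, dose=30.0 / p.therapy.isf)
            assert measured == pytest.approx(p.therapy.isf, rel=0.02), p.id
            g150, _ = measure_meal_recovery(
                p.model_params, p.therapy, grams=max(MEAL_PLAN[p.cohort])
            )
            assert abs(g150 - 100.0) <= 5.0, p.id


class TestSteadyStateBasal:
    def test_recovers_equilibrium_rate(self, adult_params):
        basal = steady_state_basal(adult_params, adult_params.g_b)
        assert basal == pytest.approx(adult_params.basal_equilibrium_rate, abs=0.1)
        trace = simulate_response(adult_params, basal, [], [], 2880, adult_params.g_b)
        assert np.max(np.abs(trace.g - adult_params.g_b)) <= 2.0

    def test_higher_clearance_needs_more_basal(self, adult_params):
        faster = replace(adult_params, i_clear=2.0 * adult_params.i_clear)
        assert steady_state_basal(faster, 100.0) > steady_state_basal(adult_params, 100.0)

    def test_insensitive_patient_has_no_bracketing_basal(self, adult_params):
        numb = replace(adult_params, si=1e-12)
        with pytest.raises(CalibrationError):
            steady_state_basal(numb, 90.0)


class TestCgmNoise:
    def test_noise_statistics_and_reproducibility(self, adult_params):
        from carbsafe.simulator import add_cgm_noise

        basal = adult_params.basal_equilibrium_rate
        trace = simulate_response(adult_params, basal, [], [], 10 * 1440, adult_params.g_b)
        noisy = add_cgm_noise(trace, sd=5.0, rho=0.7, seed=3)
        again = add_cgm_noise(trace, sd=5.0, rho=0.7, seed=3)
        assert np.array_equal(noisy.g, again.g)
        resid = noisy.g - trace.g
        assert np.std(resid) == pytest.approx(5.0, rel=0.15)
        lag1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert lag1 == pytest.approx(0.7, abs=0.05)

    def test_invalid_noise_parameters_rejected(self, adult_params):
        from carbsafe.simulator import add_cgm_noise

        basal = adult_params.basal_equilibrium_rate
        trace = simulate_response(adult_params, basal, [], [], 1440, adult_params.g_b)
        with pytest.raises(ValueError):
            add_cgm_noise(trace, sd=-1.0)
        with pytest.raises(ValueError):
            add_cgm_noise(trace, rho=1.0)
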