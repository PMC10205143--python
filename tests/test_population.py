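"""Synthetic cohort and plant: distributions, dynamics, disturbances."""

import numpy as np
import pytest

import ippid as ip
from ippid.population import (PopulationConfig, dawn_bump, robust_shift,
                              population_from_frame, population_to_frame)


class TestMakePopulation:
    def test_dispersion_zero_reproduces_average_tf(self, avg_patient):
        assert avg_patient.tf.poles == pytest.approx(
            (0.9887, 0.8353 + 0.1949j, 0.8353 - 0.1949j))
        assert avg_patient.tf.gain == pytest.approx(-0.0769)

    def test_deterministic_given_seed(self):
        a = ip.make_population(20, seed=5)
        b = ip.make_population(20, seed=5)
        for x, y in zip(a, b):
            assert x == y

    def test_cohort_invariants(self, cohort):
        assert len(cohort) == 100
        cfg = PopulationConfig()
        for p in cohort:
            assert p.tf.is_stable
            assert p.tf.gain < 0
            assert all(0 < c <= cfg.cr_max for c in p.crs)
            assert 0 < p.tdi <= cfg.tdi_max
            assert p.basal_rate > 0
            # CR anchored to the gain ratio: more sensitive => higher CR
        kappas = [p.tf.gain / -0.0769 for p in cohort]
        crs = [np.mean(p.crs) for p in cohort]
        assert np.corrcoef(kappas, crs)[0, 1] > 0.5

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            ip.make_population(0, seed=1)


class TestPlant:
    def test_zero_insulin_equilibrium(self, avg_patient):
        """No insulin, no meals, dawn off: G stays at the open-loop
        equilibrium implied by the endogenous term."""
        plant = ip.Plant(avg_patient)
        st = plant.steady_state(0.0)
        g0 = avg_patient.equilibrium_glucose
        for _ in range(200):
            st, g = ip.plant_step(st, plant, 0.0, 1.0, 0.0, g0)
        assert g == pytest.approx(g0, abs=1e-9)

    def test_constant_insulin_dc_deviation(self, avg_patient):
        """1 U/h sustained lowers glucose by the TF DC gain ~ -104.5 mg/dl."""
        plant = ip.Plant(avg_patient)
        st = plant.steady_state(0.0)
        g0 = st.G
        for _ in range(40000):
            st, g = ip.plant_step(st, plant, 1.0, 1.0, 0.0,
                                  avg_patient.equilibrium_glucose)
        assert g - g0 == pytest.approx(-104.5, abs=0.1)

    def test_five_minute_sampling_matches_arx_recursion(self, avg_patient):
        """The 30-s modal plant sampled every 5 min reproduces the ARX
        difference equation exactly (oracle: direct evaluation)."""
        plant = ip.Plant(avg_patient, dt=0.5)
        st = plant.steady_state(0.0)
        rng = np.random.default_rng(3)
        u = rng.uniform(0, 2, 60)
        g5 = [st.G]
        for rate in u:
            for _ in range(10):
                st, g = ip.plant_step(st, plant, float(rate), 1.0, 0.0,
                                      avg_patient.equilibrium_glucose)
            g5.append(g)
        # oracle: y(k) = -a1 y(k-1) - a2 y(k-2) - a3 y(k-3) + b u(k-3), deviations
        a1, a2, a3 = avg_patient.tf.a
        b = avg_patient.tf.gain
        y = np.zeros(len(u) + 1)
        for k in range(1, len(y)):
            y[k] = (-a1 * y[k - 1]
                    - (a2 * y[k - 2] if k >= 2 else 0.0)
                    - (a3 * y[k - 3] if k >= 3 else 0.0)
                    + (b * u[k - 3] if k >= 3 else 0.0))
        dev = np.array(g5) - avg_patient.equilibrium_glucose
        assert dev == pytest.approx(y, abs=1e-8)

    def test_superposition_of_insulin_and_meal(self, avg_patient):
        """Linear core: response to insulin+meal = sum of separate responses."""
        plant = ip.Plant(avg_patient)
        ra = ip.meal_response(60.0, avg_patient)
        g0 = avg_patient.equilibrium_glucose

        def run(rate, with_meal):
            st = plant.steady_state(0.0)
            base = st.G
            out = []
            for j in range(600):
                m = ra[j] if (with_meal and j < ra.size) else 0.0
                st, g = ip.plant_step(st, plant, rate, 1.0, m, g0)
                out.append(g - base)
            return np.array(out)

        both = run(1.5, True)
        insulin_only = run(1.5, False)
        meal_only = run(0.0, True)
        assert both == pytest.approx(insulin_only + meal_only, abs=1e-9)

    def test_nonnegative_insulin_enforced(self, avg_patient):
        plant = ip.Plant(avg_patient)
        st = plant.steady_state(0.0)
        with pytest.raises(ValueError):
            ip.plant_step(st, plant, -1.0, 1.0, 0.0, 100.0)


class TestMealResponse:
    def test_zero_grams_zero_curve(self, avg_patient):
        assert np.all(ip.meal_response(0.0, avg_patient) == 0.0)

    def test_linearity_in_grams(self, avg_patient):
        c80 = ip.meal_response(80.0, avg_patient)
        c40 = ip.meal_response(40.0, avg_patient)
        assert c80 == pytest.approx(2.0 * c40)

    def test_unimodal_nonnegative_peak_calibration(self, avg_patient):
        c = ip.meal_response(60.0, avg_patient)
        assert np.all(c >= 0)
        peak = np.argmax(c)
        assert np.all(np.diff(c[:peak + 1]) >= 0)
        assert np.all(np.diff(c[peak:]) <= 0)
        assert c.max() == pytest.approx(60.0 * avg_patient.meal_gain, rel=1e-3)

    def test_open_loop_meal_excursion_in_physiologic_band(self, avg_patient):
        """60 g under basal insulin raises glucose by 40-180 mg/dl at peak."""
        plant = ip.Plant(avg_patient)
        st = plant.steady_state(avg_patient.basal_rate)
        base = st.G
        ra = ip.meal_response(60.0, avg_patient)
        peak = base
        for j in range(1200):
            m = ra[j] if j < ra.size else 0.0
            st, g = ip.plant_step(st, plant, avg_patient.basal_rate, 1.0, m,
                                  avg_patient.equilibrium_glucose)
            peak = max(peak, g)
        assert 40.0 <= peak - base <= 180.0

    def test_negative_grams_rejected(self, avg_patient):
        with pytest.raises(ValueError):
            ip.meal_response(-1.0, avg_patient)


class TestSensitivityPath:
    def test_zero_noise_equals_smoothed_nominal(self, avg_patient):
        cfg = PopulationConfig(si_noise_sd=0.0)
        p1 = ip.sensitivity_path(avg_patient, 0, "standard", 1, config=cfg)
        p2 = ip.sensitivity_path(avg_patient, 5, "standard", 9, config=cfg)
        assert p1.values == pytest.approx(p2.values)
        assert min(avg_patient.si_nominal) - 1e-9 <= p1.values.min()
        assert p1.values.max() <= max(avg_patient.si_nominal) + 1e-9

    def test_daily_multiplier_coverage_of_pm40_band(self):
        """Gaussian(1, 0.2) daily draws land in [0.6, 1.4] ~95.45% of the time."""
        rng = np.random.default_rng(7)
        draws = 1.0 + 0.2 * rng.standard_normal(10 ** 6)
        frac = np.mean((draws >= 0.6) & (draws <= 1.4))
        assert frac == pytest.approx(0.9545, abs=0.001)

    def test_path_is_smooth(self, avg_patient):
        path = ip.sensitivity_path(avg_patient, 2, "standard", 3)
        # no step discontinuities at the smoothing scale: bounded increments
        assert np.max(np.abs(np.diff(path.values))) < 0.01

    def test_robust_is_constant_multiple_of_standard(self, avg_patient):
        std = ip.sensitivity_path(avg_patient, 4, "standard", 11)
        rob = ip.sensitivity_path(avg_patient, 4, "robust", 11)
        ratio = rob.values / std.values
        assert np.ptp(ratio) < 1e-9
        assert 0.7 <= ratio[0] <= 1.3

    def test_robust_shift_fixed_across_days(self, avg_patient):
        assert robust_shift(avg_patient, 13) == robust_shift(avg_patient, 13)
        r0 = ip.sensitivity_path(avg_patient, 0, "robust", 13)
        r9 = ip.sensitivity_path(avg_patient, 9, "robust", 13)
        s0 = ip.sensitivity_path(avg_patient, 0, "standard", 13)
        s9 = ip.sensitivity_path(avg_patient, 9, "standard", 13)
        assert r0.values / s0.values == pytest.approx(r9.values / s9.values)

    def test_sample_moments_over_many_days(self, avg_patient):
        """Meal-time multipliers over many days: mean ~1, sd ~0.2."""
        draws = []
        for day in range(400):
            path = ip.sensitivity_path(avg_patient, day, "standard", 17)
            # read the multiplier at the lunch segment center (14:00)
            mid = int(14 * 60 / path.dt)
            draws.append(path.values[mid] / avg_patient.si_nominal[1])
        assert np.mean(draws) == pytest.approx(1.0, abs=0.05)
        assert np.std(draws) == pytest.approx(0.2, abs=0.05)


def test_dawn_bump_confined_to_window():
    t = np.arange(0, 1440.0, 0.5)
    bump = dawn_bump(t)
    inside = (t >= 240) & (t < 480)
    assert np.all(bump[~inside] == 0)
    assert bump.max() == pytest.approx(1.0, abs=1e-6)


def test_population_csv_roundtrip(cohort):
    df = population_to_frame(cohort[:10])
    back = population_from_frame(df)
    for a, b in zip(cohort[:10], back):
        assert a.tf.gain == pytest.approx(b.tf.gain)
        assert a.crs == pytest.approx(b.crs)
        assert a.tdi == pytest.approx(b.tdi)
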