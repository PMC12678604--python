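import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sprintergetics as sg
from sprintergetics.cost_power import PowerSeries
from sprintergetics.metabolic_model import (
    MEN_PARAMS,
    WOMEN_PARAMS,
    ModelAmplitudes,
    PathwayParams,
    biexp_peak_time,
)


def _grid_knorm(k1, k2):
    """Independent oracle: normalization constant by dense grid maximization."""
    t = np.linspace(1e-4, 40 * k1 + 3 * k2, 400_000)
    shape = (1.0 - np.exp(-t / k1)) * np.exp(-t / k2)
    return 1.0 / shape.max()


class TestKnorm:
    @pytest.mark.parametrize(
        "k1, k2, t_star, k_norm",
        [
            (2.75, 35.0, 7.2035, 1.3250),  # frozen from the grid oracle
            (20.0, 1500.0, 86.6147, 1.07357),
        ],
    )
    def test_analytic_against_frozen_oracle_values(self, k1, k2, t_star, k_norm):
        assert biexp_peak_time(k1, k2) == pytest.approx(t_star, abs=1e-3)
        assert sg.knorm(k1, k2) == pytest.approx(k_norm, abs=1e-4)

    def test_analytic_matches_grid_maximization(self):
        for k1, k2 in [(2.75, 35.0), (1.0, 5.0), (10.0, 200.0)]:
            assert sg.knorm(k1, k2) == pytest.approx(_grid_knorm(k1, k2), rel=1e-6)

    def test_equal_constants_peak_at_k_ln2(self):
        # limiting case k1 == k2: peak time k * ln 2
        k = 4.0
        assert biexp_peak_time(k, k) == pytest.approx(k * np.log(2.0))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(k1=st.floats(0.5, 50.0), ratio=st.floats(1.1, 100.0))
    def test_lactic_peak_equals_amplitude(self, k1, ratio):
        """Normalization: the glycolytic pulse maximum equals its amplitude."""
        k2 = k1 * ratio
        params = PathwayParams(k1=k1, k2=k2)
        ts = biexp_peak_time(k1, k2)
        assert sg.lactic_power(ts, 47.6, params) == pytest.approx(47.6, rel=1e-9)
        t = np.linspace(0, 5 * ts, 5000)
        assert sg.lactic_power(t, 47.6, params).max() == pytest.approx(47.6, rel=1e-6)


class TestAerobic:
    def test_power_rise(self):
        assert sg.aerobic_power(0.0, MEN_PARAMS) == 0.0
        one_tc = (24.5 - 1.2) * (1 - np.exp(-1))
        assert sg.aerobic_power(23.0, MEN_PARAMS) == pytest.approx(one_tc)
        assert sg.aerobic_power(1e4, WOMEN_PARAMS) == pytest.approx(19.8)

    @pytest.mark.parametrize("T, expected, tol", [(9.43, 40.0, 1.0), (43.91, 566.0, 1.0)])
    def test_energy_closed_form_published_values(self, T, expected, tol):
        assert abs(sg.aerobic_energy(T, MEN_PARAMS) - expected) < tol

    def test_energy_matches_numeric_integral(self):
        T = 19.04
        t = np.linspace(0, T, 20000)
        numeric = np.trapezoid(sg.aerobic_power(t, MEN_PARAMS), t)
        assert sg.aerobic_energy(T, MEN_PARAMS) == pytest.approx(numeric, rel=1e-6)

    def test_map_must_exceed_bmr(self):
        with pytest.raises(ValueError):
            PathwayParams(maximal_aerobic_power=1.0)


class TestAlactic:
    def test_zero_limit_and_peak_location(self):
        assert sg.alactic_power(0.0, 137.7, MEN_PARAMS) == 0.0
        assert sg.alactic_power(1e-9, 137.7, MEN_PARAMS) == pytest.approx(0.0, abs=1e-12)
        t_peak = np.exp(MEN_PARAMS.mu_al)
        assert sg.alactic_power(t_peak, 137.7, MEN_PARAMS) == pytest.approx(137.7)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(mu=st.floats(-1.0, 2.0), sigma=st.floats(0.3, 2.0))
    def test_peak_at_exp_mu_by_grid_search(self, mu, sigma):
        params = PathwayParams(mu_al=mu, sigma_al=sigma)
        t = np.geomspace(1e-3, 50.0, 20000)
        p = sg.alactic_power(t, 100.0, params)
        assert t[np.argmax(p)] == pytest.approx(np.exp(mu), rel=1e-3)
        assert p.max() == pytest.approx(100.0, rel=1e-6)

    def test_log_normal_value(self):
        # one ln-unit from the peak with sigma=0.4: exp(-1/(2*0.16)) of the amplitude
        params = PathwayParams(mu_al=1.0, sigma_al=0.4)
        assert sg.alactic_power(1.0, 1.0, params) == pytest.approx(
            np.exp(-1.0 / 0.32), rel=1e-9
        )


class TestTotalPowerAndFit:
    def test_additivity(self):
        amps = ModelAmplitudes(100.0, 40.0)
        t = np.linspace(0, 10, 101)
        total = sg.total_power(t, amps, MEN_PARAMS)
        parts = (
            sg.alactic_power(t, 100.0, MEN_PARAMS)
            + sg.lactic_power(t, 40.0, MEN_PARAMS)
            + sg.aerobic_power(t, MEN_PARAMS)
        )
        np.testing.assert_allclose(total, parts, rtol=1e-12)
        assert sg.total_power(0.0, amps, MEN_PARAMS) == 0.0

    def test_fit_recovers_self_generated_amplitudes_exactly(self):
        t = np.linspace(0.0, 9.43, 944)
        true = ModelAmplitudes(100.0, 40.0)
        series = PowerSeries.from_samples(
            t, sg.total_power(t, true, MEN_PARAMS), source="from_model"
        )
        est = sg.fit_amplitudes(series, MEN_PARAMS)
        assert est.p_al_max == pytest.approx(100.0, rel=1e-10)
        assert est.p_la_max == pytest.approx(40.0, rel=1e-10)
        assert est.adjusted_r2 == pytest.approx(1.0, abs=1e-12)

    def test_fit_unbiased_under_noise(self):
        """Gaussian noise (sd 5 W/kg), 200 seeds: mean amplitude error < 1%."""
        t = np.linspace(0.01, 9.43, 400)
        true = ModelAmplitudes(137.7, 47.6)
        clean = sg.total_power(t, true, MEN_PARAMS)
        als, las = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = np.clip(clean + rng.normal(0, 5.0, clean.shape), 0, None)
            est = sg.fit_amplitudes(
                PowerSeries.from_samples(t, noisy, source="from_model"), MEN_PARAMS
            )
            als.append(est.p_al_max)
            las.append(est.p_la_max)
        assert abs(np.mean(als) / true.p_al_max - 1) < 0.01
        assert abs(np.mean(las) / true.p_la_max - 1) < 0.01

    def test_fit_rejects_zero_series(self):
        t = np.linspace(0, 5, 50)
        series = PowerSeries.from_samples(t, np.zeros_like(t), source="from_model")
        with pytest.raises(ValueError):
            sg.fit_amplitudes(series, MEN_PARAMS)

    def test_fit_to_berlin_power_matches_published_amplitudes(self, men100_power):
        """Published men's 100 m fit: P_al,max 137.7, P_la,max 47.6, adj R^2 0.95."""
        est = sg.fit_amplitudes(men100_power, MEN_PARAMS)
        assert est.p_al_max == pytest.approx(137.7, rel=0.03)
        assert est.p_la_max == pytest.approx(47.6, rel=0.05)
        assert est.adjusted_r2 == pytest.approx(0.95, abs=0.02)


class TestPathwayEnergies:
    def test_total_equals_integral_of_total_power(self):
        amps = ModelAmplitudes(137.7, 47.6)
        T = 9.43
        energies = sg.pathway_energies(amps, MEN_PARAMS, T)
        n = int(round(T / 0.01))
        t = np.linspace(0, T, n + 1)
        integral = np.trapezoid(sg.total_power(t, amps, MEN_PARAMS), t)
        assert energies["total"] == pytest.approx(integral, rel=1e-9)

    def test_published_event_energies(self, catalogue):
        """Published amplitudes reproduce the per-event pathway energies."""
        for key, T in [("men_100", 9.43), ("men_400", 43.91), ("women_100", 10.58)]:
            p_al, p_la = catalogue["model_amplitudes"][key]
            sex = "f" if key.startswith("women") else "m"
            params = WOMEN_PARAMS if sex == "f" else MEN_PARAMS
            expected = catalogue["pathway_energies"][key]
            got = sg.pathway_energies(ModelAmplitudes(p_al, p_la), params, T)
            assert got["alactic"] == pytest.approx(expected["alactic"], abs=2.0)
            assert got["lactic"] == pytest.approx(expected["lactic"], abs=4.0)
            assert got["aerobic"] == pytest.approx(expected["aerobic"], abs=1.0)

    def test_zero_amplitudes_leave_aerobic_only(self):
        energies = sg.pathway_energies(ModelAmplitudes(0.0, 0.0), MEN_PARAMS, 9.43)
        assert energies["alactic"] == 0.0
        assert energies["lactic"] == 0.0
        assert energies["total"] == pytest.approx(energies["aerobic"])
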