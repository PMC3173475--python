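"""Generator correctness: determinism, closed forms, and oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from protstab import (
    GroundTruth,
    gen_eyring_series,
    gen_isotherm,
    gen_melt,
    gen_saxs_body,
    gen_trace,
    guinier_fit,
    ift_pr,
    sequential_uin_populations,
)
from protstab.kinetics import eyring_ln_rate


class TestDeterminism:
    def test_same_seed_bit_identical(self, apo_isotherm_truth):
        t = GroundTruth("isotherm", apo_isotherm_truth.params, noise_sd=0.05, seed=42)
        a = gen_isotherm(t)
        b = gen_isotherm(t)
        assert np.array_equal(a.signal, b.signal)

    def test_different_seeds_same_truth_independent_noise(self, apo_isotherm_truth):
        t = GroundTruth("isotherm", apo_isotherm_truth.params, noise_sd=0.05, seed=1)
        a = gen_isotherm(t)
        b = gen_isotherm(t, seed=2)
        assert not np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.denaturant, b.denaturant)

    def test_invalid_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth("unknown_kind", {})
        with pytest.raises(ValueError):
            GroundTruth("isotherm", {}, noise_sd=-1.0)


class TestIsotherm:
    def test_signal_at_midpoint_is_exact_endpoint_mean(self, apo_isotherm_truth):
        p = dict(apo_isotherm_truth.params)
        cm = p["dG0"] / p["m"]
        grid = np.sort(np.append(p["denaturant_grid"], cm))
        p["denaturant_grid"] = grid
        iso = gen_isotherm(GroundTruth("isotherm", p))
        i = int(np.searchsorted(grid, cm))
        mid = 0.5 * (p["signal_native"] + p["signal_denatured"])
        assert iso.signal[i] == pytest.approx(mid, abs=1e-12)

    def test_transition_centered_near_independent_cm(self, apo_isotherm_truth):
        """Half-signal crossing located by interpolation ≈ ΔG°/m = 1.186 M."""
        iso = gen_isotherm(apo_isotherm_truth)
        half = 0.5 * (iso.signal[0] + iso.signal[-1])
        j = np.nonzero(np.diff(np.sign(iso.signal - half)))[0][0]
        f = (half - iso.signal[j]) / (iso.signal[j + 1] - iso.signal[j])
        crossing = iso.denaturant[j] + f * (iso.denaturant[j + 1] - iso.denaturant[j])
        assert crossing == pytest.approx(3.7 / 3.12, abs=0.02)

    def test_bound_form_shifts_transition_to_higher_denaturant(
        self, apo_isotherm_truth, holo_isotherm_truth
    ):
        apo = gen_isotherm(apo_isotherm_truth)
        holo = gen_isotherm(holo_isotherm_truth)

        def crossing(iso):
            half = 0.5 * (iso.signal[0] + iso.signal[-1])
            j = np.nonzero(np.diff(np.sign(iso.signal - half)))[0][0]
            return iso.denaturant[j]

        assert crossing(holo) > crossing(apo)

    def test_grid_validation(self, apo_isotherm_truth):
        p = dict(apo_isotherm_truth.params)
        p["denaturant_grid"] = np.array([0.0, 2.0, 1.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            gen_isotherm(GroundTruth("isotherm", p))
        p = dict(apo_isotherm_truth.params, m=-1.0)
        with pytest.raises(ValueError):
            gen_isotherm(GroundTruth("isotherm", p))


class TestMelt:
    def test_inflection_at_tm(self, melt_truth):
        """Numerical second derivative changes sign at the stated Tm."""
        p = dict(melt_truth.params, temperature_grid=np.linspace(25, 90, 651))
        melt = gen_melt(GroundTruth("melt", p))
        d2 = np.gradient(np.gradient(melt.ellipticity, melt.temperature_c),
                         melt.temperature_c)
        sign_change = np.nonzero(np.diff(np.sign(d2)))[0]
        t_inflect = melt.temperature_c[sign_change[0]]
        assert t_inflect == pytest.approx(58.0, abs=0.2)

    def test_value_at_tm_is_asymptote_midpoint(self, melt_truth):
        p = dict(melt_truth.params, tm=74.0,
                 temperature_grid=np.array([25., 40., 55., 74., 80., 85., 88., 90.]))
        melt = gen_melt(GroundTruth("melt", p))
        midpoint = p["baseline"] + 0.5 * p["amplitude"]
        assert melt.ellipticity[3] == pytest.approx(midpoint, abs=1e-12)

    def test_zero_amplitude_flat(self, melt_truth):
        p = dict(melt_truth.params, amplitude=0.0)
        melt = gen_melt(GroundTruth("melt", p))
        assert np.ptp(melt.ellipticity) == 0.0

    def test_tm_outside_grid_warns(self, melt_truth):
        p = dict(melt_truth.params, tm=120.0)
        with pytest.warns(UserWarning):
            gen_melt(GroundTruth("melt", p))


class TestTrace:
    def test_sequential_zero_initial_slope(self):
        t = np.linspace(0.0, 200.0, 2000)
        tr = gen_trace(GroundTruth("trace", {
            "scheme": "sequential_UIN", "k_UI": 0.01, "k_IN": 0.1,
            "signal_native": 1.0, "t_grid": t, "direction": "refolding"}))
        initial_slope = (tr.signal[1] - tr.signal[0]) / (t[1] - t[0])
        max_slope = np.max(np.gradient(tr.signal, t))
        assert abs(initial_slope) < 0.02 * max_slope

    def test_degenerate_sequential_closed_form_and_ode_oracle(self):
        """k_UI = k_IN: N(t) = 1 - (1+kt)e^(-kt), cross-checked by ODE."""
        k = 0.05
        t = np.linspace(0.0, 150.0, 80)
        _, _, n = sequential_uin_populations(t, k, k)
        closed = 1.0 - (1.0 + k * t) * np.exp(-k * t)
        assert np.allclose(n, closed, atol=1e-10)

        def rhs(_, y):
            u, i = y
            return [-k * u, k * u - k * i]

        sol = solve_ivp(rhs, (0, 150), [1.0, 0.0], t_eval=t, rtol=1e-10, atol=1e-12)
        n_ode = 1.0 - sol.y[0] - sol.y[1]
        assert np.allclose(n, n_ode, atol=1e-7)

    def test_population_conservation(self):
        t = np.linspace(0.0, 500.0, 300)
        for k1, k2 in [(0.01, 0.1), (0.2, 0.2), (0.5, 0.03)]:
            u, i, n = sequential_uin_populations(t, k1, k2)
            assert np.max(np.abs(u + i + n - 1.0)) < 1e-12

    def test_trace_validation(self):
        t = np.linspace(0.0, 10.0, 30)
        with pytest.raises(ValueError):
            gen_trace(GroundTruth("trace", {
                "scheme": "single_exp", "rate": -1.0, "amplitude": 1.0,
                "offset": 0.0, "t_grid": t}))
        with pytest.raises(ValueError):
            gen_trace(GroundTruth("trace", {"scheme": "triple_exp", "t_grid": t}))


class TestEyringSeries:
    def test_zero_dcp_is_arrhenius_linear_in_inverse_prefactor_frame(self):
        """With ΔCp‡ = 0, ln k - ln T is exactly linear in 1/T."""
        t = np.linspace(278.0, 303.0, 12)
        s = gen_eyring_series(GroundTruth("eyring_series", {
            "dH": 20.0, "dS": 0.071, "dCp": 0.0, "T0": 298.0,
            "temperature_grid": t}))
        y = s.ln_rate - np.log(s.temperature)
        coef = np.polyfit(1.0 / t, y, 1)
        resid = y - np.polyval(coef, 1.0 / t)
        assert np.max(np.abs(resid)) < 1e-10

    def test_curvature_matches_finite_difference_of_generator(self, eyring_truth):
        """d²(ln k)/d(1/T)² of the series ≈ numerical second derivative of
        the generating expression."""
        inv_t = np.linspace(1.0 / 303.0, 1.0 / 278.0, 201)
        p = dict(eyring_truth.params, temperature_grid=(1.0 / inv_t)[::-1])
        s = gen_eyring_series(GroundTruth("eyring_series", p))
        x = 1.0 / s.temperature
        mid = 100
        h = x[mid + 1] - x[mid]
        d2_series = (s.ln_rate[mid + 1] - 2 * s.ln_rate[mid] + s.ln_rate[mid - 1]) / h**2

        def f(inv_t):
            return eyring_ln_rate(1.0 / inv_t, p["dH"], p["dS"], p["dCp"], p["T0"])

        d2_direct = (f(x[mid] + h) - 2 * f(x[mid]) + f(x[mid] - h)) / h**2
        assert d2_series == pytest.approx(d2_direct, rel=1e-6)
        # visibly curved: quadratic term dominates the linear-fit residual
        assert abs(d2_series) > 0

    def test_temperature_validation(self):
        with pytest.raises(ValueError):
            gen_eyring_series(GroundTruth("eyring_series", {
                "dH": 20.0, "dS": 0.071, "dCp": 0.0,
                "temperature_grid": np.array([-5.0, 280.0])}))


class TestSaxsBody:
    def test_sphere_guinier_relation(self, saxs_q_grid):
        body = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 30.0, "q_grid": saxs_q_grid}))
        rg = guinier_fit(body).Rg
        assert rg == pytest.approx(np.sqrt(3.0 / 5.0) * 30.0, rel=0.01)

    def test_sphere_pr_support_ends_at_diameter(self, saxs_q_grid):
        body = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 36.0, "q_grid": saxs_q_grid}))
        pr = ift_pr(body)
        assert pr.Dmax == pytest.approx(72.0, abs=2.0)

    def test_ellipsoid_recovers_both_size_parameters(self, saxs_q_grid):
        body = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "prolate_ellipsoid", "rg": 23.4, "dmax": 72.0,
            "q_grid": saxs_q_grid}))
        assert guinier_fit(body).Rg == pytest.approx(23.4, abs=2.0)
        assert ift_pr(body).Dmax == pytest.approx(72.0, abs=2.0)

    def test_sigma_column_is_stated_fraction_plus_floor(self, saxs_q_grid):
        body = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 25.0, "q_grid": saxs_q_grid,
            "sigma_frac": 0.05, "sigma_floor": 1e-8}))
        assert np.allclose(body.sigma, 0.05 * np.abs(body.intensity) + 1e-8)

    def test_nonpositive_dimension_rejected(self, saxs_q_grid):
        with pytest.raises(ValueError):
            gen_saxs_body(GroundTruth("saxs_body", {
                "body": "sphere", "radius": -3.0, "q_grid": saxs_q_grid}))


@settings(deadline=None, max_examples=25)
@given(k1=st.floats(1e-3, 1.0), k2=st.floats(1e-3, 1.0))
def test_sequential_populations_conserved_property(k1, k2):
    t = np.linspace(0.0, 50.0, 40)
    u, i, n = sequential_uin_populations(t, k1, k2)
    assert np.max(np.abs(u + i + n - 1.0)) < 1e-9
    assert np.all(u >= -1e-12) and np.all(i >= -1e-12) and np.all(n >= -1e-12)
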