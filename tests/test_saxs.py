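"""SAXS reduction: Guinier, Kratky, IFT p(r), MW, Debye model, χ²."""

import numpy as np
import pytest

from protstab import (
    AtomicModel,
    GroundTruth,
    ScatteringCurve,
    chi2_discrepancy,
    debye_intensity,
    ellipsoid_bead_model,
    gen_saxs_body,
    guinier_fit,
    ift_pr,
    kratky,
    mw_from_i0,
    resolution,
)


def sphere_pr_analytic(r, radius):
    """Closed-form pair-distance distribution of a homogeneous sphere."""
    d = 2.0 * radius
    x = np.clip(r / d, 0.0, 1.0)
    p = r**2 * (1.0 - 1.5 * x + 0.5 * x**3)
    p[r > d] = 0.0
    return p


class TestGuinier:
    def test_gaussian_curve_exact(self, saxs_q_grid):
        rg, i0 = 23.0, 7.0
        curve = ScatteringCurve(q=saxs_q_grid,
                                intensity=i0 * np.exp(-saxs_q_grid**2 * rg**2 / 3.0))
        fit = guinier_fit(curve)
        assert fit.Rg == pytest.approx(rg, rel=1e-9)
        assert fit.I0 == pytest.approx(i0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_sphere_within_one_percent(self, saxs_q_grid):
        body = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 30.0, "q_grid": saxs_q_grid}))
        fit = guinier_fit(body)
        assert fit.Rg == pytest.approx(np.sqrt(0.6) * 30.0, rel=0.01)
        assert fit.qmax_rg <= 1.3 + 1e-9

    def test_noisy_globular_body_near_truth(self, saxs_q_grid):
        body = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "prolate_ellipsoid", "rg": 23.0, "dmax": 72.0,
            "q_grid": saxs_q_grid}, noise_sd=0.02, seed=7))
        assert guinier_fit(body).Rg == pytest.approx(23.0, abs=1.5)

    def test_rising_intensity_rejected(self, saxs_q_grid):
        curve = ScatteringCurve(q=saxs_q_grid,
                                intensity=1.0 + saxs_q_grid**2)
        with pytest.raises(ValueError):
            guinier_fit(curve)

    def test_too_few_points_rejected(self):
        q = np.linspace(0.01, 0.05, 5)
        curve = ScatteringCurve(q=q, intensity=np.exp(-q**2 * 100))
        with pytest.raises(ValueError):
            guinier_fit(curve)


class TestKratky:
    def test_gaussian_peak_at_sqrt3_over_rg(self):
        rg = 23.0
        q = np.linspace(0.002, 0.3, 3000)
        curve = ScatteringCurve(q=q, intensity=np.exp(-q**2 * rg**2 / 3.0))
        qk, yk = kratky(curve)
        assert qk[np.argmax(yk)] == pytest.approx(np.sqrt(3.0) / rg, rel=1e-3)

    def test_flat_curve_monotone_increasing(self, saxs_q_grid):
        curve = ScatteringCurve(q=saxs_q_grid, intensity=np.ones(saxs_q_grid.size))
        _, yk = kratky(curve)
        assert np.all(np.diff(yk) > 0)

    def test_sphere_bell_then_decay(self, saxs_q_grid):
        body = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 30.0, "q_grid": saxs_q_grid}))
        _, yk = kratky(body)
        peak = int(np.argmax(yk))
        assert 0 < peak < yk.size - 1
        assert yk[peak] > 3.0 * yk[0]


class TestIFT:
    def test_sphere_pr_matches_analytic_and_dmax(self, saxs_q_grid):
        body = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 36.0, "q_grid": saxs_q_grid}))
        pr = ift_pr(body)
        assert pr.Dmax == pytest.approx(72.0, abs=2.0)
        ana = sphere_pr_analytic(pr.r, 36.0)
        ana /= np.trapezoid(ana, pr.r)
        est = pr.p / np.trapezoid(pr.p, pr.r)
        l2 = np.sqrt(np.trapezoid((est - ana) ** 2, pr.r)
                     / np.trapezoid(ana**2, pr.r))
        assert l2 < 0.05

    def test_hard_postconditions_on_every_output(self, saxs_q_grid):
        for body_params in (
            {"body": "sphere", "radius": 30.0},
            {"body": "prolate_ellipsoid", "rg": 23.0, "dmax": 72.0},
        ):
            body = gen_saxs_body(GroundTruth("saxs_body", {
                **body_params, "q_grid": saxs_q_grid}, noise_sd=0.02, seed=3))
            pr = ift_pr(body)
            assert pr.p[0] == 0.0
            assert pr.p[-1] == 0.0
            assert np.all(pr.p >= 0.0)
            rg_moment = np.sqrt(np.trapezoid(pr.r**2 * pr.p, pr.r)
                                / (2.0 * np.trapezoid(pr.p, pr.r)))
            assert pr.Rg_real == pytest.approx(rg_moment, rel=1e-9)

    def test_estimator_consistency_triangle(self, saxs_q_grid):
        """Guinier Rg ≈ p(r)-moment Rg ≈ coordinate Rg, pairwise within 2%."""
        model = ellipsoid_bead_model(24.0, 34.0, spacing=4.0)
        curve = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "bead_model", "model": model, "q_grid": saxs_q_grid}))
        rg_coord = model.radius_of_gyration()
        rg_guinier = guinier_fit(curve).Rg
        rg_real = ift_pr(curve).Rg_real
        assert rg_guinier == pytest.approx(rg_coord, rel=0.02)
        assert rg_real == pytest.approx(rg_coord, rel=0.02)
        assert rg_real == pytest.approx(rg_guinier, rel=0.02)

    def test_information_insufficient_q_range_rejected(self):
        q = np.linspace(0.08, 0.3, 60)  # qmin·Dmax > π for Dmax = 72
        curve = ScatteringCurve(q=q, intensity=np.exp(-q**2 * 23.0**2 / 3.0))
        with pytest.raises(ValueError):
            ift_pr(curve, dmax_trial=72.0)


class TestMolecularWeight:
    def _reference(self, q, radius, i0, conc):
        return gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": radius, "q_grid": q,
            "I0": i0, "concentration": conc}))

    def test_identity_with_reference(self, saxs_q_grid):
        bsa = self._reference(saxs_q_grid, 27.0, 2.0, 4.0)
        assert mw_from_i0(bsa, [(bsa, 66.4)]) == pytest.approx(66.4, rel=1e-6)

    def test_proportional_to_i0_over_c(self, saxs_q_grid):
        bsa = self._reference(saxs_q_grid, 27.0, 2.0, 4.0)
        half = self._reference(saxs_q_grid, 27.0, 1.0, 4.0)
        assert mw_from_i0(half, [(bsa, 66.4)]) == pytest.approx(66.4 / 2, rel=1e-6)

    def test_two_consistent_references_agree(self, saxs_q_grid):
        bsa = self._reference(saxs_q_grid, 27.0, 2.0, 4.0)
        # HEWL at the same specific I0/C per kDa as BSA
        hewl = self._reference(saxs_q_grid, 15.0, 2.0 * 14.3 / 66.4, 4.0)
        sample = self._reference(saxs_q_grid, 23.0, 2.0 * 36.7 / 66.4, 4.0)
        mw_one = mw_from_i0(sample, [(bsa, 66.4)])
        mw_both = mw_from_i0(sample, [(bsa, 66.4), (hewl, 14.3)])
        assert mw_one == pytest.approx(36.7, rel=0.01)
        assert mw_both == pytest.approx(mw_one, rel=0.01)

    def test_missing_concentration_rejected(self, saxs_q_grid):
        no_conc = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 27.0, "q_grid": saxs_q_grid}))
        with pytest.raises(ValueError):
            mw_from_i0(no_conc, [(no_conc, 66.4)])


class TestDebye:
    def test_single_site_flat(self):
        model = AtomicModel(coordinates=[[1.0, 2.0, 3.0]], weights=[3.0])
        curve = debye_intensity(model, np.linspace(0.01, 0.3, 20))
        assert np.allclose(curve.intensity, 9.0)

    def test_two_unit_sites_closed_form(self):
        d = 10.0
        model = AtomicModel(coordinates=[[0, 0, 0], [0, 0, d]], weights=[1.0, 1.0])
        q = np.linspace(0.01, 0.5, 40)
        curve = debye_intensity(model, q)
        expected = 2.0 * (1.0 + np.sin(q * d) / (q * d))
        assert np.allclose(curve.intensity, expected, rtol=1e-12)

    def test_guinier_rg_matches_coordinate_rg(self):
        model = ellipsoid_bead_model(20.0, 30.0, spacing=5.0)
        q = np.linspace(0.004, 0.2, 120)
        curve = debye_intensity(model, q)
        fit = guinier_fit(ScatteringCurve(q=q, intensity=curve.intensity))
        assert fit.Rg == pytest.approx(model.radius_of_gyration(), rel=0.01)

    def test_histogram_acceleration_close_to_exact(self):
        model = ellipsoid_bead_model(18.0, 26.0, spacing=6.0)
        q = np.linspace(0.01, 0.3, 50)
        exact = debye_intensity(model, q).intensity
        binned = debye_intensity(model, q, hist_bin=0.1).intensity
        assert np.max(np.abs(binned - exact)) < 5e-4 * exact[0]


class TestDiscrepancy:
    def test_identical_curves_zero(self, saxs_q_grid):
        data = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 30.0, "q_grid": saxs_q_grid}))
        model = ScatteringCurve(q=data.q, intensity=data.intensity)
        assert chi2_discrepancy(data, model).chi2 == pytest.approx(0.0, abs=1e-20)

    def test_scale_invariance(self, saxs_q_grid):
        data = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 30.0, "q_grid": saxs_q_grid}))
        model = ScatteringCurve(q=data.q, intensity=2.0 * data.intensity)
        res = chi2_discrepancy(data, model)
        assert res.chi2 == pytest.approx(0.0, abs=1e-20)
        assert res.scale == pytest.approx(0.5)

    def test_one_sigma_offset_gives_unit_chi2_at_fixed_scale(self, saxs_q_grid):
        data = gen_saxs_body(GroundTruth("saxs_body", {
            "body": "sphere", "radius": 30.0, "q_grid": saxs_q_grid}))
        model = ScatteringCurve(q=data.q, intensity=data.intensity + data.sigma)
        assert chi2_discrepancy(data, model, scale=1.0).chi2 == pytest.approx(1.0)

    def test_missing_sigma_rejected(self, saxs_q_grid):
        bare = ScatteringCurve(q=saxs_q_grid,
                               intensity=np.exp(-saxs_q_grid**2 * 100))
        with pytest.raises(ValueError):
            chi2_discrepancy(bare, bare)


def test_resolution_bookkeeping():
    assert resolution(0.2) == pytest.approx(2.0 * np.pi / 0.2)
    assert resolution(0.2) == pytest.approx(31.4, abs=0.1)
    with pytest.raises(ValueError):
        resolution(0.0)
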