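"""Calibration-stage tests: normalization, Prony fit, tension least squares."""

import numpy as np
import pytest

from renomech import (
    DamageParameters,
    HyperelasticCoefficients,
    MaterialParameters,
    PronyBranch,
    PronySeries,
    fit_prony,
    fit_tension,
    goodness_of_fit,
    normalize_relaxation,
    predict_rates,
    relaxation_function,
    simulate_relaxation,
    simulate_uniaxial_tension,
)
from renomech.calibration import CalibrationConfig, TensionCurve, correct_for_ramp
from renomech.exceptions import InvalidInputError
from renomech.models import PronyRelaxationModel, TensionCalibrationModel


def make_tension_data(material, rate=0.001, max_strain=0.2, steps=1200, sub=20):
    sim = simulate_uniaxial_tension(rate, max_strain, material, steps=steps)
    return TensionCurve(
        sim.eng_strain[::sub], sim.eng_stress_MPa[::sub], rate=rate
    )


class TestNormalizeRelaxation:
    def test_constant_trace_normalizes_to_ones(self):
        t = np.linspace(0.0, 100.0, 50)
        tt, m = normalize_relaxation(t, np.full_like(t, 0.07))
        np.testing.assert_allclose(m, 1.0)
        assert tt[0] == 0.0

    def test_scale_invariance(self):
        t = np.linspace(0.0, 200.0, 300)
        decay = 0.4 + 0.6 * np.exp(-t / 10.0)
        for peak in (0.01, 5.0):
            _, m = normalize_relaxation(t, peak * decay)
            np.testing.assert_allclose(m, decay / decay[0], rtol=1e-12)

    def test_simulated_trace_matches_spectrum_within_ramp_error(self, reference_material):
        curve = simulate_relaxation(params=reference_material, steps=1000)
        t, m = normalize_relaxation(curve.time_s, curve.eng_stress_MPa)
        expected = relaxation_function(t, reference_material.prony)
        # the only systematic deviation is the finite loading ramp (1.8 s
        # against tau_1 = 3 s), worth a few percent near the hold start and
        # fading as the fast branch dies out
        err = np.abs(m - expected)
        assert err.max() < 0.04
        assert err[t > 100.0].max() < 0.02

    def test_rejects_bad_traces(self):
        with pytest.raises(InvalidInputError):
            normalize_relaxation([0.0, 1.0, 2.0], [-1.0, -2.0, -3.0])
        with pytest.raises(InvalidInputError):
            normalize_relaxation(np.arange(6.0), np.array([1, 2, 3, 4, 5, 6.0]))


class TestFitProny:
    def test_two_branch_recovery_on_exact_samples(self):
        truth = PronySeries(
            m_inf=0.3, branches=(PronyBranch(0.5, 5.0), PronyBranch(0.2, 100.0))
        )
        t = np.linspace(0.0, 600.0, 400)
        series, rmse = fit_prony(t, relaxation_function(t, truth), n_branches=2)
        assert series.m_inf == pytest.approx(0.3, abs=1e-3)
        assert rmse < 1e-4
        taus = sorted(b.tau for b in series.branches)
        assert taus[0] == pytest.approx(5.0, rel=0.05)
        assert taus[1] == pytest.approx(100.0, rel=0.05)

    def test_constant_samples_give_pure_equilibrium(self):
        t = np.linspace(0.0, 100.0, 30)
        series, _ = fit_prony(t, np.ones_like(t), n_branches=2)
        assert series.m_inf == pytest.approx(1.0, abs=1e-9)
        assert all(b.m == pytest.approx(0.0, abs=1e-9) for b in series.branches)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_prony(np.arange(4.0), np.ones(4), n_branches=2)

    def test_ramp_correction_inverts_linear_ramp_weighting(self):
        truth = PronySeries(
            m_inf=0.25, branches=(PronyBranch(0.45, 4.0), PronyBranch(0.3, 60.0))
        )
        T = 2.0
        x = T / truth.taus
        g = (1.0 - np.exp(-x)) / x
        u = truth.weights * g
        scale = truth.m_inf + u.sum()
        biased = PronySeries.from_weights(truth.m_inf / scale, u / scale, truth.taus)
        recovered = correct_for_ramp(biased, T)
        assert recovered.m_inf == pytest.approx(0.25, rel=1e-10)
        np.testing.assert_allclose(recovered.weights, truth.weights, rtol=1e-10)

    def test_model_results_interface(self, reference_material):
        curve = simulate_relaxation(params=reference_material, steps=800)
        res = PronyRelaxationModel.from_stress_trace(
            curve.time_s, curve.eng_stress_MPa, n_branches=2
        ).fit()
        # ramp-corrected spectrum close to the generating one
        assert res.series.m_inf == pytest.approx(
            reference_material.prony.m_inf, abs=0.02
        )
        assert "m_inf" in res.summary()
        assert res.resid.shape == res.fittedvalues.shape


class TestFitTension:
    def test_recovers_yeoh_coefficients_with_damage_fixed(self, reference_material):
        data = make_tension_data(reference_material)
        start = MaterialParameters(
            hyperelastic=HyperelasticCoefficients(C10=1e-2, C20=0.0, C30=0.0),
            damage=reference_material.damage,
            prony=reference_material.prony,
        )
        res = fit_tension(
            [data],
            reference_material.prony,
            CalibrationConfig(steps=1200),
            vary="hyperelastic",
            start=start,
        )
        assert res.hyperelastic.C10 == pytest.approx(8.3e-3, rel=0.05)
        assert res.hyperelastic.C20 == pytest.approx(0.8, rel=0.05)
        assert res.hyperelastic.C30 == pytest.approx(-0.74, rel=0.05)
        assert res.rmse_MPa[0.001] < 1e-6

    def test_recovers_damage_constants_with_yeoh_fixed(self, reference_material):
        data = make_tension_data(reference_material)
        start = MaterialParameters(
            hyperelastic=reference_material.hyperelastic,
            damage=DamageParameters(alpha=0.0, beta=1e-4, n_exp=1.5),
            prony=reference_material.prony,
        )
        res = fit_tension(
            [data],
            reference_material.prony,
            CalibrationConfig(steps=1200),
            vary="damage",
            start=start,
        )
        assert res.damage.beta == pytest.approx(3.0e-4, rel=0.05)
        assert res.damage.n_exp == pytest.approx(2.0, rel=0.05)

    def test_objective_decreases_across_stages(self, reference_material):
        data = make_tension_data(reference_material, steps=600)
        res = fit_tension(
            [data],
            reference_material.prony,
            CalibrationConfig(steps=600, n_rounds=1),
            vary="alternating",
        )
        costs = [meta["cost"] for meta in res.convergence]
        assert costs == sorted(costs, reverse=True) or costs[-1] <= costs[0]

    def test_zero_strain_range_rejected(self, reference_material):
        with pytest.raises(InvalidInputError):
            TensionCurve(np.array([0.0, 0.0]), np.array([0.0, 0.0]), rate=0.001)

    def test_noisy_recovery_within_tolerance(self, reference_material):
        # 5% multiplicative-noise-free but additive 5%-of-peak noise, fixed
        # seed: Yeoh coefficients still within 15%
        data = make_tension_data(reference_material, steps=1200)
        rng = np.random.default_rng(7)
        noisy = TensionCurve(
            data.eng_strain,
            data.eng_stress_MPa
            + 0.05 * data.eng_stress_MPa.max() * rng.standard_normal(data.eng_strain.size),
            rate=data.rate,
        )
        start = MaterialParameters(
            hyperelastic=HyperelasticCoefficients(C10=1e-2, C20=0.0, C30=0.0),
            damage=reference_material.damage,
            prony=reference_material.prony,
        )
        res = fit_tension(
            [noisy],
            reference_material.prony,
            CalibrationConfig(steps=600),
            vary="hyperelastic",
            start=start,
        )
        assert res.hyperelastic.C20 == pytest.approx(0.8, rel=0.15)
        assert res.hyperelastic.C30 == pytest.approx(-0.74, rel=0.15)


class TestPredictionAndScoring:
    def test_prediction_at_calibration_rate_is_idempotent(self, reference_material):
        data = make_tension_data(reference_material, steps=600)
        res = fit_tension(
            [data],
            reference_material.prony,
            CalibrationConfig(steps=600),
            vary="hyperelastic",
            start=reference_material,
        )
        pred = predict_rates(res, [0.001], [0.2])[0]
        rmse, rel = goodness_of_fit(data, pred)
        assert rel < 1e-3

    def test_predicted_stress_increases_with_rate(self, reference_material):
        res = fit_tension(
            [make_tension_data(reference_material, steps=600)],
            reference_material.prony,
            CalibrationConfig(steps=600),
            vary="hyperelastic",
            start=reference_material,
        )
        curves = predict_rates(res, [0.001, 0.01, 0.1], [0.15, 0.15, 0.15], steps=400)
        finals = [c.eng_stress_MPa[-1] for c in curves]
        assert finals[0] < finals[1] < finals[2]

    def test_goodness_of_fit_reference_values(self):
        s = np.linspace(0.0, 0.2, 50)
        y = 0.1 * s
        assert goodness_of_fit((s, y), (s, y)) == (0.0, 0.0)
        rmse, _ = goodness_of_fit((s, y), (s, y + 0.01))
        assert rmse == pytest.approx(0.01, rel=1e-9)
        with pytest.raises(InvalidInputError):
            goodness_of_fit((s, y), (s + 1.0, y))

    def test_model_fit_summary_and_save(self, reference_material, tmp_path):
        data = make_tension_data(reference_material, steps=400)
        model = TensionCalibrationModel(
            [data], reference_material.prony, CalibrationConfig(steps=400)
        )
        fit = model.fit(vary="hyperelastic", start=reference_material)
        text = fit.summary()
        assert "C10" in text and "RMSE" in text
        out = tmp_path / "params.yaml"
        fit.save(out)
        loaded = fit.load_material(out)
        assert loaded.hyperelastic.C10 == pytest.approx(fit.params.hyperelastic.C10)
        assert loaded.prony.m_inf == pytest.approx(reference_material.prony.m_inf)
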