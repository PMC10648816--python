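"""Exponential NLS fitting, prediction, and fit diagnostics."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import least_squares

from ueff.calibration import (
    CalibrationModel,
    DegenerateInputError,
    FitMeta,
    ModelKind,
    diagnostics_from_predictions,
    fit_combined_model,
    fit_single_model,
    model_diagnostics,
    predict_ueff,
)
from ueff.cohort import Cohort, Group, PatientRecord


def _cohort_from_arrays(ac, bscd, pdff):
    return Cohort(
        [
            PatientRecord(
                id=f"p{i}", group=Group.NAFLD, ac=float(a), bscd=float(b), ls=5.0,
                pdff=float(p),
            )
            for i, (a, b, p) in enumerate(zip(ac, bscd, pdff))
        ]
    )


class TestSingleModel:
    def test_exact_recovery_on_noiseless_grid(self):
        x = np.linspace(0, 1, 20)
        y = 2.0 * np.exp(3.0 * x) + 1.0
        m = fit_single_model(x, y, ModelKind.AC)
        assert np.allclose(m.coefficients, (2.0, 3.0, 1.0), rtol=1e-6)
        assert m.fit_meta.sse == pytest.approx(0.0, abs=1e-12)
        assert m.fit_meta.converged

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_single_model(np.full(10, 0.8), np.arange(10.0), ModelKind.AC)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_single_model([0.1, 0.2, 0.3], [1.0, 2.0, 3.0], ModelKind.AC)

    def test_sse_matches_grid_polish_oracle(self, rng):
        # brute force: dense grid over (b1, b2, b3) then local refinement
        x = rng.uniform(0.5, 1.3, 30)
        y = 4.0 * np.exp(2.0 * x) - 10.0 + rng.normal(0, 2.0, 30)
        m = fit_single_model(x, y, ModelKind.AC)

        def sse(p):
            return float(np.sum((p[0] * np.exp(p[1] * x) + p[2] - y) ** 2))

        best = None
        for b1 in np.linspace(0.5, 10, 24):
            for b2 in np.linspace(0.5, 4, 24):
                for b3 in np.linspace(-25, 5, 24):
                    s = sse((b1, b2, b3))
                    if best is None or s < best[0]:
                        best = (s, (b1, b2, b3))
        polish = least_squares(
            lambda p: p[0] * np.exp(p[1] * x) + p[2] - y, best[1], xtol=1e-15, ftol=1e-15
        )
        oracle_sse = float(2 * polish.cost)
        assert m.fit_meta.sse <= oracle_sse + 1e-6

    def test_curve_monotone_convex_for_positive_coefficients(self):
        x = np.linspace(0.5, 1.3, 40)
        m = CalibrationModel(
            ModelKind.AC, (4.0, 2.0, -10.0),
            FitMeta(True, 1, 0.0, (4.0, 2.0, -10.0)),
        )
        yhat = m.predict(ac=x)
        d1 = np.diff(yhat)
        assert (d1 > 0).all()          # strictly increasing
        assert (np.diff(d1) > 0).all()  # convex

    def test_refit_on_predictions_idempotent(self, rng):
        x = rng.uniform(0.5, 1.3, 60)
        y = 4.0 * np.exp(2.2 * x) - 11.0 + rng.normal(0, 3.0, 60)
        m = fit_single_model(x, y, ModelKind.AC)
        yhat = m.predict(ac=x)
        m2 = fit_single_model(x, yhat, ModelKind.AC)
        assert np.allclose(m2.coefficients, m.coefficients, rtol=1e-4)


class TestCombinedModel:
    def test_exact_recovery_additive_form(self):
        rng = np.random.default_rng(1)
        ac = rng.uniform(0.5, 1.3, 40)
        bscd = rng.uniform(80, 115, 40)
        truth = (3.0, 2.0, 0.05, 0.04, -8.0)
        y = truth[0] * np.exp(truth[1] * ac) + truth[2] * np.exp(truth[3] * bscd) + truth[4]
        m = fit_combined_model(ac, bscd, y)
        assert m.n_predictors == 2
        assert np.allclose(m.coefficients, truth, rtol=1e-5)

    def test_identical_predictors_flagged(self):
        rng = np.random.default_rng(2)
        ac = rng.uniform(0.5, 1.3, 30)
        y = 4.0 * np.exp(2.0 * ac) - 10.0 + rng.normal(0, 1.0, 30)
        with pytest.warns(UserWarning, match="collinear"):
            m = fit_combined_model(ac, ac.copy(), y)
        assert m.fit_meta.ill_conditioned

    def test_nests_ac_only_model(self, noisy_cohort):
        ac = noisy_cohort.column("ac")
        bscd = noisy_cohort.column("bscd")
        y = noisy_cohort.column("pdff")
        combined = fit_combined_model(ac, bscd, y)
        single = fit_single_model(ac, y, ModelKind.AC)
        assert combined.fit_meta.sse <= single.fit_meta.sse * (1 + 1e-9)


class TestPrediction:
    def test_closed_form(self):
        m = CalibrationModel(
            ModelKind.AC, (1.0, 2.0, 0.5), FitMeta(True, 1, 0.0, (1.0, 2.0, 0.5))
        )
        c = _cohort_from_arrays([1e-12], [100.0], [10.0])
        out = predict_ueff(m, c)
        assert out.records[0].ueff == pytest.approx(1.5)

    def test_negative_ueff_unclipped(self):
        m = CalibrationModel(
            ModelKind.AC, (1.0, 2.0, -5.0), FitMeta(True, 1, 0.0, (1.0, 2.0, -5.0))
        )
        c = _cohort_from_arrays([0.01], [100.0], [0.5])
        out = predict_ueff(m, c)
        assert out.records[0].ueff < 0

    def test_permutation_equivariance(self, noisy_cohort, rng):
        m = fit_combined_model(
            noisy_cohort.column("ac"), noisy_cohort.column("bscd"),
            noisy_cohort.column("pdff"),
        )
        perm = rng.permutation(len(noisy_cohort))
        direct = predict_ueff(m, noisy_cohort).column("ueff")[perm]
        permuted = predict_ueff(m, noisy_cohort.subset(perm)).column("ueff")
        assert np.allclose(direct, permuted)


class TestDiagnostics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 5.0, 9.0, 14.0, 20.0])
        d = diagnostics_from_predictions(y, y, 1)
        assert d.r2 == pytest.approx(1.0)
        assert d.adj_r2 == pytest.approx(1.0)
        assert d.rmse == pytest.approx(0.0)

    def test_mean_prediction_zero_r2(self):
        y = np.array([1.0, 5.0, 9.0, 14.0, 20.0])
        d = diagnostics_from_predictions(y, np.full_like(y, y.mean()), 1)
        assert d.r2 == pytest.approx(0.0)
        assert d.adj_r2 < 0

    def test_matches_formula_oracle(self, rng):
        y = rng.normal(10, 5, 25)
        yhat = y + rng.normal(0, 2, 25)
        d = diagnostics_from_predictions(y, yhat, 2)
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1 - ss_res / ss_tot
        assert d.r2 == pytest.approx(r2, rel=1e-12)
        assert d.adj_r2 == pytest.approx(1 - (1 - r2) * 24 / (25 - 3), rel=1e-12)
        assert d.rmse == pytest.approx(np.sqrt(ss_res / 25), rel=1e-12)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            diagnostics_from_predictions([1.0, 2.0], [1.0, 2.0], 1)

    def test_model_diagnostics_on_cohort(self, zero_noise_cohort):
        from ueff.validation import fit_model

        m = fit_model(zero_noise_cohort, ModelKind.AC)
        d = model_diagnostics(m, zero_noise_cohort)
        assert d.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert d.rmse == pytest.approx(0.0, abs=1e-6)
        assert d.n == len(zero_noise_cohort)
        assert d.p == 1


def test_json_round_trip_bit_exact(noisy_cohort):
    m = fit_combined_model(
        noisy_cohort.column("ac"), noisy_cohort.column("bscd"), noisy_cohort.column("pdff")
    )
    back = CalibrationModel.from_json(m.to_json())
    assert back.kind is m.kind
    assert back.coefficients == m.coefficients
    assert back.fit_meta.sse == m.fit_meta.sse


def test_coefficient_count_enforced():
    with pytest.raises(ValueError):
        CalibrationModel(ModelKind.COMBINED, (1.0, 2.0, 3.0), FitMeta(True, 1, 0.0, ()))
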