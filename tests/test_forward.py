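import numpy as np
import pytest

from conftest import random_same_sign_model
from isoturn.forward import (
    CoverageError,
    build_kernel,
    continuous_step_response,
    estimate_shift,
    predict_output,
    validate,
)
from isoturn.kinetics import CompartmentModel, Pool, kernel_value
from isoturn.timeseries import IsotopeSeries

LACTOSE = CompartmentModel(0.0, 12.0, [Pool.from_half_life(2.7, 10.0)])


def _step_input(delta=-2.7, t0=-400.0, t1=200.0):
    t = np.arange(t0, t1)
    return IsotopeSeries("a", "diet", t, np.where(t >= 0, delta, 0.0))


class TestKernel:
    def test_geometric_closed_form_at_step_equal_half_life(self):
        k = build_kernel(LACTOSE, step_h=10.0)
        # raw weights 2^-j for j=0..6; w0 = 64/127
        assert k.weights.size == 7
        assert k.weights[0] == pytest.approx(64 / 127)
        np.testing.assert_allclose(k.weights, (0.5 ** np.arange(7)) / (127 / 64))

    def test_invariants_on_random_models(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = random_same_sign_model(rng)
            k = build_kernel(m, step_h=float(rng.uniform(0.5, 6.0)))
            assert np.all(k.weights >= 0)
            assert k.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(k.weights) <= 1e-15)
            assert 0.0 <= k.truncated_mass < 0.05

    def test_additivity_of_unnormalized_weights(self):
        p1 = CompartmentModel(0.0, 0.0, [Pool.from_half_life(1.0, 10.0)])
        p2 = CompartmentModel(0.0, 0.0, [Pool.from_half_life(1.0, 21.0)])
        both = CompartmentModel(
            0.0, 0.0, [Pool.from_half_life(1.0, 10.0), Pool.from_half_life(1.0, 21.0)]
        )
        ages = np.linspace(0, 80, 50)
        np.testing.assert_allclose(
            kernel_value(both, ages),
            kernel_value(p1, ages) + kernel_value(p2, ages),
        )

    def test_degenerate_model_rejected(self):
        m = CompartmentModel(0.0, 0.0, [Pool(0.0, 10.0)])
        with pytest.raises(ValueError):
            build_kernel(m)


class TestPredict:
    def test_constant_input_returns_shifted_constant(self):
        t = np.arange(-300.0, 100.0)
        inp = IsotopeSeries("a", "diet", t, np.full(t.size, -27.4))
        pred = predict_output(inp, LACTOSE, shift=-0.62, times=[0.0, 24.0, 48.0])
        np.testing.assert_allclose(pred.values, -27.4 - 0.62, atol=1e-12)

    def test_step_half_completion_matches_continuous_oracle(self):
        """At one half-life past the delay the discrete engine must be within
        2% of the exact continuous convolution of the step."""
        pred = predict_output(_step_input(), LACTOSE, shift=0.0, times=[22.0])
        exact = continuous_step_response(LACTOSE, -2.7, 22.0)
        assert abs(pred.values[0] - exact) / 2.7 < 0.02
        assert abs(pred.values[0] / -2.7 - 0.5) < 0.02

    def test_halving_step_changes_prediction_below_0p01(self):
        times = [22.0, 40.0, 80.0]
        p1 = predict_output(_step_input(), LACTOSE, shift=0.0, times=times, step_h=1.0)
        p2 = predict_output(_step_input(), LACTOSE, shift=0.0, times=times, step_h=0.5)
        assert np.max(np.abs(p1.values - p2.values)) < 0.01

    def test_fluctuating_input_is_attenuated(self):
        rng = np.random.default_rng(12)
        t = np.arange(-600.0, 200.0, 12.0)
        z = np.empty(t.size)
        z[0] = rng.standard_normal()
        for i in range(1, t.size):
            z[i] = 0.5 * z[i - 1] + np.sqrt(0.75) * rng.standard_normal()
        inp = IsotopeSeries("a", "diet", t, -27.4 + 0.45 * z)
        times = np.arange(-300.0, 150.0, 12.0)
        pred = predict_output(inp, LACTOSE, shift=0.0, times=times)
        assert pred.values.std(ddof=1) < inp.values.std(ddof=1)

    def test_insufficient_history_raises_coverage_error(self):
        t = np.arange(-20.0, 100.0)
        inp = IsotopeSeries("a", "diet", t, np.full(t.size, -27.4))
        with pytest.raises(CoverageError, match="needs"):
            predict_output(inp, LACTOSE, shift=0.0, times=[0.0])


class TestShiftAndValidation:
    def test_shift_trivial_cases(self):
        t = np.arange(0.0, 40.0, 2.0)
        pred = IsotopeSeries("a", "p", t, -27.4 + 0.1 * np.sin(t))
        same = IsotopeSeries("a", "m", t, pred.values)
        assert estimate_shift(same, pred).shift_permil == 0.0
        plus = IsotopeSeries("a", "m", t, pred.values + 1.0)
        est = estimate_shift(plus, pred)
        assert est.shift_permil == pytest.approx(1.0)
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_shift_recovery_under_noise(self):
        """True shift -0.62 recovered within 2 SEs in >= 8 of 10 replicates."""
        t = np.arange(0.0, 384.0, 12.0)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pred = IsotopeSeries("a", "p", t, -27.4 + 0.12 * np.sin(t / 30))
            meas = IsotopeSeries(
                "a", "m", t, pred.values - 0.62 + rng.normal(0, 0.19, t.size)
            )
            est = estimate_shift(meas, pred)
            hits += abs(est.shift_permil + 0.62) <= 2 * est.se
        assert hits >= 8

    def test_validate_exact_agreement(self):
        t = np.arange(0.0, 50.0)
        pred = IsotopeSeries("a", "p", t, -27.4 + 0.2 * np.sin(t / 5))
        rep = validate(IsotopeSeries("a", "m", t, pred.values), pred)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-9)

    def test_validate_noise_only_differences(self):
        rng = np.random.default_rng(13)
        t = np.arange(128.0)
        pred = IsotopeSeries("a", "p", t, -27.4 + 0.3 * np.sin(t / 20))
        meas = IsotopeSeries("a", "m", t, pred.values + rng.normal(0, 0.2, 128))
        rep = validate(meas, pred)
        assert rep.n == 128
        assert rep.rmse == pytest.approx(0.2, rel=0.2)
        assert rep.p_slope_vs_1 > 0.05
        assert rep.p_intercept_vs_0 > 0.05

    def test_validate_detects_wrong_slope(self):
        t = np.arange(0.0, 60.0)
        x = -27.4 + 0.3 * np.sin(t / 6)
        pred = IsotopeSeries("a", "p", t, x)
        meas = IsotopeSeries("a", "m", t, 2 * x)
        rep = validate(meas, pred)
        assert rep.p_slope_vs_1 < 1e-6

    def test_validate_constant_prediction_skips_regression(self):
        t = np.arange(0.0, 20.0)
        pred = IsotopeSeries("a", "p", t, np.full(t.size, -27.4))
        meas = IsotopeSeries("a", "m", t, -27.4 + 0.01 * np.sin(t))
        rep = validate(meas, pred)
        assert rep.slope is None
        assert rep.rmse > 0


class TestEndToEnd:
    def test_generated_then_fitted_recovers_half_life(self):
        """Data produced by the forward engine, refit by the estimator,
        covers the generating half-life in >= 8 of 10 replicates."""
        from isoturn.fitting import FULLY_SHARED, fit_model

        times = np.arange(24.0, 204.0, 12.0)
        base = predict_output(_step_input(), LACTOSE, shift=0.0, times=times)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            series = [
                IsotopeSeries(
                    f"c{i}", "x", times, base.values + rng.normal(0, 0.15, times.size)
                )
                for i in range(8)
            ]
            fr = fit_model(series, 1, FULLY_SHARED, delay_h=12.0, seed=seed)
            ci = fr.half_life_ci(1)
            hits += ci.lower <= 10.0 <= ci.upper
        assert hits >= 8
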