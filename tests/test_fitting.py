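import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.stats import t as student_t

from isoturn.fitting import (
    FULLY_SHARED,
    LN2,
    SharingStructure,
    TurnoverModel,
    fit_model,
    select_model,
)
from isoturn.kinetics import CompartmentModel, Pool
from isoturn.simulate import OutputStreamSpec, gen_switch_experiment
from isoturn.timeseries import IsotopeSeries

CHASE_TIMES = np.arange(0.0, 180.0, 12.0)  # 15 twice-daily chase samplings


def _switch_series(model, n_animals=8, noise=0.0, seed=0, shift=0.0):
    spec = OutputStreamSpec("x", model, trophic_shift=shift, noise_sd=noise)
    return gen_switch_experiment(spec, n_animals=n_animals, seed=seed)


def _chase(series, start=23.5):
    return [s.slice_time(start, np.inf) for s in series]


ONE_POOL_TRUTH = CompartmentModel(0.0, 12.0, [Pool.from_half_life(2.9, 10.0)])


class TestFit:
    def test_zero_noise_recovery_to_1e4(self):
        chase = _chase(_switch_series(ONE_POOL_TRUTH, noise=0.0))
        fr = fit_model(chase, 1, FULLY_SHARED, delay_h=12.0, seed=0)
        m = list(fr.models.values())[0]
        # absolute level anchored at -27.40 plateau minus total amplitude
        assert m.c == pytest.approx(-27.40 - 2.9, rel=1e-4)
        assert m.pools[0].amplitude_a == pytest.approx(2.9, rel=1e-4)
        assert m.pools[0].tau == pytest.approx(10.0 / LN2, rel=1e-4)

    def test_overparameterized_fit_is_degenerate_and_not_selected(self):
        chase = _chase(_switch_series(ONE_POOL_TRUTH, noise=0.02, seed=1))
        f1 = fit_model(chase, 1, FULLY_SHARED, 12.0, seed=1)
        f2 = fit_model(chase, 2, FULLY_SHARED, 12.0, seed=1)
        assert f2.is_degenerate() or f2.aic >= f1.aic - 2.0
        sel = select_model(chase, max_pools=2, structures=[FULLY_SHARED], delay_h=12.0, seed=1)
        assert sel.model.pool_count == 1

    def test_offset_animal_prefers_per_animal_baseline(self):
        series = _switch_series(ONE_POOL_TRUTH, noise=0.13, seed=3)
        shifted = IsotopeSeries(
            series[0].animal_id, "x", series[0].times_h, series[0].values + 1.0
        )
        chase = _chase([shifted] + series[1:])
        sel = select_model(
            chase,
            max_pools=2,
            structures=[FULLY_SHARED, SharingStructure(c="per_animal")],
            delay_h=12.0,
            seed=3,
        )
        assert sel.model.structure.c == "per_animal"

    def test_unresolvable_two_pool_mixture_recovered_functionally(self):
        """Pools 10 h and 21 h at analytical noise are nearly one exponential;
        the selected model must still reproduce the underlying curve and its
        gross half-life even though the pool split is unidentifiable."""
        from isoturn.kinetics import gross_half_life
        from isoturn.pipeline import consensus_model

        truth = CompartmentModel(
            0.0, 12.0,
            [Pool.from_half_life(2.1 * 0.55, 10.0), Pool.from_half_life(2.1 * 0.45, 21.0)],
        )
        true_gross = gross_half_life(truth)
        abs_truth = CompartmentModel(-27.40 - truth.total_amplitude, 12.0, truth.pools)
        tt = np.arange(24.0, 168.0)
        for seed in range(3):
            chase = _chase(_switch_series(truth, noise=0.15, seed=seed))
            sel = select_model(chase, max_pools=2, structures=[FULLY_SHARED], delay_h=12.0, seed=seed)
            m = consensus_model(sel)
            rms = np.sqrt(np.mean((m.evaluate(tt) - abs_truth.evaluate(tt)) ** 2))
            assert rms < 0.08
            # the pool split is unidentifiable; the overall timescale is not
            assert gross_half_life(m) == pytest.approx(true_gross, rel=0.25)

    def test_too_few_observations_raise(self):
        s = IsotopeSeries("c1", "x", [24.0, 36.0, 48.0], [-29.0, -29.5, -29.8])
        with pytest.raises(ValueError, match="observations"):
            TurnoverModel([s], pool_count=2, delay_h=12.0)


class TestResults:
    def test_aic_identity_and_selection_optimality(self):
        chase = _chase(_switch_series(ONE_POOL_TRUTH, noise=0.13, seed=5))
        sel = select_model(chase, max_pools=2, structures=[FULLY_SHARED], delay_h=12.0, seed=5)
        assert sel.aic == pytest.approx(2 * sel.n_params - 2 * sel.llf)
        tab = sel.candidates
        ok = tab[(tab.converged) & (tab.note == "")]
        assert (sel.aic <= ok.aic + 2.0 + 1e-9).all()

    def test_half_life_ci_uses_student_t_with_n_minus_1_df(self):
        chase = _chase(_switch_series(ONE_POOL_TRUTH, noise=0.13, seed=6))
        fr = fit_model(chase, 1, FULLY_SHARED, 12.0, seed=6)
        ci = fr.half_life_ci(1)
        tau, se_tau = fr.tau_estimate(1)
        ta = student_t.ppf(0.975, 7)  # 8 animals
        assert ci.t_half == pytest.approx(tau * LN2)
        assert ci.upper - ci.t_half == pytest.approx(se_tau * LN2 * ta, rel=1e-9)
        assert ci.lower <= ci.t_half <= ci.upper

    def test_zero_noise_ci_collapses(self):
        chase = _chase(_switch_series(ONE_POOL_TRUTH, noise=0.0))
        fr = fit_model(chase, 1, FULLY_SHARED, 12.0, seed=0)
        ci = fr.half_life_ci(1)
        assert ci.upper - ci.lower == pytest.approx(0.0, abs=1e-4)

    def test_two_animal_interval_is_wide_but_ordered(self):
        chase = _chase(_switch_series(ONE_POOL_TRUTH, n_animals=2, noise=0.13, seed=7))
        fr = fit_model(chase, 1, FULLY_SHARED, 12.0, seed=7)
        ci = fr.half_life_ci(1)
        assert ci.lower <= ci.t_half <= ci.upper
        # T_a = 12.706 at 1 degree of freedom blows the interval up
        assert (ci.upper - ci.lower) > 4 * fr.tau_estimate(1)[1] * LN2

    def test_permuting_animals_leaves_estimates_unchanged(self):
        series = _switch_series(ONE_POOL_TRUTH, noise=0.13, seed=8)
        f1 = fit_model(_chase(series), 1, FULLY_SHARED, 12.0, seed=8)
        f2 = fit_model(_chase(series[::-1]), 1, FULLY_SHARED, 12.0, seed=8)
        assert np.allclose(f1.params.values, f2.params.values, atol=1e-8)

    def test_summary_mentions_key_quantities(self):
        chase = _chase(_switch_series(ONE_POOL_TRUTH, noise=0.13, seed=9))
        fr = fit_model(chase, 1, FULLY_SHARED, 12.0, seed=9)
        text = fr.summary()
        for token in ("AIC", "t1/2", "tau1", "converged: True"):
            assert token in text


class TestPooledOracle:
    def test_fully_shared_fit_equals_pooled_curve_fit(self):
        """With every parameter shared, the joint fit must coincide with a
        plain least-squares fit on the pooled observations."""
        series = _switch_series(ONE_POOL_TRUTH, noise=0.13, seed=10)
        chase = _chase(series)
        fr = fit_model(chase, 1, FULLY_SHARED, 12.0, seed=10)
        t = np.concatenate([s.times_h for s in chase])
        y = np.concatenate([s.values for s in chase])

        def f(tt, c, a, log_tau):
            return c + a * np.exp(-(tt - 12.0) / np.exp(log_tau))

        popt, _ = curve_fit(f, t, y, p0=[-30.0, 3.0, np.log(15.0)], maxfev=10000)
        assert fr.params["c"] == pytest.approx(popt[0], abs=1e-5)
        assert fr.params["a1"] == pytest.approx(popt[1], abs=1e-5)
        assert fr.params["tau1"] == pytest.approx(np.exp(popt[2]), rel=1e-5)
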