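import numpy as np
import pytest

from conftest import random_same_sign_model
from isoturn.delay import (
    NoIntersectionError,
    NoSwitchResponseError,
    partition_delay_chase,
    refine_delay_by_intersection,
)
from isoturn.kinetics import CompartmentModel, Pool
from isoturn.simulate import OutputStreamSpec, gen_switch_experiment
from isoturn.timeseries import IsotopeSeries


def _series_grid(values_by_animal, times):
    return [
        IsotopeSeries(a, "x", times, v) for a, v in values_by_animal.items()
    ]


class TestPartition:
    def test_instant_shift_zero_noise_gives_single_delay_sample(self):
        times = np.arange(0.0, 72.0, 12.0)
        series = _series_grid(
            {f"c{i}": np.where(times > 0, -29.6, -26.9) for i in range(8)}, times
        )
        part = partition_delay_chase(series)
        assert part.first_chase_time_h == 12.0
        assert part.delay_sample_times == [0.0]
        assert part.baseline_mean == pytest.approx(-26.9)

    def test_constant_series_raise_no_response(self):
        times = np.arange(0.0, 120.0, 12.0)
        series = _series_grid({f"c{i}": np.full(times.size, -27.0) for i in range(8)}, times)
        with pytest.raises(NoSwitchResponseError):
            partition_delay_chase(series)

    def test_feces_like_modal_boundary_is_24h(self):
        """Delay 20 h with 12 h sampling: the first detectable response is
        usually the 24 h sample (the 12 h one still sits in the delay)."""
        spec = OutputStreamSpec(
            "feces",
            CompartmentModel(0.0, 20.0, [Pool.from_half_life(1.1, 9.0)]),
            trophic_shift=-2.11,
            noise_sd=0.12,
        )
        boundaries = []
        for seed in range(200):
            series = gen_switch_experiment(spec, seed=seed)
            post = [s.slice_time(-1e-9, np.inf) for s in series]
            boundaries.append(partition_delay_chase(post).first_chase_time_h)
        values, counts = np.unique(boundaries, return_counts=True)
        assert values[np.argmax(counts)] == 24.0

    def test_monotone_in_alpha(self):
        spec = OutputStreamSpec(
            "casein",
            CompartmentModel(0.0, 12.0, [Pool.from_half_life(2.64, 18.0)]),
            trophic_shift=2.01,
            noise_sd=0.25,
        )
        for seed in range(10):
            series = gen_switch_experiment(spec, seed=seed)
            post = [s.slice_time(-1e-9, np.inf) for s in series]
            prev = np.inf
            for alpha in (0.2, 0.05, 0.01, 0.001):
                try:
                    t = partition_delay_chase(post, alpha=alpha).first_chase_time_h
                except NoSwitchResponseError:
                    t = np.inf
                # lowering alpha never moves the boundary earlier
                assert t >= prev or prev is np.inf
                prev = t if np.isfinite(t) else prev

    def test_too_few_animals_skips_all_time_points(self):
        times = np.arange(0.0, 72.0, 12.0)
        series = _series_grid(
            {f"c{i}": np.where(times > 0, -29.6, -26.9) for i in range(2)}, times
        )
        with pytest.raises(NoSwitchResponseError):
            partition_delay_chase(series)  # every point below min_pairs

    def test_underpowered_time_point_skipped_but_scan_continues(self):
        times = np.arange(0.0, 72.0, 12.0)
        full = _series_grid(
            {f"c{i}": np.where(times > 0, -29.6, -26.9) for i in range(8)}, times
        )
        # drop the 12 h sample for half the herd: that point lacks pairs
        trimmed = []
        for i, s in enumerate(full):
            if i < 4:
                keep = s.times_h != 12.0
                trimmed.append(
                    type(s)(s.animal_id, s.stream, s.times_h[keep], s.values[keep])
                )
            else:
                trimmed.append(s)
        part = partition_delay_chase(trimmed)
        assert 12.0 in part.skipped_times
        assert part.first_chase_time_h == 24.0


class TestRefineDelay:
    def test_baseline_at_plateau_returns_model_delay(self):
        m = CompartmentModel(-29.8, 12.0, [Pool(2.9, 10.0 / np.log(2))])
        est = refine_delay_by_intersection(m, -26.9)
        assert est.delay_h == pytest.approx(12.0)
        assert est.method == "model_intersection"

    def test_baseline_halfway_is_delay_plus_half_life(self):
        m = CompartmentModel(-29.8, 12.0, [Pool.from_half_life(2.9, 10.0)])
        est = refine_delay_by_intersection(m, -29.8 + 1.45)
        assert est.delay_h == pytest.approx(22.0, abs=1e-5)

    def test_matches_dense_grid_oracle_on_random_models(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 100:
            m = random_same_sign_model(rng, max_pools=2)
            frac = rng.uniform(0.05, 0.95)
            baseline = m.c + frac * (m.plateau - m.c)
            t = m.delay_h + np.arange(0.0, 8 * m.taus.max(), 0.001)
            vals = m.c + m.decay(t - m.delay_h)
            hit = (
                np.argmax(vals <= baseline)
                if m.total_amplitude > 0
                else np.argmax(vals >= baseline)
            )
            est = refine_delay_by_intersection(m, baseline)
            assert est.delay_h == pytest.approx(t[hit], abs=0.01)
            checked += 1

    def test_two_pool_quarter_shift_bracketed(self):
        m = CompartmentModel(
            -29.8, 12.0,
            [Pool.from_half_life(1.0, 10.0), Pool.from_half_life(1.0, 21.0)],
        )
        baseline = m.plateau - 0.25 * m.total_amplitude
        est = refine_delay_by_intersection(m, baseline)
        assert est.delay_h > 12.0
        assert m.c + m.decay(est.delay_h - 12.0) == pytest.approx(baseline, abs=1e-5)

    def test_baseline_outside_range_raises(self):
        m = CompartmentModel(-29.8, 12.0, [Pool.from_half_life(2.9, 10.0)])
        with pytest.raises(NoIntersectionError):
            refine_delay_by_intersection(m, -31.0)  # beyond the asymptote

    def test_zero_noise_pipeline_recovers_generating_delay(self):
        """On noise-free switch data the refined delay equals the truth."""
        from isoturn.pipeline import fit_stream
        from isoturn.timeseries import StudyDataset

        for delay, th in [(12.0, 10.0), (20.0, 9.0)]:
            spec = OutputStreamSpec(
                "x",
                CompartmentModel(0.0, delay, [Pool.from_half_life(2.64, th)]),
                trophic_shift=0.0,
                noise_sd=0.0,
            )
            ds = StudyDataset()
            for s in gen_switch_experiment(spec, seed=0):
                ds.add(s)
            r = fit_stream(ds, "x", pool_count=1, seed=0)
            assert r["delay"]["delay_h"] == pytest.approx(delay, abs=1e-3)
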