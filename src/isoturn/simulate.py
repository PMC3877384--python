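"""Synthetic diet-switch studies with known ground truth.

Emulates the statistical structure of a dairy-herd diet-switch experiment:
a long equilibration period on a mixed diet whose delta13C fluctuates
naturally (AR(1) around -27.40 permil, SD 0.45 permil), an abrupt switch of
about -2.6 permil to a pure-grass diet, and delayed, attenuated responses in
the outputs (feces, lactose, casein, milk fat, and whole milk mixed from the
three milk components).  Outputs are generated by convolving the input with
each stream's true turnover kernel, then adding a constant trophic shift, an
animal-level offset, and i.i.d. analytical noise.

Default design: 8 animals; per output 32 equilibration samples plus 15 chase
samples at twice-daily (12 h) spacing; per-stream delays, half-lives and
analytical noise at realistic dairy values (delays 12-20 h, half-lives
9-19 h, noise SD 0.11-0.19 permil).  Everything is deterministic under a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .forward import build_kernel, predict_output
from .kinetics import CompartmentModel, Pool
from .mixtures import MixtureSpec
from .timeseries import IsotopeSeries, StudyDataset

__all__ = [
    "InputSignalSpec",
    "OutputStreamSpec",
    "StudyConfig",
    "SyntheticStudy",
    "gen_input",
    "gen_output",
    "gen_study",
    "gen_switch_experiment",
    "default_config",
    "default_sample_times",
]

SAMPLING_INTERVAL_H = 12.0  # twice-daily milkings / feed sampling
N_EQUILIBRATION = 32
N_CHASE = 15


def default_sample_times() -> np.ndarray:
    """Twice-daily output sampling: 32 equilibration + 15 chase samples."""
    equil = -SAMPLING_INTERVAL_H * np.arange(N_EQUILIBRATION, 0, -1)
    chase = SAMPLING_INTERVAL_H * np.arange(N_CHASE)
    return np.concatenate([equil, chase])


@dataclass(frozen=True)
class InputSignalSpec:
    """Fluctuating diet input: AR(1) around a mean with a step switch at t=0."""

    equil_mean: float = -27.40
    equil_sd: float = 0.45
    ar1_rho: float = 0.5
    switch_delta: float = -2.64
    chase_mean_sd: float = 0.38
    sampling_interval_h: float = SAMPLING_INTERVAL_H
    t_start_h: float = -552.0
    t_end_h: float = 168.0

    def __post_init__(self):
        if self.equil_sd < 0 or self.chase_mean_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling interval must be positive")
        if not (self.t_start_h < 0 < self.t_end_h):
            raise ValueError("need t_start_h < 0 < t_end_h")


@dataclass
class OutputStreamSpec:
    """Ground truth for one output stream."""

    stream: str
    true_model: CompartmentModel
    trophic_shift: float
    noise_sd: float
    sample_times_h: np.ndarray = field(default_factory=default_sample_times)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.sample_times_h = np.asarray(self.sample_times_h, dtype=float)


def _one_pool(delay_h: float, t_half: float, total_shift: float) -> CompartmentModel:
    """True model for a one-pool output responding to a switch of size
    ``total_shift`` (asymptote placed at 0; only shape matters for kernels)."""
    return CompartmentModel(0.0, delay_h, [Pool.from_half_life(-total_shift, t_half)])


@dataclass
class StudyConfig:
    """Full study-level generator configuration."""

    n_animals: int = 8
    input_spec: InputSignalSpec = field(default_factory=InputSignalSpec)
    streams: dict[str, OutputStreamSpec] = field(default_factory=dict)
    milk_mixture: MixtureSpec | None = None
    whole_milk_noise_sd: float = 0.19
    animal_jitter_sd: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_animals": self.n_animals,
            "input_spec": self.input_spec.__dict__ | {},
            "streams": {
                name: {
                    "true_model": s.true_model.to_dict(),
                    "trophic_shift": s.trophic_shift,
                    "noise_sd": s.noise_sd,
                    "sample_times_h": s.sample_times_h.tolist(),
                }
                for name, s in self.streams.items()
            },
            "milk_mixture": (
                None
                if self.milk_mixture is None
                else list(self.milk_mixture.components)
            ),
            "whole_milk_noise_sd": self.whole_milk_noise_sd,
            "animal_jitter_sd": self.animal_jitter_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        cfg = default_config()
        if "n_animals" in d:
            cfg.n_animals = int(d["n_animals"])
        if "input_spec" in d:
            cfg.input_spec = InputSignalSpec(**d["input_spec"])
        if "streams" in d:
            cfg.streams = {
                name: OutputStreamSpec(
                    stream=name,
                    true_model=CompartmentModel.from_dict(s["true_model"]),
                    trophic_shift=float(s["trophic_shift"]),
                    noise_sd=float(s["noise_sd"]),
                    sample_times_h=np.asarray(
                        s.get("sample_times_h", default_sample_times()), float
                    ),
                )
                for name, s in d["streams"].items()
            }
        if "milk_mixture" in d:
            mm = d["milk_mixture"]
            cfg.milk_mixture = None if mm is None else MixtureSpec(mm)
        for k in ("whole_milk_noise_sd", "animal_jitter_sd"):
            if k in d:
                setattr(cfg, k, float(d[k]))
        return cfg


def default_config() -> StudyConfig:
    """Realistic dairy diet-switch study (see module docstring).

    Trophic shifts are the equilibration offsets of each output from the
    diet; carbon fractions of the milk components (0.40 lactose / 0.30
    casein / 0.30 fat) are a configurable stand-in, as published component
    carbon contents vary.
    """
    inp = InputSignalSpec()
    shift = inp.switch_delta  # output shift equals input shift by construction
    streams = {
        "feces": OutputStreamSpec("feces", _one_pool(20.0, 9.0, shift), -2.11, 0.12),
        "lactose": OutputStreamSpec("lactose", _one_pool(12.0, 10.0, shift), 0.46, 0.13),
        "casein": OutputStreamSpec("casein", _one_pool(12.0, 18.0, shift), 2.01, 0.11),
        "milk_fat": OutputStreamSpec(
            "milk_fat", _one_pool(12.0, 19.0, shift), -2.83, 0.14
        ),
    }
    return StudyConfig(
        n_animals=8,
        input_spec=inp,
        streams=streams,
        milk_mixture=MixtureSpec(
            [("lactose", 0.40), ("casein", 0.30), ("milk_fat", 0.30)]
        ),
        whole_milk_noise_sd=0.19,
        animal_jitter_sd=0.0,
    )


@dataclass
class SyntheticStudy:
    """Generated dataset plus the truth that produced it."""

    dataset: StudyDataset
    truth: dict[str, OutputStreamSpec]
    seed: int
    input_full: IsotopeSeries  # extended-history diet series used internally
    config: StudyConfig


def gen_input(
    spec: InputSignalSpec, seed: int, animal_id: str = "herd"
) -> IsotopeSeries:
    """Fluctuating diet series: AR(1) deviations with the stated stationary
    SD around the period mean, plus the step switch at t = 0."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1D]))
    dt = spec.sampling_interval_h
    n_pre = int(np.ceil(-spec.t_start_h / dt))
    times = -dt * n_pre + dt * np.arange(
        n_pre + int(np.floor(spec.t_end_h / dt + 1e-9)) + 1
    )
    rho = spec.ar1_rho
    z = np.empty(times.size)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(times.size - 1) * np.sqrt(1 - rho**2)
    for i in range(1, times.size):
        z[i] = rho * z[i - 1] + innov[i - 1]
    post = times >= 0
    mean = np.where(post, spec.equil_mean + spec.switch_delta, spec.equil_mean)
    sd = np.where(post, spec.chase_mean_sd, spec.equil_sd)
    return IsotopeSeries(animal_id, "diet", times, mean + sd * z)


def _clean_output(
    input_series: IsotopeSeries, spec: OutputStreamSpec, step_h: float = 1.0
) -> IsotopeSeries:
    kernel = build_kernel(spec.true_model, step_h)
    return predict_output(
        input_series,
        spec.true_model,
        kernel=kernel,
        shift=spec.trophic_shift,
        times=spec.sample_times_h,
    )


def gen_output(
    input_series: IsotopeSeries,
    spec: OutputStreamSpec,
    n_animals: int = 8,
    animal_jitter_sd: float = 0.0,
    seed: int = 0,
) -> list[IsotopeSeries]:
    """Per-animal output series: input convolved with the true kernel, plus
    trophic shift, a Normal(0, animal_jitter_sd) per-animal offset, and
    i.i.d. Normal(0, noise_sd) analytical noise per sample."""
    clean = _clean_output(input_series, spec)
    stream_tag = int.from_bytes(spec.stream.encode()[:4].ljust(4, b"\0"), "big")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), stream_tag]))
    out = []
    for i in range(n_animals):
        offset = rng.normal(0.0, animal_jitter_sd) if animal_jitter_sd > 0 else 0.0
        noise = rng.normal(0.0, spec.noise_sd, clean.values.size)
        out.append(
            IsotopeSeries(
                f"cow{i + 1}",
                spec.stream,
                clean.times_h,
                clean.values + offset + noise,
            )
        )
    return out


def gen_switch_experiment(
    spec: OutputStreamSpec,
    n_animals: int = 8,
    seed: int = 0,
    equil_mean: float = -27.40,
    animal_jitter_sd: float = 0.0,
    sample_times_h=None,
) -> list[IsotopeSeries]:
    """Idealized diet-switch experiment: exact model response plus noise.

    The classical parameter-recovery setting: a clean step switch at t = 0
    (no short-term input fluctuation), so each output sample is the true
    delayed multi-exponential evaluated at the sampling time plus i.i.d.
    analytical noise.  The absolute level is anchored so the pre-switch
    plateau equals ``equil_mean + trophic_shift``.
    """
    times = (
        default_sample_times() if sample_times_h is None
        else np.asarray(sample_times_h, dtype=float)
    )
    m = spec.true_model
    c_abs = equil_mean + spec.trophic_shift - m.total_amplitude
    abs_model = CompartmentModel(c_abs, m.delay_h, list(m.pools))
    clean = abs_model.evaluate(times)
    stream_tag = int.from_bytes(spec.stream.encode()[:4].ljust(4, b"\0"), "big")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E, stream_tag]))
    out = []
    for i in range(n_animals):
        offset = rng.normal(0.0, animal_jitter_sd) if animal_jitter_sd > 0 else 0.0
        noise = rng.normal(0.0, spec.noise_sd, times.size)
        out.append(
            IsotopeSeries(f"cow{i + 1}", spec.stream, times, clean + offset + noise)
        )
    return out


def gen_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full study: diet + all output streams for every animal.

    Whole milk (when a milk mixture is configured) is the carbon-weighted
    mix of the clean lactose/casein/fat signals plus its own analytical
    noise, so its kinetics are a genuine multi-pool mixture rather than an
    independently drawn stream.
    """
    if config is None:
        config = default_config()
    ss = np.random.SeedSequence(int(seed))
    input_seed, out_seed, milk_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    input_full = gen_input(config.input_spec, input_seed)

    dataset = StudyDataset(metadata={"seed": int(seed), "synthetic": True})
    truth: dict[str, OutputStreamSpec] = dict(config.streams)

    sample_times = default_sample_times()
    # dataset view of the diet: per-animal copy at the standard sample times
    diet_idx = np.searchsorted(input_full.times_h, sample_times)
    diet_vals = input_full.values[np.clip(diet_idx, 0, len(input_full) - 1)]
    for i in range(config.n_animals):
        dataset.add(
            IsotopeSeries(f"cow{i + 1}", "diet", sample_times, diet_vals)
        )

    clean_by_stream: dict[str, IsotopeSeries] = {}
    for name, spec in config.streams.items():
        clean = _clean_output(input_full, spec)
        clean_by_stream[name] = clean
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [out_seed, sorted(config.streams).index(name)]
            )
        )
        for i in range(config.n_animals):
            offset = (
                rng.normal(0.0, config.animal_jitter_sd)
                if config.animal_jitter_sd > 0
                else 0.0
            )
            noise = rng.normal(0.0, spec.noise_sd, clean.values.size)
            dataset.add(
                IsotopeSeries(
                    f"cow{i + 1}", name, clean.times_h, clean.values + offset + noise
                )
            )

    if config.milk_mixture is not None:
        comps = config.milk_mixture
        mixed = np.zeros_like(sample_times, dtype=float)
        for stream_name, frac in comps.components:
            mixed = mixed + frac * clean_by_stream[stream_name].values
        rng = np.random.default_rng(np.random.SeedSequence([milk_seed]))
        for i in range(config.n_animals):
            noise = rng.normal(0.0, config.whole_milk_noise_sd, mixed.size)
            dataset.add(
                IsotopeSeries(f"cow{i + 1}", "whole_milk", sample_times, mixed + noise)
            )
        truth["whole_milk"] = OutputStreamSpec(
            "whole_milk",
            _mixture_truth(config),
            trophic_shift=sum(
                f * config.streams[s].trophic_shift for s, f in comps.components
            ),
            noise_sd=config.whole_milk_noise_sd,
        )

    return SyntheticStudy(dataset, truth, int(seed), input_full, config)


def _mixture_truth(config: StudyConfig) -> CompartmentModel:
    """True multi-pool model of the mixed whole-milk stream: component pools
    scaled by carbon fraction (pools with equal residence times merge)."""
    pools: dict[float, float] = {}
    delay = None
    for stream_name, frac in config.milk_mixture.components:
        m = config.streams[stream_name].true_model
        delay = m.delay_h if delay is None else delay
        for p in m.pools:
            pools[p.tau] = pools.get(p.tau, 0.0) + frac * p.amplitude_a
    return CompartmentModel(
        0.0, float(delay), [Pool(a, tau) for tau, a in sorted(pools.items())]
    )
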