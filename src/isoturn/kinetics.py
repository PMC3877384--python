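"""Multi-pool exponential turnover kinetics.

The central object is a compartment model for an output stream after a diet
switch,

    delta(t) = c + sum_p a_p * exp(-(t - delay) / tau_p),   t > delay,

with the pre-switch plateau c + sum_p a_p for t <= delay.  ``c`` is the
asymptote reached on the new diet, each pool p has amplitude ``a_p`` (its
share of the total isotopic shift, sign = direction of the switch) and mean
residence time ``tau_p``; the pool half-life is t_1/2 = tau * ln 2.  The
delay is the lag between ingestion and first appearance of the new dietary
signal in the output (passage time), preceding exponential washout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Pool",
    "CompartmentModel",
    "half_life",
    "gross_half_life",
    "kernel_value",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Pool:
    """One kinetic pool: amplitude (permil) and mean residence time (h)."""

    amplitude_a: float
    tau: float

    def __post_init__(self):
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if not math.isfinite(self.amplitude_a):
            raise ValueError("amplitude must be finite")

    @property
    def half_life(self) -> float:
        return self.tau * LN2

    @classmethod
    def from_half_life(cls, amplitude_a: float, t_half: float) -> "Pool":
        return cls(amplitude_a, t_half / LN2)


def half_life(pool: Pool) -> float:
    """Pool half-life t_1/2 = tau * ln 2, in hours."""
    return pool.tau * LN2


class CompartmentModel:
    """Delayed multi-pool exponential model of one output stream.

    Parameters
    ----------
    c : float
        Asymptotic baseline (permil), the value after complete turnover on
        the new diet.
    delay_h : float
        Ingestion-to-output delay in hours (>= 0).
    pools : sequence of Pool
        1-4 pools.  Stored sorted by ascending tau (exponential mixtures are
        permutation invariant); taus must be distinct.
    """

    def __init__(self, c: float, delay_h: float, pools: Sequence[Pool]):
        pools = [p if isinstance(p, Pool) else Pool(*p) for p in pools]
        if not 1 <= len(pools) <= 4:
            raise ValueError("need between 1 and 4 pools")
        if delay_h < 0 or not math.isfinite(delay_h):
            raise ValueError("delay_h must be finite and >= 0")
        if not math.isfinite(c):
            raise ValueError("c must be finite")
        pools = sorted(pools, key=lambda p: p.tau)
        taus = [p.tau for p in pools]
        if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("pool taus must be strictly increasing")
        self.c = float(c)
        self.delay_h = float(delay_h)
        self.pools = tuple(pools)

    # -- basic quantities -------------------------------------------------

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude_a for p in self.pools])

    @property
    def taus(self) -> np.ndarray:
        return np.array([p.tau for p in self.pools])

    @property
    def total_amplitude(self) -> float:
        return float(self.amplitudes.sum())

    @property
    def plateau(self) -> float:
        """Pre-switch value c + sum(a_p)."""
        return self.c + self.total_amplitude

    def same_signed(self) -> bool:
        a = self.amplitudes
        return bool(np.all(a >= 0) or np.all(a <= 0))

    def __repr__(self) -> str:
        pools = ", ".join(
            f"(a={p.amplitude_a:.4g}, t1/2={p.half_life:.4g} h)" for p in self.pools
        )
        return f"CompartmentModel(c={self.c:.4g}, delay={self.delay_h:.4g} h, [{pools}])"

    # -- evaluation --------------------------------------------------------

    def __call__(self, t) -> np.ndarray | float:
        return self.evaluate(t)

    def evaluate(self, t):
        """Model value at time(s) t; the plateau is returned for t <= delay."""
        t = np.asarray(t, dtype=float)
        u = np.maximum(t - self.delay_h, 0.0)
        out = self.c + np.sum(
            self.amplitudes[:, None] * np.exp(-u[None, :] / self.taus[:, None])
            if u.ndim
            else self.amplitudes * np.exp(-u / self.taus),
            axis=0,
        )
        return out if out.ndim else float(out)

    def decay(self, age_h):
        """sum_p a_p exp(-age/tau_p): the signed deviation from c at a given
        time-since-delay (defined for age >= 0)."""
        age = np.asarray(age_h, dtype=float)
        out = np.sum(
            self.amplitudes[:, None] * np.exp(-age[None, :] / self.taus[:, None])
            if age.ndim
            else self.amplitudes * np.exp(-age / self.taus),
            axis=0,
        )
        return out if out.ndim else float(out)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "c": self.c,
            "delay_h": self.delay_h,
            "pools": [{"a": p.amplitude_a, "tau": p.tau} for p in self.pools],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentModel":
        return cls(
            d["c"], d["delay_h"], [Pool(p["a"], p["tau"]) for p in d["pools"]]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CompartmentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def gross_half_life(
    model: CompartmentModel, tol: float = 1e-6, method: str = "auto"
) -> float:
    """Time after the switch (delay included) at which half of the total
    output shift is completed.

    Solves sum_p a_p exp(-(t - delay)/tau_p) = 1/2 sum_p a_p for the unique
    t > delay (bracketed root finding, tolerance ``tol`` hours).  For a
    one-pool model this is exactly delay + tau * ln 2, used as a shortcut
    unless ``method="root"`` forces the numerical solve.
    """
    a_tot = model.total_amplitude
    if a_tot == 0:
        raise ValueError("total amplitude is zero: no shift, no half-life")
    if not model.same_signed():
        raise ValueError("mixed-sign amplitudes: gross half-life undefined")
    if len(model.pools) == 1 and method != "root":
        return model.delay_h + model.pools[0].tau * LN2
    target = 0.5 * a_tot

    def f(u):
        return model.decay(u) - target

    hi = 6.0 * max(p.tau for p in model.pools) * LN2
    while f(hi) * f(0.0) > 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for same-sign pools
            raise RuntimeError("failed to bracket the gross half-life")
    u_star = brentq(f, 0.0, hi, xtol=tol)
    return model.delay_h + float(u_star)


def kernel_value(
    model: CompartmentModel, age_h, impulse_response: bool = False
):
    """Unnormalized turnover-kernel weight at a given input age.

    ``age_h`` is time since the input cleared the delay.  The default is the
    magnitude of the model value with the offset c removed,
    |sum_p a_p exp(-age/tau_p)|; taken as a magnitude so upward and downward
    switches weight history identically.  ``impulse_response=True`` uses
    |sum_p (a_p/tau_p) exp(-age/tau_p)| instead (the derivative form), kept
    as a sensitivity option.
    """
    if not model.same_signed():
        raise ValueError("mixed-sign amplitudes make the kernel non-monotone")
    age = np.asarray(age_h, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_h must be >= 0")
    amps = model.amplitudes / model.taus if impulse_response else model.amplitudes
    out = np.abs(
        np.sum(
            amps[:, None] * np.exp(-age[None, :] / model.taus[:, None])
            if age.ndim
            else amps * np.exp(-age / model.taus),
            axis=0,
        )
    )
    return out if out.ndim else float(out)
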