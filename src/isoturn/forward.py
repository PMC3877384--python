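"""Forward prediction of output delta13C from a fluctuating diet input.

A chase-fitted compartment model implies a weighting of the input history:
the output at time "now" is a convex combination of past diet values,

    delta_out(now) = sum_u w(u) * delta_in(now - delay - u) + shift,

where the weight at input age u (time since the input cleared the delay) is
the model's decay value |sum_p a_p exp(-u/tau_p)|, normalized over a history
window of six half-lives of the slowest pool.  ``shift`` is the constant
trophic offset between diet and output at equilibrium.  Because the weights
sum to one, input fluctuations are attenuated, never amplified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import t as student_t

from .kinetics import LN2, CompartmentModel, kernel_value
from .timeseries import IsotopeSeries, resample_to_grid

__all__ = [
    "WeightKernel",
    "ShiftEstimate",
    "ValidationReport",
    "CoverageError",
    "build_kernel",
    "predict_output",
    "estimate_shift",
    "validate",
    "validate_paired",
]


class CoverageError(ValueError):
    """Input history does not cover the span the prediction needs."""


@dataclass(frozen=True)
class ShiftEstimate:
    """Constant diet-to-output offset (trophic shift), permil."""

    shift_permil: float
    se: float = 0.0


@dataclass
class WeightKernel:
    """Discretized normalized input-history weights.

    ``weights[k]`` applies to the input at age ``k * step_h`` beyond the
    delay; ages run from 0 to ``window_h`` = six half-lives of the slowest
    pool.  Weights are nonnegative, non-increasing with age and sum to 1.
    """

    step_h: float
    weights: np.ndarray
    window_h: float
    delay_h: float
    truncated_mass: float  # fraction of the untruncated integral cut off

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("kernel weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1")
        self.weights = w

    @property
    def ages_h(self) -> np.ndarray:
        return self.step_h * np.arange(self.weights.size)


def build_kernel(
    model: CompartmentModel,
    step_h: float = 1.0,
    impulse_response: bool = False,
) -> WeightKernel:
    """Build the normalized history kernel of a fitted model.

    Raw weights are :func:`~isoturn.kinetics.kernel_value` evaluated at ages
    0, step, 2*step, ... up to six half-lives of the slowest pool, then
    normalized to sum 1.  The mass lost to the truncation (relative to the
    infinite-history sum) is recorded on the kernel.
    """
    if step_h <= 0:
        raise ValueError("step_h must be positive")
    if not model.same_signed():
        raise ValueError("kernel requires same-signed pool amplitudes")
    if model.total_amplitude == 0:
        raise ValueError("degenerate model: all amplitudes zero")
    t_half_max = max(p.tau for p in model.pools) * LN2
    window = 6.0 * t_half_max
    n = int(math.floor(window / step_h + 1e-9))
    ages = step_h * np.arange(n + 1)
    raw = kernel_value(model, ages, impulse_response=impulse_response)
    total = raw.sum()
    if total <= 0:
        raise ValueError("degenerate kernel: zero total weight")
    # tail mass beyond the window, from the closed-form geometric sums
    amps = np.abs(model.amplitudes / model.taus if impulse_response else model.amplitudes)
    r = np.exp(-step_h / model.taus)
    full = float(np.sum(amps / (1.0 - r)))
    truncated = max(0.0, 1.0 - total / full)
    return WeightKernel(
        step_h=step_h,
        weights=raw / total,
        window_h=window,
        delay_h=model.delay_h,
        truncated_mass=truncated,
    )


def predict_output(
    input_series: IsotopeSeries,
    model: CompartmentModel,
    kernel: WeightKernel | None = None,
    shift: ShiftEstimate | float = 0.0,
    times: Sequence[float] | None = None,
    step_h: float = 1.0,
) -> IsotopeSeries:
    """Predict output delta13C at the requested times.

    The input series is resampled onto the kernel grid with carried-forward
    values (batch-fed diet), then each output value is the kernel-weighted
    mean of the input over [now - delay - window, now - delay], plus the
    trophic shift.  Raises :class:`CoverageError` when the input does not
    span the needed history (no silent extrapolation).
    """
    if kernel is None:
        kernel = build_kernel(model, step_h)
    if times is None:
        raise ValueError("times must be given")
    times = np.asarray(times, dtype=float)
    sh = shift.shift_permil if isinstance(shift, ShiftEstimate) else float(shift)
    delay = kernel.delay_h
    # each weight represents one age cell [u, u + step); the input is read at
    # the cell midpoint, which aligns the discrete sum with the continuous
    # convolution (midpoint rule) and halves the discretization bias
    half = 0.5 * kernel.step_h
    need_lo = times.min() - delay - kernel.window_h - half
    need_hi = times.max() - delay
    have_lo, have_hi = input_series.times_h[0], input_series.times_h[-1]
    eps = 1e-9
    if need_lo < have_lo - eps or need_hi > have_hi + eps:
        raise CoverageError(
            f"input covers [{have_lo:g}, {have_hi:g}] h but the prediction "
            f"needs [{need_lo:g}, {need_hi:g}] h"
        )
    grid = resample_to_grid(input_series, kernel.step_h, method="previous")

    def input_at(ts: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(grid.times_h, ts + eps) - 1
        idx = np.clip(idx, 0, len(grid) - 1)
        return grid.values[idx]

    w = kernel.weights
    ages = kernel.ages_h + half
    preds = np.empty(times.size)
    for i, now in enumerate(times):
        preds[i] = float(w @ input_at(now - delay - ages)) + sh
    return IsotopeSeries(
        input_series.animal_id, "predicted", times, preds
    )


def continuous_step_response(
    model: CompartmentModel, delta: float, t: float, impulse_response: bool = False
) -> float:
    """Exact continuous-time convolution of a step input of size ``delta``
    at t = 0 with the (truncated, normalized) kernel: the completed fraction
    of the step at output time ``t``.  Test oracle for the discrete engine.
    """
    taus = model.taus
    amps = np.abs(model.amplitudes / taus if impulse_response else model.amplitudes)
    W = 6.0 * max(taus) * LN2
    denom = float(np.sum(amps * taus * (1.0 - np.exp(-W / taus))))
    u = t - model.delay_h
    if u <= 0:
        return 0.0
    u = min(u, W)
    num = float(np.sum(amps * taus * (1.0 - np.exp(-u / taus))))
    return delta * num / denom


def estimate_shift(
    measured: IsotopeSeries,
    predicted_no_shift: IsotopeSeries,
    match_tol_h: float | None = None,
) -> ShiftEstimate:
    """Trophic shift as the mean measured-minus-predicted difference.

    Pairs are matched by nearest time within ``match_tol_h`` (default: half
    the median predicted-time spacing, at least 1 h).  Needs >= 3 pairs.
    """
    tp = predicted_no_shift.times_h
    if match_tol_h is None:
        spacing = np.median(np.diff(tp)) if tp.size > 1 else 2.0
        match_tol_h = max(1.0, 0.5 * float(spacing))
    diffs = []
    for t, v in measured:
        j = int(np.argmin(np.abs(tp - t)))
        if abs(tp[j] - t) <= match_tol_h:
            diffs.append(v - predicted_no_shift.values[j])
    if len(diffs) < 3:
        raise ValueError(
            f"only {len(diffs)} overlapping time point(s); need >= 3"
        )
    d = np.asarray(diffs)
    return ShiftEstimate(
        shift_permil=float(d.mean()),
        se=float(d.std(ddof=1) / math.sqrt(d.size)) if d.size > 1 else 0.0,
    )


@dataclass
class ValidationReport:
    """Measured-vs-predicted agreement statistics."""

    rmse: float
    n: int
    slope: float | None
    slope_se: float | None
    p_slope_vs_1: float | None
    intercept: float | None
    intercept_se: float | None
    p_intercept_vs_0: float | None
    prediction_interval_halfwidth: float
    confidence: float = 0.95

    def to_dict(self) -> dict:
        return {k: (None if v is None else float(v) if not isinstance(v, int) else v)
                for k, v in self.__dict__.items()}


def validate(
    measured: IsotopeSeries,
    predicted: IsotopeSeries,
    confidence: float = 0.95,
    match_tol_h: float = 1.0,
) -> ValidationReport:
    """Validate predictions against measurements.

    RMSE is computed on the raw paired differences.  Measured values are
    regressed on predicted by OLS, with t-tests of slope against 1 and
    intercept against 0 (agreement means both non-significant).  The
    prediction-interval half-width is SD * T_a with SD the standard
    deviation of the paired differences and T_a the Student-t percentile at
    n - 1 degrees of freedom.  A zero-variance predictor skips the
    regression but still reports RMSE.
    """
    tp = predicted.times_h
    pairs = []
    for t, v in measured:
        j = int(np.argmin(np.abs(tp - t)))
        if abs(tp[j] - t) <= match_tol_h:
            pairs.append((v, predicted.values[j]))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} paired point(s); need >= 3")
    y, x = np.array(pairs).T
    return validate_paired(y, x, confidence)


def validate_paired(
    measured_values, predicted_values, confidence: float = 0.95
) -> ValidationReport:
    """:func:`validate` on already-paired value arrays (e.g. pooled across
    animals)."""
    y = np.asarray(measured_values, dtype=float)
    x = np.asarray(predicted_values, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 measured/predicted pairs of equal length")
    resid = y - x
    n = y.size
    rmse = float(np.sqrt(np.mean(resid**2)))
    sd = float(resid.std(ddof=1))
    ta = float(student_t.ppf(1 - (1 - confidence) / 2, n - 1))
    if np.ptp(x) < 1e-12:
        return ValidationReport(
            rmse, n, None, None, None, None, None, None, sd * ta, confidence
        )
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    icpt, slope = ols.params
    se_i, se_s = ols.bse
    t_slope = (slope - 1.0) / se_s
    p_slope = 2 * float(student_t.sf(abs(t_slope), n - 2))
    t_icpt = icpt / se_i
    p_icpt = 2 * float(student_t.sf(abs(t_icpt), n - 2))
    return ValidationReport(
        rmse=rmse,
        n=n,
        slope=float(slope),
        slope_se=float(se_s),
        p_slope_vs_1=p_slope,
        intercept=float(icpt),
        intercept_se=float(se_i),
        p_intercept_vs_0=p_icpt,
        prediction_interval_halfwidth=sd * ta,
        confidence=confidence,
    )
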