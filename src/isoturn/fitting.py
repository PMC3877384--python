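"""Nonlinear least-squares fitting of multi-pool turnover models.

The estimation problem: chase-period delta13C series from several animals
are fitted jointly with the delayed multi-exponential model (see
:mod:`isoturn.kinetics`), where each parameter (asymptote ``c``, pool
amplitudes ``a_p``, residence times ``tau_p``) is either shared across all
animals or estimated per animal.  Candidate pool counts (1-4) and sharing
structures are compared by AIC; per-animal variants are only kept when they
beat the shared fit by at least 2 AIC units.

The interface follows the Model/Results convention: build a
:class:`TurnoverModel` from the data, call :meth:`TurnoverModel.fit`, and
inspect the returned :class:`TurnoverResults` (estimates, standard errors,
log-likelihood, AIC, per-animal :class:`~isoturn.kinetics.CompartmentModel`
objects, ``summary()``).

Internally the fit uses variable projection: for fixed residence times the
model is linear in ``c`` and the amplitudes, which are therefore solved by
ordinary least squares inside the residual function, leaving only the
log-residence-times to the trust-region optimizer.  Eight deterministic
multistarts with initial residence times log-spaced in [2 h, 200 h] guard
against local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear
from scipy.stats import t as student_t

from .kinetics import LN2, CompartmentModel, Pool
from .timeseries import IsotopeSeries

__all__ = [
    "SharingStructure",
    "TurnoverModel",
    "TurnoverResults",
    "HalfLifeCI",
    "ConvergenceError",
    "fit_model",
    "select_model",
    "half_life_ci",
    "DEFAULT_STRUCTURES",
]

SHARED = "shared"
PER_ANIMAL = "per_animal"

TAU_INIT_RANGE = (2.0, 200.0)  # h
LOG_TAU_BOUNDS = (math.log(1e-2), math.log(1e4))
N_STARTS = 8
SSR_FTOL = 1e-10


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SharingStructure:
    """Which parameters are shared across animals vs. estimated per animal."""

    c: str = SHARED
    a: str = SHARED
    tau: str = SHARED

    def __post_init__(self):
        for f in (self.c, self.a, self.tau):
            if f not in (SHARED, PER_ANIMAL):
                raise ValueError(f"sharing flag must be 'shared' or 'per_animal', got {f!r}")

    def label(self) -> str:
        def s(x):
            return "s" if x == SHARED else "i"

        return f"c:{s(self.c)} a:{s(self.a)} tau:{s(self.tau)}"


FULLY_SHARED = SharingStructure()
#: Default candidate set for model selection: fully shared plus one
#: per-animal relaxation of each parameter.
DEFAULT_STRUCTURES = (
    FULLY_SHARED,
    SharingStructure(c=PER_ANIMAL),
    SharingStructure(a=PER_ANIMAL),
    SharingStructure(tau=PER_ANIMAL),
)


@dataclass(frozen=True)
class HalfLifeCI:
    t_half: float
    lower: float
    upper: float
    confidence: float = 0.95

    def __post_init__(self):
        if not self.lower <= self.t_half <= self.upper:
            raise ValueError("half-life CI must be ordered: lower <= t_half <= upper")


class TurnoverModel:
    """Joint delayed multi-exponential model for a set of chase series.

    Parameters
    ----------
    chase_series : sequence of IsotopeSeries
        One chase-period series per animal (same stream).  Only samples with
        ``time_h >= delay_h`` enter the fit.
    pool_count : int
        Number of exponential pools, 1-4.
    structure : SharingStructure
        Per-parameter sharing across animals.
    delay_h : float
        Ingestion delay, held fixed during the fit (estimated separately;
        see :mod:`isoturn.delay`).
    """

    def __init__(
        self,
        chase_series: Sequence[IsotopeSeries],
        pool_count: int = 1,
        structure: SharingStructure = FULLY_SHARED,
        delay_h: float = 0.0,
    ):
        if not 1 <= pool_count <= 4:
            raise ValueError("pool_count must be between 1 and 4")
        if delay_h < 0:
            raise ValueError("delay_h must be >= 0")
        series = sorted(chase_series, key=lambda s: s.animal_id)
        if not series:
            raise ValueError("no series given")
        self.pool_count = int(pool_count)
        self.structure = structure
        self.delay_h = float(delay_h)
        self.animals = [s.animal_id for s in series]
        if len(set(self.animals)) != len(self.animals):
            raise ValueError("one chase series per animal expected")
        self.stream = series[0].stream

        ts, ys, gs = [], [], []
        for gi, s in enumerate(series):
            m = s.times_h >= delay_h
            ts.append(s.times_h[m])
            ys.append(s.values[m])
            gs.append(np.full(m.sum(), gi))
        self.t = np.concatenate(ts)
        self.y = np.concatenate(ys)
        self.group = np.concatenate(gs).astype(int)
        self.n_obs = self.y.size
        self._a_sign = self._amplitude_sign()
        if self.n_obs < self.n_params + 3:
            raise ValueError(
                f"too few observations ({self.n_obs}) for {self.n_params} parameters"
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, stream: str, delay_h: float = 0.0, **kw
    ) -> "TurnoverModel":
        """Build from a long DataFrame (columns animal_id, stream, time_h,
        delta13C), keeping one stream's post-delay samples."""
        sub = df[df["stream"] == stream]
        series = [
            IsotopeSeries(str(a), stream, g["time_h"], g["delta13C"])
            for a, g in sub.groupby("animal_id")
        ]
        return cls(series, delay_h=delay_h, **kw)

    # -- parameter bookkeeping --------------------------------------------

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def _count(self, flag: str, per_pool: bool) -> int:
        base = self.pool_count if per_pool else 1
        return base * (self.n_animals if flag == PER_ANIMAL else 1)

    @property
    def n_mean_params(self) -> int:
        return (
            self._count(self.structure.c, False)
            + self._count(self.structure.a, True)
            + self._count(self.structure.tau, True)
        )

    @property
    def n_params(self) -> int:
        """Mean parameters plus the residual variance."""
        return self.n_mean_params + 1

    # -- variable projection ----------------------------------------------

    def _tau_matrix(self, theta: np.ndarray) -> np.ndarray:
        """log-tau vector -> (n_animals, pool_count) tau array."""
        tau = np.exp(theta)
        if self.structure.tau == SHARED:
            return np.tile(tau, (self.n_animals, 1))
        return tau.reshape(self.n_animals, self.pool_count)

    def _design(self, taus: np.ndarray) -> np.ndarray:
        """Design matrix for the linear parameters (c then amplitudes)."""
        n, P, A = self.n_obs, self.pool_count, self.n_animals
        u = self.t - self.delay_h
        E = np.exp(-u[:, None] / taus[self.group])  # (n, P) pool regressors
        cols = []
        if self.structure.c == SHARED:
            cols.append(np.ones((n, 1)))
        else:
            cols.append((self.group[:, None] == np.arange(A)[None, :]).astype(float))
        if self.structure.a == SHARED:
            cols.append(E)
        else:
            X = np.zeros((n, P * A))
            for gi in range(A):
                m = self.group == gi
                X[np.ix_(m, gi * P + np.arange(P))] = E[m]
            cols.append(X)
        return np.hstack(cols)

    def _amplitude_sign(self) -> float:
        """Direction of the washout, from early vs. late chase means.

        A diet switch drives every pool the same way, so all amplitudes are
        constrained to this common sign; mixed-sign solutions are spurious
        (they mimic shared short-term input fluctuations, not turnover).
        """
        order = np.argsort(self.t)
        k = max(self.n_obs // 4, 1)
        early = self.y[order[:k]].mean()
        late = self.y[order[-k:]].mean()
        return 1.0 if early >= late else -1.0

    def _solve_linear(self, taus: np.ndarray):
        X = self._design(taus)
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        nc = self._count(self.structure.c, False)
        sign = self._a_sign
        if np.all(sign * beta[nc:] >= 0):
            return beta, X
        # sign constraint active: bounded linear least squares
        n_amp = beta.size - nc
        lo = np.concatenate(
            [np.full(nc, -np.inf), np.zeros(n_amp) if sign > 0 else np.full(n_amp, -np.inf)]
        )
        hi = np.concatenate(
            [np.full(nc, np.inf), np.full(n_amp, np.inf) if sign > 0 else np.zeros(n_amp)]
        )
        res = lsq_linear(X, self.y, bounds=(lo, hi), method="bvls")
        return res.x, X

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        beta, X = self._solve_linear(self._tau_matrix(theta))
        return self.y - X @ beta

    def _starts(self, seed: int) -> list[np.ndarray]:
        """Eight deterministic starting points for the log-tau search."""
        lo, hi = TAU_INIT_RANGE
        P = self.pool_count
        anchors = np.geomspace(lo, hi, N_STARTS)
        seeds = np.random.SeedSequence(seed).spawn(N_STARTS)
        starts = []
        for j in range(N_STARTS):
            rng = np.random.default_rng(seeds[j])
            spread = np.geomspace(1.0, 3.0 ** max(P - 1, 1), P)
            taus = np.clip(anchors[j] * spread, lo, hi * 3)
            taus *= np.exp(rng.uniform(-0.05, 0.05, P))
            taus = np.sort(taus) * (1 + 1e-3 * np.arange(P))  # keep distinct
            theta = np.log(taus)
            if self.structure.tau == PER_ANIMAL:
                theta = np.tile(theta, self.n_animals)
            starts.append(theta)
        return starts

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0) -> "TurnoverResults":
        """Multistart variable-projection least squares; best SSR wins."""
        best = None
        n_theta = self.pool_count * (
            self.n_animals if self.structure.tau == PER_ANIMAL else 1
        )
        for theta0 in self._starts(seed):
            try:
                res = least_squares(
                    self._residuals,
                    theta0,
                    bounds=(
                        np.full(n_theta, LOG_TAU_BOUNDS[0]),
                        np.full(n_theta, LOG_TAU_BOUNDS[1]),
                    ),
                    ftol=SSR_FTOL,
                    xtol=1e-12,
                    gtol=1e-12,
                    method="trf",
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
            ssr = float(res.cost * 2)
            if res.status > 0 and (best is None or ssr < best[0] - 0.0):
                best = (ssr, res)
        if best is None:
            return TurnoverResults(self, None, converged=False)
        return TurnoverResults(self, best[1].x, converged=True)


class TurnoverResults:
    """Fitted turnover model: estimates, uncertainties and diagnostics.

    Attributes of note: ``params`` / ``bse`` (pandas Series keyed by
    parameter name, e.g. ``tau1``, ``a1[cow3]``), ``llf``, ``aic``,
    ``resid_sd``, ``models`` (per-animal CompartmentModel), ``converged``.
    """

    def __init__(self, model: TurnoverModel, theta, converged: bool):
        self.model = model
        self.converged = bool(converged)
        self.nobs = model.n_obs
        self.n_params = model.n_params
        if not converged:
            self.params = pd.Series(dtype=float)
            self.bse = pd.Series(dtype=float)
            self.llf = -np.inf
            self.aic = np.inf
            self.resid_sd = np.nan
            self.models = {}
            return
        theta = np.asarray(theta, dtype=float)
        taus = model._tau_matrix(theta)
        beta, X = model._solve_linear(taus)
        order = self._canonical_order(taus)
        taus, beta = self._apply_order(taus, beta, order)
        self._taus = taus
        self._beta = beta
        resid = model.y - model._design(taus) @ beta
        self.ssr = float(resid @ resid)
        n = self.nobs
        sigma2_mle = self.ssr / n
        self.llf = -0.5 * n * (math.log(2 * math.pi * sigma2_mle) + 1)
        self.aic = 2 * self.n_params - 2 * self.llf
        dof = max(n - model.n_mean_params, 1)
        self.resid_sd = math.sqrt(self.ssr / dof)
        self.params, self.bse = self._params_and_se(taus, beta)
        self.models = self._build_models(taus, beta)

    # -- canonicalization ---------------------------------------------------

    def _canonical_order(self, taus: np.ndarray) -> np.ndarray:
        return np.argsort(taus.mean(axis=0))

    def _apply_order(self, taus, beta, order):
        m = self.model
        taus = taus[:, order]
        nc = m._count(m.structure.c, False)
        c_part, a_part = beta[:nc], beta[nc:]
        if m.structure.a == SHARED:
            a_part = a_part[order]
        else:
            a_part = a_part.reshape(m.n_animals, m.pool_count)[:, order].ravel()
        return taus, np.concatenate([c_part, a_part])

    # -- parameter table ------------------------------------------------------

    def _param_names(self) -> list[str]:
        m = self.model
        names = []
        if m.structure.c == SHARED:
            names.append("c")
        else:
            names += [f"c[{a}]" for a in m.animals]
        if m.structure.a == SHARED:
            names += [f"a{p + 1}" for p in range(m.pool_count)]
        else:
            names += [
                f"a{p + 1}[{a}]" for a in m.animals for p in range(m.pool_count)
            ]
        if m.structure.tau == SHARED:
            names += [f"tau{p + 1}" for p in range(m.pool_count)]
        else:
            names += [
                f"tau{p + 1}[{a}]" for a in m.animals for p in range(m.pool_count)
            ]
        return names

    def _full_vector(self, taus, beta) -> np.ndarray:
        m = self.model
        if m.structure.tau == SHARED:
            tau_vec = taus[0]
        else:
            tau_vec = taus.ravel()
        return np.concatenate([beta, tau_vec])

    def _predict_full(self, vec: np.ndarray) -> np.ndarray:
        m = self.model
        k_lin = m._count(m.structure.c, False) + m._count(m.structure.a, True)
        beta, tau_vec = vec[:k_lin], vec[k_lin:]
        if m.structure.tau == SHARED:
            taus = np.tile(tau_vec, (m.n_animals, 1))
        else:
            taus = tau_vec.reshape(m.n_animals, m.pool_count)
        return m._design(taus) @ beta

    def _params_and_se(self, taus, beta):
        vec = self._full_vector(taus, beta)
        names = self._param_names()
        # Gauss-Newton covariance from a forward-difference Jacobian
        f0 = self._predict_full(vec)
        J = np.empty((self.nobs, vec.size))
        for j in range(vec.size):
            h = 1e-6 * max(abs(vec[j]), 1e-3)
            vp = vec.copy()
            vp[j] += h
            J[:, j] = (self._predict_full(vp) - f0) / h
        dof = max(self.nobs - vec.size, 1)
        sigma2 = self.ssr / dof
        JtJ = J.T @ J
        try:
            cov = sigma2 * np.linalg.pinv(JtJ)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = np.full(vec.size, np.nan)
        self.cov_params = pd.DataFrame(cov, index=names, columns=names)
        return (
            pd.Series(vec, index=names),
            pd.Series(se, index=names),
        )

    def _build_models(self, taus, beta) -> dict[str, CompartmentModel]:
        m = self.model
        nc = m._count(m.structure.c, False)
        out = {}
        for gi, animal in enumerate(m.animals):
            c = beta[0] if m.structure.c == SHARED else beta[gi]
            if m.structure.a == SHARED:
                amps = beta[nc : nc + m.pool_count]
            else:
                amps = beta[nc + gi * m.pool_count : nc + (gi + 1) * m.pool_count]
            pools = _merge_collapsed(amps, taus[gi])
            out[animal] = CompartmentModel(float(c), m.delay_h, pools)
        return out

    # -- derived quantities ---------------------------------------------------

    def is_degenerate(
        self, tau_ratio_min: float = 1.1, amp_frac_min: float = 1e-3
    ) -> bool:
        """True when the nominal pool count is not supported: adjacent
        residence times collapsed onto each other (ratio < tau_ratio_min) or
        a pool's amplitude vanished relative to the total.  Such fits are
        redundant re-fits of a smaller model and are excluded from model
        selection."""
        if not self.converged:
            return True
        if self.model.pool_count == 1:
            return False
        # a pool slower than the observation window is not identifiable:
        # its exponential is collinear with the constant baseline c
        span = float(self.model.t.max() - self.model.delay_h)
        for m in self.models.values():
            if len(m.pools) < self.model.pool_count:
                return True  # pools merged during canonicalization
            taus = m.taus
            if np.any(taus[1:] / taus[:-1] < tau_ratio_min):
                return True
            if np.any(taus * LN2 > span):
                return True
            amps = np.abs(m.amplitudes)
            if amps.sum() > 0 and np.any(amps < amp_frac_min * amps.sum()):
                return True
        return False

    def tau_estimate(self, pool_index: int):
        """(value, SE) for tau of one pool (1-based index).

        Per-animal residence times are summarized by their mean across
        animals with SE = sd / sqrt(n_animals).
        """
        m = self.model
        if not self.converged:
            raise ConvergenceError("fit did not converge")
        if not 1 <= pool_index <= m.pool_count:
            raise IndexError("pool_index out of range")
        if m.structure.tau == SHARED:
            name = f"tau{pool_index}"
            return float(self.params[name]), float(self.bse[name])
        vals = np.array(
            [self.params[f"tau{pool_index}[{a}]"] for a in m.animals]
        )
        return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(vals.size))

    def half_life(self, pool_index: int) -> float:
        return self.tau_estimate(pool_index)[0] * LN2

    def half_life_ci(self, pool_index: int, confidence: float = 0.95) -> HalfLifeCI:
        """t_1/2 +/- SE * T_a with T_a the Student-t percentile at
        (n_animals - 1) degrees of freedom; SE by the delta method."""
        tau, se_tau = self.tau_estimate(pool_index)
        if not np.isfinite(se_tau):
            raise ValueError(
                f"standard error unavailable for pool {pool_index} "
                "(non-identifiable pool)"
            )
        th = tau * LN2
        se = se_tau * LN2
        ta = float(student_t.ppf(1 - (1 - confidence) / 2, self.model.n_animals - 1))
        return HalfLifeCI(th, th - se * ta, th + se * ta, confidence)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Turnover model fit",
            f"  stream: {m.stream}   animals: {m.n_animals}   n_obs: {self.nobs}",
            f"  pools: {m.pool_count}   structure: {m.structure.label()}   "
            f"delay (fixed): {m.delay_h:g} h",
            f"  converged: {self.converged}",
        ]
        if self.converged:
            lines += [
                f"  SSR: {self.ssr:.6g}   resid SD: {self.resid_sd:.4g} permil",
                f"  logLik: {self.llf:.4f}   AIC: {self.aic:.4f}   "
                f"k: {self.n_params}",
                "",
                f"  {'param':<14}{'estimate':>12}{'SE':>12}",
            ]
            for name in self.params.index:
                lines.append(
                    f"  {name:<14}{self.params[name]:>12.5g}{self.bse[name]:>12.3g}"
                )
            for p in range(1, m.pool_count + 1):
                try:
                    ci = self.half_life_ci(p)
                    lines.append(
                        f"  pool {p} t1/2: {ci.t_half:.2f} h "
                        f"(95% CI {ci.lower:.2f}-{ci.upper:.2f})"
                    )
                except (ValueError, ConvergenceError):
                    lines.append(f"  pool {p} t1/2: unavailable")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "stream": self.model.stream,
            "pool_count": self.model.pool_count,
            "structure": self.model.structure.label(),
            "delay_h": self.model.delay_h,
            "converged": self.converged,
            "n_obs": self.nobs,
            "n_params": self.n_params,
            "log_likelihood": self.llf if np.isfinite(self.llf) else None,
            "aic": self.aic if np.isfinite(self.aic) else None,
            "residual_sd": None if not self.converged else self.resid_sd,
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
        }


def _merge_collapsed(amps, taus, rtol: float = 1e-6):
    """Merge pools whose residence times collapsed onto each other so the
    resulting CompartmentModel keeps strictly increasing taus."""
    order = np.argsort(taus)
    amps, taus = np.asarray(amps)[order], np.asarray(taus)[order]
    pools: list[list[float]] = []
    for a, tau in zip(amps, taus):
        if pools and abs(tau - pools[-1][1]) <= rtol * pools[-1][1]:
            pools[-1][0] += a
        else:
            pools.append([float(a), float(tau)])
    return [Pool(a, tau) for a, tau in pools]


# -- functional wrappers ------------------------------------------------------


def fit_model(
    chase_series: Sequence[IsotopeSeries],
    pool_count: int,
    structure: SharingStructure = FULLY_SHARED,
    delay_h: float = 0.0,
    seed: int = 0,
) -> TurnoverResults:
    """Fit one (pool_count, structure) candidate; see :class:`TurnoverModel`."""
    return TurnoverModel(chase_series, pool_count, structure, delay_h).fit(seed)


def select_model(
    chase_series: Sequence[IsotopeSeries],
    max_pools: int = 4,
    structures: Sequence[SharingStructure] = (FULLY_SHARED,),
    delay_h: float = 0.0,
    seed: int = 0,
    min_pools: int = 1,
) -> TurnoverResults:
    """Fit every (pool count, sharing structure) candidate and pick by AIC.

    The candidate with minimal AIC wins, except that a candidate with fewer
    parameters beats a more complex one whenever their AICs differ by less
    than 2 (parsimony tie-break).  Attaches a ``candidates`` DataFrame to
    the returned results.
    """
    if not 1 <= max_pools <= 4:
        raise ValueError("max_pools must be between 1 and 4")
    fits, rows = [], []
    for P, structure in product(range(min_pools, max_pools + 1), structures):
        try:
            fr = fit_model(chase_series, P, structure, delay_h, seed)
        except ValueError as exc:  # e.g. too few observations for this P
            rows.append((P, structure.label(), None, None, False, str(exc)))
            continue
        degenerate = fr.is_degenerate()
        rows.append(
            (P, structure.label(), fr.n_params, fr.aic, fr.converged,
             "degenerate" if degenerate and fr.converged else "")
        )
        if fr.converged and not degenerate:
            fits.append(fr)
    table = pd.DataFrame(
        rows, columns=["pool_count", "structure", "n_params", "aic", "converged", "note"]
    )
    if not fits:
        raise ConvergenceError(
            "no candidate converged:\n" + table.to_string(index=False)
        )
    best_aic = min(f.aic for f in fits)
    admissible = [f for f in fits if f.aic < best_aic + 2.0]
    best = min(admissible, key=lambda f: (f.n_params, f.aic))
    best.candidates = table
    return best


def half_life_ci(
    fit: TurnoverResults, pool_index: int, confidence: float = 0.95
) -> HalfLifeCI:
    """Module-level alias for :meth:`TurnoverResults.half_life_ci`."""
    return fit.half_life_ci(pool_index, confidence)
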