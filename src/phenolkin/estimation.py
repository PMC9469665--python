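"""SSR-minimising nonlinear regression for the batch kinetic models.

The inference chain mirrors standard practice for batch biodegradation
studies: extract the specific growth rate from the slope of ln(X/X0) over the
detected log phase, fit the logistic model to each growth curve, fit the
Haldane model to the (S, mu) rate profile, and fit the modified Gompertz
model to each degradation curve.  Every fit minimises the sum of squared
residuals (SSR) with a bounded trust-region least-squares solver inside a
seeded multistart, so results are fully deterministic given (data, seed).

The public surface is statsmodels-shaped: build a model object from data,
call :meth:`~KineticsModel.fit`, and read estimates, standard errors and
diagnostics off the returned :class:`KineticsFitResult` (or print its
``summary()``).  Thin functional wrappers (:func:`fit_logistic`,
:func:`fit_haldane`, :func:`fit_gompertz`) are provided for pipeline use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .data import RatePoint, TimeSeries
from .models import (
    GompertzParams,
    HaldaneParams,
    LogisticParams,
    gompertz_remaining,
    haldane_mu,
    logistic_density,
)

__all__ = [
    "ssr",
    "LogPhaseWindow",
    "NoLogPhaseError",
    "NonConvergenceError",
    "detect_log_phase",
    "estimate_specific_growth_rate",
    "multistart_minimize",
    "KineticsFitResult",
    "KineticsModel",
    "LogisticGrowthModel",
    "HaldaneModel",
    "GompertzDegradationModel",
    "fit_logistic",
    "fit_haldane",
    "fit_gompertz",
]

# Parameter bounds used by every fit. Lower bounds are open intervals in
# principle; 1e-8 stands in for 0+ inside the solver.
BOUNDS = {
    "mu": (1e-8, 10.0),      # specific growth rates, 1/h
    "X": (1e-8, 10.0),       # OD600 densities
    "Ks": (1e-8, 1e4),       # mg/L
    "Ki": (1e-8, 1e6),       # mg/L
    "Rm": (1e-8, 100.0),     # mg/L/h
    "lam": (-50.0, 200.0),   # h
}

_FTOL = 1e-12


class NoLogPhaseError(ValueError):
    """No admissible exponential-phase window exists in the series."""


class NonConvergenceError(RuntimeError):
    """Every multistart restart failed; carries the best-effort parameters."""

    def __init__(self, message: str, best_params=None, best_value=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_value = best_value


def ssr(observed, predicted) -> float:
    """Sum of squared residuals between paired observations and predictions."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.shape} vs predicted {predicted.shape}"
        )
    if observed.size < 1:
        raise ValueError("need at least one paired observation")
    r = observed - predicted
    return float(np.dot(r, r))


@dataclass(frozen=True)
class LogPhaseWindow:
    """An inclusive index window [start_index, end_index] into a TimeSeries,
    plus the R^2 of the ln-linear fit over that window."""

    start_index: int
    end_index: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.end_index - self.start_index < 3:
            raise ValueError("log-phase window needs at least 4 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    @property
    def n_points(self) -> int:
        return self.end_index - self.start_index + 1


def _ln_linear_r2(t: np.ndarray, y: np.ndarray) -> float:
    """R^2 of an OLS line through (t, ln y)."""
    ln_y = np.log(y)
    slope, intercept = np.polyfit(t, ln_y, 1)
    resid = ln_y - (slope * t + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((ln_y - ln_y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def detect_log_phase(
    ts: TimeSeries,
    lower_frac: float = 0.05,
    upper_frac: float = 0.70,
    min_points: int = 4,
) -> LogPhaseWindow:
    """Locate the exponential-growth window of a biomass series.

    Candidate windows are contiguous runs of at least ``min_points`` replicate
    means lying within ``[lower_frac, upper_frac]`` of the series maximum —
    i.e. past the lag but before the curve bends toward stationary phase.
    Among candidates, the window maximising the R^2 of ln(mean) versus time
    wins; ties break toward the longest, then the earliest, window.
    """
    if ts.kind != "biomass":
        raise ValueError("log-phase detection applies to biomass series")
    m = ts.replicate_mean()
    peak = m.max()
    admissible = (m >= lower_frac * peak) & (m <= upper_frac * peak) & (m > 0)

    best: LogPhaseWindow | None = None
    n = m.size
    for i in range(n):
        if not admissible[i]:
            continue
        for j in range(i + min_points - 1, n):
            if not admissible[i : j + 1].all():
                break
            r2 = _ln_linear_r2(ts.times[i : j + 1], m[i : j + 1])
            cand = LogPhaseWindow(i, j, r2)
            if best is None:
                best = cand
                continue
            if cand.r_squared > best.r_squared + 1e-12:
                best = cand
            elif abs(cand.r_squared - best.r_squared) <= 1e-12:
                if cand.n_points > best.n_points or (
                    cand.n_points == best.n_points
                    and cand.start_index < best.start_index
                ):
                    best = cand
    if best is None:
        raise NoLogPhaseError(
            "no contiguous window of >= "
            f"{min_points} points lies within [{lower_frac:.0%}, "
            f"{upper_frac:.0%}] of the series maximum"
        )
    return best


def estimate_specific_growth_rate(ts: TimeSeries, window: LogPhaseWindow) -> float:
    """OLS slope of ln(X / X0) against time over the log-phase window.

    X is the replicate mean and X0 the first in-window mean; the slope is the
    specific growth rate mu in 1/h and is invariant to rescaling of the
    biomass units.
    """
    if window.end_index >= ts.times.size:
        raise ValueError("window extends past the series")
    m = ts.replicate_mean()[window.start_index : window.end_index + 1]
    t = ts.times[window.start_index : window.end_index + 1]
    if np.any(m <= 0):
        raise ValueError("nonpositive biomass values inside the log-phase window")
    y = np.log(m / m[0])
    slope = float(np.polyfit(t, y, 1)[0])
    return slope


def _draw_start(rng: np.random.Generator, bounds: Sequence[tuple[float, float]]):
    """One random restart point: log-uniform over positive bounds, uniform
    over bounds that admit negative values."""
    x = np.empty(len(bounds))
    for k, (lo, hi) in enumerate(bounds):
        if lo > 0:
            x[k] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        else:
            x[k] = rng.uniform(lo, hi)
    return x


def multistart_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    n_restarts: int = 20,
    seed: int = 0,
    x0: np.ndarray | None = None,
    residuals: Callable[[np.ndarray], np.ndarray] | None = None,
):
    """Seeded multistart local minimisation over box bounds.

    The first start is the heuristic guess ``x0`` (midpoint of the bounds in
    log/linear space if omitted); the remaining ``n_restarts - 1`` starts are
    drawn from the seeded generator, log-uniformly for positive-bounded
    parameters.  Each start is refined by a bounded trust-region
    least-squares solve when ``residuals`` is supplied (objective must then
    equal the sum of squared residuals), otherwise by Nelder–Mead.  The best
    value wins; exact ties keep the earliest restart.  Fully deterministic
    given (objective, bounds, n_restarts, seed); increasing ``n_restarts``
    with the same seed can only improve (never worsen) the result because
    the start sequence is a prefix-stable stream.

    Returns
    -------
    (best_x, best_value, info) : tuple
        ``info`` carries ``converged``, ``n_restarts_used`` and, for
        least-squares solves, the Jacobian at the optimum.
    """
    if n_restarts < 1:
        raise ValueError("need at least one restart")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for lo, hi in bounds:
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"bounds must be finite nonempty intervals, got ({lo}, {hi})")
    rng = np.random.default_rng(seed)

    if x0 is None:
        x0 = np.array(
            [
                math.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
                for lo, hi in bounds
            ]
        )
    lo_arr = np.array([b[0] for b in bounds])
    hi_arr = np.array([b[1] for b in bounds])
    x0 = np.clip(np.asarray(x0, dtype=float), lo_arr, hi_arr)

    best_x = None
    best_val = math.inf
    best_jac = None
    any_converged = False

    for k in range(n_restarts):
        start = x0 if k == 0 else _draw_start(rng, bounds)
        try:
            if residuals is not None:
                res = least_squares(
                    residuals,
                    start,
                    bounds=(lo_arr, hi_arr),
                    method="trf",
                    xtol=_FTOL,
                    ftol=_FTOL,
                    gtol=_FTOL,
                )
                x, val, ok, jac = res.x, 2.0 * res.cost, res.success, res.jac
            else:
                res = minimize(
                    objective,
                    start,
                    method="Nelder-Mead",
                    bounds=bounds,
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
                )
                x, val, ok, jac = res.x, res.fun, res.success, None
        except (ValueError, FloatingPointError):
            continue
        if not math.isfinite(val):
            continue
        any_converged = any_converged or bool(ok)
        if val < best_val:  # strict: ties keep the earliest restart
            best_x, best_val, best_jac = x, val, jac

    if best_x is None or not any_converged:
        raise NonConvergenceError(
            f"no restart converged after {n_restarts} attempts",
            best_params=best_x,
            best_value=best_val if best_x is not None else None,
        )
    info = {"converged": True, "n_restarts_used": n_restarts, "jac": best_jac}
    return best_x, best_val, info


def _gauss_newton_bse(jac: np.ndarray | None, ssr_val: float, n: int, p: int):
    """Asymptotic standard errors from the Gauss-Newton covariance
    ``s^2 (J^T J)^{-1}``; None when not estimable."""
    if jac is None or n <= p:
        return None
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (ssr_val / (n - p))
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d < 0):
        return None
    return np.sqrt(d)


@dataclass
class KineticsFitResult:
    """Fit outcome for any of the three kinetic models.

    Carries the fitted parameter triple (as its typed dataclass), the SSR at
    the optimum, approximate standard errors from the Gauss-Newton
    linearisation, and the multistart provenance needed to reproduce the fit.
    """

    model_id: str
    params: LogisticParams | HaldaneParams | GompertzParams
    param_names: tuple[str, ...]
    params_array: np.ndarray
    ssr: float
    n_points: int
    converged: bool
    n_restarts_used: int
    seed: int
    bse: np.ndarray | None = None
    weakly_identified: bool = False
    predict_fn: Callable | None = None

    def predict(self, x):
        """Model prediction at time (logistic/Gompertz) or substrate
        concentration (Haldane)."""
        if self.predict_fn is None:
            raise RuntimeError("no prediction function attached")
        return self.predict_fn(x)

    def summary(self) -> str:
        lines = [
            f"{self.model_id.capitalize()} model fit",
            "=" * 46,
            f"{'n points':<22}{self.n_points:>24}",
            f"{'SSR':<22}{self.ssr:>24.6g}",
            f"{'converged':<22}{str(self.converged):>24}",
            f"{'restarts':<22}{self.n_restarts_used:>24}",
            f"{'seed':<22}{self.seed:>24}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>16}{'std err':>16}",
        ]
        for k, name in enumerate(self.param_names):
            se = f"{self.bse[k]:.4g}" if self.bse is not None else "--"
            lines.append(f"{name:<12}{self.params_array[k]:>16.6g}{se:>16}")
        if self.weakly_identified:
            lines.append("warning: inhibition coefficient weakly identified "
                         "(estimate at or near its bound)")
        lines.append("=" * 46)
        return "\n".join(lines)


class KineticsModel:
    """Base class: subclasses define the residual vector and heuristics."""

    model_id: str = ""
    param_names: tuple[str, ...] = ()

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _start(self) -> np.ndarray:
        raise NotImplementedError

    def _bounds(self) -> list[tuple[float, float]]:
        raise NotImplementedError

    def _wrap(self, theta: np.ndarray):
        raise NotImplementedError

    def _n_obs(self) -> int:
        raise NotImplementedError

    def fit(self, n_restarts: int = 20, seed: int = 0) -> KineticsFitResult:
        """Minimise the SSR by bounded multistart least squares."""

        def objective(theta):
            r = self._residuals(theta)
            return float(np.dot(r, r))

        theta, val, info = multistart_minimize(
            objective,
            self._bounds(),
            n_restarts=n_restarts,
            seed=seed,
            x0=self._start(),
            residuals=self._residuals,
        )
        params, predict_fn, weak = self._wrap(theta)
        n = self._n_obs()
        result = KineticsFitResult(
            model_id=self.model_id,
            params=params,
            param_names=self.param_names,
            params_array=theta,
            ssr=val,
            n_points=n,
            converged=info["converged"],
            n_restarts_used=info["n_restarts_used"],
            seed=seed,
            bse=_gauss_newton_bse(info["jac"], val, n, theta.size),
            weakly_identified=weak,
            predict_fn=predict_fn,
        )
        return result


class LogisticGrowthModel(KineticsModel):
    """Logistic batch-growth model fitted to a replicated OD600 series.

    Fits (X0, mu_m, X_m) to the replicate-mean curve by default; pass
    ``pooled=True`` to fit against every replicate's residuals instead.
    The heuristic start takes X0 from the first observation, X_m from the
    maximum, and mu_m from the log-phase slope when a log phase is found.
    """

    model_id = "logistic"
    param_names = ("X0", "mu_m", "X_m")

    def __init__(self, ts: TimeSeries, pooled: bool = False):
        if ts.kind != "biomass":
            raise ValueError("logistic model expects a biomass series")
        self.ts = ts
        self.pooled = pooled
        self._t = ts.times
        self._y = ts.values if pooled else ts.replicate_mean()[:, None]

    def _model(self, theta, t):
        x0, mu_m, x_m = theta
        return x_m / (1.0 + (x_m / x0 - 1.0) * np.exp(-mu_m * t))

    def _residuals(self, theta):
        pred = self._model(theta, self._t)[:, None]
        return (self._y - pred).ravel()

    def _start(self):
        m = self.ts.replicate_mean()
        x0 = max(m[0], 1e-6)
        x_m = max(m.max(), x0 * 1.01)
        try:
            window = detect_log_phase(self.ts)
            mu_m = max(estimate_specific_growth_rate(self.ts, window), 1e-3)
        except (NoLogPhaseError, ValueError):
            mu_m = 0.1
        return np.array([x0, mu_m, x_m])

    def _bounds(self):
        return [BOUNDS["X"], BOUNDS["mu"], BOUNDS["X"]]

    def _n_obs(self):
        return self._y.size

    def _wrap(self, theta):
        params = LogisticParams(X0=float(theta[0]), mu_m=float(theta[1]),
                                X_m=float(theta[2]))
        return params, (lambda t: logistic_density(t, params)), False


class HaldaneModel(KineticsModel):
    """Haldane substrate-inhibition model fitted to (S, mu) rate points.

    Needs at least 3 points; fewer than 4, or points that do not straddle
    the rate peak, leave the inhibition coefficient K_i weakly identified
    (warned, and flagged on the result when the estimate hits its bound).
    """

    model_id = "haldane"
    param_names = ("mu_max", "K_s", "K_i")

    def __init__(self, points: Sequence[RatePoint]):
        points = list(points)
        if len(points) < 3:
            raise ValueError("need at least 3 rate points to fit Haldane")
        order = np.argsort([p.S0 for p in points])
        self._S = np.array([points[i].S0 for i in order])
        self._mu = np.array([points[i].mu for i in order])
        peak = int(np.argmax(self._mu))
        if len(points) < 4 or peak == 0 or peak == len(points) - 1:
            warnings.warn(
                "rate points do not straddle the growth-rate peak with >= 4 "
                "points; the inhibition coefficient K_i is weakly identified",
                stacklevel=2,
            )

    def _residuals(self, theta):
        mu_max, ks, ki = theta
        pred = mu_max * self._S / (ks + self._S + self._S**2 / ki)
        return self._mu - pred

    def _start(self):
        mu_max = 1.2 * self._mu.max()
        peak = int(np.argmax(self._mu))
        s_peak = self._S[peak]
        # half-max crossing on the rising limb, by interpolation
        rising_mu = self._mu[: peak + 1]
        rising_s = self._S[: peak + 1]
        half = self._mu.max() / 2.0
        if rising_mu.size >= 2 and rising_mu[0] < half:
            ks = float(np.interp(half, rising_mu, rising_s))
        else:
            ks = max(rising_s[0] / 2.0, 1e-3)
        ki = s_peak**2 / ks
        return np.array([mu_max, ks, ki])

    def _bounds(self):
        return [BOUNDS["mu"], BOUNDS["Ks"], BOUNDS["Ki"]]

    def _n_obs(self):
        return self._S.size

    def _wrap(self, theta):
        params = HaldaneParams(mu_max=float(theta[0]), K_s=float(theta[1]),
                               K_i=float(theta[2]))
        weak = theta[2] >= 0.99 * BOUNDS["Ki"][1]
        return params, (lambda s: haldane_mu(s, params)), bool(weak)


class GompertzDegradationModel(KineticsModel):
    """Modified-Gompertz degradation model fitted to a residual-substrate
    series, with the initial concentration S0 held fixed (only R_m and the
    lag time are estimated)."""

    model_id = "gompertz"
    param_names = ("R_m", "lam")

    def __init__(self, ts: TimeSeries, s0: float, pooled: bool = False):
        if ts.kind != "substrate":
            raise ValueError("Gompertz model expects a substrate series")
        if s0 <= 0:
            raise ValueError("S0 must be strictly positive")
        self.ts = ts
        self.s0 = float(s0)
        self.pooled = pooled
        self._t = ts.times
        self._y = ts.values if pooled else ts.replicate_mean()[:, None]

    def _model(self, theta, t):
        rm, lam = theta
        a = (rm * math.e / self.s0) * (lam - t) + 1.0
        return self.s0 * (1.0 - np.exp(-np.exp(np.minimum(a, 700.0))))

    def _residuals(self, theta):
        pred = self._model(theta, self._t)[:, None]
        return (self._y - pred).ravel()

    def _start(self):
        m = self.ts.replicate_mean()
        depletion = -np.diff(m) / np.diff(self._t)
        rm = max(float(depletion.max(initial=0.0)), 1e-3)
        above = np.nonzero(m >= 0.95 * self.s0)[0]
        lam = float(self._t[above[-1]]) if above.size else 0.0
        return np.array([rm, lam])

    def _bounds(self):
        return [BOUNDS["Rm"], BOUNDS["lam"]]

    def _n_obs(self):
        return self._y.size

    def _wrap(self, theta):
        params = GompertzParams(S0=self.s0, R_m=float(theta[0]),
                                lam=float(theta[1]))
        return params, (lambda t: gompertz_remaining(t, params)), False


def fit_logistic(ts: TimeSeries, n_restarts: int = 20, seed: int = 0,
                 pooled: bool = False) -> KineticsFitResult:
    """Fit the logistic growth model to a biomass time series."""
    return LogisticGrowthModel(ts, pooled=pooled).fit(n_restarts=n_restarts,
                                                      seed=seed)


def fit_haldane(points: Sequence[RatePoint], n_restarts: int = 20,
                seed: int = 0) -> KineticsFitResult:
    """Fit the Haldane inhibition model to (S, mu) rate points."""
    return HaldaneModel(points).fit(n_restarts=n_restarts, seed=seed)


def fit_gompertz(ts: TimeSeries, s0: float, n_restarts: int = 20,
                 seed: int = 0, pooled: bool = False) -> KineticsFitResult:
    """Fit the modified Gompertz degradation model with S0 held fixed."""
    return GompertzDegradationModel(ts, s0, pooled=pooled).fit(
        n_restarts=n_restarts, seed=seed)
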