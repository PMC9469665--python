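"""Closed-form batch-culture kinetic models and their analytic identities.

Three models describe a batch phenol-degradation experiment:

* **Logistic growth** — biomass ``X(t)`` follows ``dX/dt = mu_m X (1 - X/X_m)``,
  a sigmoid rising from the inoculum density ``X0`` to the carrying capacity
  ``X_m`` with maximum specific growth rate ``mu_m`` (per hour).
* **Haldane (Andrews) substrate inhibition** — the specific growth rate as a
  function of substrate concentration, ``mu(S) = mu_max S / (K_s + S + S^2/K_i)``,
  a unimodal curve that peaks at ``S* = sqrt(K_s K_i)`` and falls off at toxic
  concentrations.
* **Modified Gompertz degradation** — residual substrate
  ``S(t) = S0 (1 - exp(-exp((R_m e / S0)(lam - t) + 1)))``, parameterised by the
  maximum depletion rate ``R_m`` (mg/L/h) and the lag time ``lam`` (h).

All functions here are pure and vectorised over time/substrate; fitting lives
in :mod:`phenolkin.estimation`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LogisticParams",
    "HaldaneParams",
    "GompertzParams",
    "ParameterDomainError",
    "logistic_density",
    "logistic_rate",
    "haldane_mu",
    "haldane_optimum",
    "gompertz_remaining",
    "gompertz_max_rate",
    "gompertz_inflection_time",
    "percent_removal",
]

_EULER = math.e  # full float precision, never 2.718


class ParameterDomainError(ValueError):
    """A kinetic parameter violates its physical domain."""


@dataclass(frozen=True)
class LogisticParams:
    """Logistic batch-growth parameters.

    Attributes
    ----------
    X0 : float
        Initial biomass density (OD600 units), > 0.
    mu_m : float
        Maximum specific growth rate (1/h), > 0.
    X_m : float
        Carrying-capacity biomass density (OD600 units), > X0.
    """

    X0: float
    mu_m: float
    X_m: float

    def __post_init__(self) -> None:
        if not (self.X0 > 0 and self.mu_m > 0 and self.X_m > 0):
            raise ParameterDomainError(
                f"logistic parameters must be strictly positive, got {self}"
            )
        if not self.X0 < self.X_m:
            # only growth branches are physical here: OD starts below capacity
            raise ParameterDomainError(
                f"X0 must be strictly below X_m (growth curve), got {self}"
            )


@dataclass(frozen=True)
class HaldaneParams:
    """Haldane/Andrews substrate-inhibition parameters.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate (1/h), > 0.
    K_s : float
        Half-saturation coefficient (mg/L), > 0.
    K_i : float
        Inhibition coefficient (mg/L), > 0; smaller means stronger inhibition.
    """

    mu_max: float
    K_s: float
    K_i: float

    def __post_init__(self) -> None:
        if not (self.mu_max > 0 and self.K_s > 0 and self.K_i > 0):
            raise ParameterDomainError(
                f"Haldane parameters must be strictly positive, got {self}"
            )


@dataclass(frozen=True)
class GompertzParams:
    """Modified-Gompertz degradation parameters.

    Attributes
    ----------
    S0 : float
        Initial substrate concentration (mg/L), > 0.
    R_m : float
        Maximum degradation rate (mg/L per hour), > 0.
    lam : float
        Lag time (h); finite. Negative values are accepted with a warning —
        fits on noisy data can produce them — but are physically dubious.
    """

    S0: float
    R_m: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.S0 > 0 and self.R_m > 0):
            raise ParameterDomainError(
                f"S0 and R_m must be strictly positive, got {self}"
            )
        if not math.isfinite(self.lam):
            raise ParameterDomainError(f"lag time must be finite, got {self.lam}")
        if self.lam < 0:
            warnings.warn(
                f"negative lag time lam={self.lam}: accepted, but physically dubious",
                stacklevel=3,
            )


def logistic_density(t, p: LogisticParams):
    """Biomass density X(t) of the integrated logistic model.

    Evaluates ``X(t) = X0 e^{mu_m t} / (1 - (X0/X_m)(1 - e^{mu_m t}))`` in the
    overflow-safe equivalent form ``X_m / (1 + (X_m/X0 - 1) e^{-mu_m t})``.

    Parameters
    ----------
    t : array_like
        Time in hours, >= 0.
    p : LogisticParams

    Returns
    -------
    ndarray or float
        Biomass density in (0, X_m], monotone nondecreasing in t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = p.X_m / (1.0 + (p.X_m / p.X0 - 1.0) * np.exp(-p.mu_m * t))
    return out if out.ndim else float(out)


def logistic_rate(X, p: LogisticParams):
    """Instantaneous growth rate dX/dt = mu_m X (1 - X/X_m).

    Zero exactly at carrying capacity. ``X`` must be positive and no greater
    than ``X_m``.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("biomass density must be strictly positive")
    if np.any(X > p.X_m * (1 + 1e-12)):
        raise ValueError("biomass density exceeds carrying capacity")
    out = p.mu_m * X * (1.0 - X / p.X_m)
    return out if out.ndim else float(out)


def haldane_mu(S, p: HaldaneParams):
    """Specific growth rate mu(S) = mu_max S / (K_s + S + S^2/K_i).

    Nonnegative, zero at S = 0, and -> 0 as S -> infinity.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be nonnegative")
    out = p.mu_max * S / (p.K_s + S + S * S / p.K_i)
    return out if out.ndim else float(out)


def haldane_optimum(p: HaldaneParams) -> tuple[float, float]:
    """Analytic peak of the Haldane curve.

    Returns ``(S_star, mu_star)`` with ``S_star = sqrt(K_s K_i)`` and
    ``mu_star = mu_max / (1 + 2 sqrt(K_s/K_i))``; always ``mu_star < mu_max``.
    """
    s_star = math.sqrt(p.K_s * p.K_i)
    mu_star = p.mu_max / (1.0 + 2.0 * math.sqrt(p.K_s / p.K_i))
    return s_star, mu_star


def gompertz_remaining(t, p: GompertzParams):
    """Residual substrate S(t) under the modified Gompertz model.

    ``S(t) = S0 (1 - exp(-exp(a)))`` with ``a = (R_m e / S0)(lam - t) + 1``.
    Monotone nonincreasing in t, bounded in [0, S0); S(0) ~= S0 whenever the
    lag is appreciable, and S -> 0 as t -> infinity.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    a = (p.R_m * _EULER / p.S0) * (p.lam - t) + 1.0
    # exp(a) overflows harmlessly to inf for a >~ 709; clip to keep it silent
    out = p.S0 * (1.0 - np.exp(-np.exp(np.minimum(a, 700.0))))
    return out if out.ndim else float(out)


def gompertz_inflection_time(p: GompertzParams) -> float:
    """Time of maximum depletion rate: t = lam + S0 / (R_m e).

    At this time the exponent argument is zero and ``S = S0 (1 - 1/e)``.
    """
    return p.lam + p.S0 / (p.R_m * _EULER)


def gompertz_max_rate(p: GompertzParams, t_max: float | None = None,
                      step: float = 1e-3) -> float:
    """Maximum substrate depletion rate -dS/dt, found numerically.

    Maximises the finite-difference depletion rate over a dense time grid;
    analytically the answer is exactly ``R_m``, attained at the inflection
    time, so this serves as a numerical cross-check of the parameterisation.
    """
    t_infl = gompertz_inflection_time(p)
    if t_max is None:
        t_max = max(2.0 * t_infl, t_infl + 10.0, 10.0)
    t = np.arange(0.0, t_max, step)
    s = gompertz_remaining(t, p)
    rates = -np.diff(s) / step
    return float(rates.max())


def percent_removal(S0: float, S_t: float) -> float:
    """Percent of substrate removed: 100 (S0 - S_t) / S0.

    ``S_t`` slightly above ``S0`` (measurement noise) clamps to 0 % with a
    warning; ``S0 <= 0`` is a domain error.
    """
    if S0 <= 0:
        raise ValueError("initial concentration must be strictly positive")
    if S_t < 0:
        raise ValueError("residual concentration must be nonnegative")
    if S_t > S0:
        warnings.warn(
            f"residual {S_t} exceeds initial {S0}; clamping removal to 0%",
            stacklevel=2,
        )
        return 0.0
    return 100.0 * (S0 - S_t) / S0
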