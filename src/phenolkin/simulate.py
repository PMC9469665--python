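"""Forward simulator of replicated batch phenol-degradation experiments.

Generates growth curves (logistic), degradation curves (modified Gompertz)
and specific-growth-rate profiles (Haldane) from a known ground truth, with
multiplicative Gaussian measurement noise, so that every estimation stage can
be exercised against data whose generating parameters are known exactly.

The default design mirrors a six-concentration batch study: initial phenol at
200-1200 mg/L, OD600 sampled every 12 h to 96 h, residual phenol every 6 h to
108 h (covering full degradation of the mid-range cultures at ~103 h),
triplicate cultures, and ~3 % relative measurement noise — the coefficient of
variation implied by replicate standard deviations of the order "63 +/- 1.89"
in percent-removal tables from such studies.

Randomness is split per curve by stable sub-seeding from (seed, kind,
concentration), so adding or removing a concentration never perturbs the
noise drawn for the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

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
    "ExperimentDesign",
    "GroundTruth",
    "SyntheticDataset",
    "default_design",
    "default_truth",
    "simulate_growth",
    "simulate_degradation",
    "simulate_rate_points",
    "simulate_dataset",
]

DEFAULT_CONCENTRATIONS = (200.0, 400.0, 700.0, 800.0, 1000.0, 1200.0)
DEFAULT_GROWTH_TIMES = tuple(float(t) for t in range(0, 97, 12))
DEFAULT_DEGRADATION_TIMES = tuple(float(t) for t in range(0, 109, 6))
DEFAULT_NOISE_CV = 0.03
DEFAULT_X0 = 0.05  # inoculum OD600 for truth curves; configurable

_KIND_CODE = {"growth": 1, "degradation": 2, "rate": 3}


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of a simulated batch experiment."""

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    sample_times: tuple[float, ...] = DEFAULT_GROWTH_TIMES
    n_replicates: int = 3
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(c <= 0) or np.unique(c).size != c.size:
            raise ValueError("concentrations must be positive and distinct")
        t = np.asarray(self.sample_times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must start at 0 and strictly increase")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0 <= self.noise_cv < 0.5:
            raise ValueError("noise_cv must lie in [0, 0.5)")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters: one logistic and one Gompertz triple per
    concentration, plus a single global Haldane triple."""

    logistic: dict[float, LogisticParams]
    gompertz: dict[float, GompertzParams]
    haldane: HaldaneParams

    def validate_against(self, design: ExperimentDesign) -> None:
        missing = [c for c in design.concentrations
                   if c not in self.logistic or c not in self.gompertz]
        if missing:
            raise ValueError(f"truth lacks entries for concentrations {missing}")


@dataclass
class SyntheticDataset:
    """Simulated curves plus the truth and seed that produced them."""

    growth: dict[float, TimeSeries]
    degradation: dict[float, TimeSeries]
    rate_points: list[RatePoint]
    truth: GroundTruth
    seed: int
    design: ExperimentDesign = field(repr=False, default=None)


# Fixture truth: per-concentration logistic (mu_m, X_m) and Gompertz
# (R_m, lam) triples typical of a Curtobacterium phenol study, with the
# global Haldane triple (mu_max, Ks, Ki) = (2.28 1/h, 4.3 mg/L, 291 mg/L).
_LOGISTIC_ROWS = {
    200.0: (0.300, 0.293),
    400.0: (0.195, 0.270),
    700.0: (0.065, 0.400),
    800.0: (0.105, 0.322),
    1000.0: (0.202, 0.116),
    1200.0: (0.050, 0.101),
}
_GOMPERTZ_ROWS = {
    200.0: (5.4, 12.1),
    400.0: (6.7, 14.5),
    700.0: (9.0, 10.2),
    800.0: (9.4, 18.3),
    1000.0: (9.2, 6.3),
    1200.0: (10.3, 13.1),
}
_HALDANE_TRUTH = (2.28, 4.3, 291.0)


def default_truth(x0: float = DEFAULT_X0) -> GroundTruth:
    """The canonical fixture truth used throughout the test-bench."""
    logistic = {
        c: LogisticParams(X0=x0, mu_m=mu, X_m=xm)
        for c, (mu, xm) in _LOGISTIC_ROWS.items()
    }
    gompertz = {
        c: GompertzParams(S0=c, R_m=rm, lam=lam)
        for c, (rm, lam) in _GOMPERTZ_ROWS.items()
    }
    return GroundTruth(logistic=logistic, gompertz=gompertz,
                       haldane=HaldaneParams(*_HALDANE_TRUTH))


def default_design(kind: str = "growth", seed: int = 0,
                   noise_cv: float = DEFAULT_NOISE_CV) -> ExperimentDesign:
    """Default sampling design for growth (0-96 h / 12 h) or degradation
    (0-108 h / 6 h) runs."""
    times = DEFAULT_GROWTH_TIMES if kind == "growth" else DEFAULT_DEGRADATION_TIMES
    return ExperimentDesign(sample_times=times, seed=seed, noise_cv=noise_cv)


def _curve_rng(seed: int, kind: str, concentration: float) -> np.random.Generator:
    """Stable per-curve stream: keyed on (seed, kind, concentration)."""
    return np.random.default_rng(
        [int(seed), _KIND_CODE[kind], int(round(concentration * 1000))]
    )


def simulate_growth(design: ExperimentDesign,
                    truth: GroundTruth) -> dict[float, TimeSeries]:
    """Simulate replicated OD600 growth curves for every concentration.

    Noise is independent Gaussian with SD = noise_cv x model value,
    truncated below at 1e-4 OD so biomass stays strictly positive.
    """
    truth.validate_against(design)
    t = np.asarray(design.sample_times)
    out = {}
    for c in design.concentrations:
        model = logistic_density(t, truth.logistic[c])
        rng = _curve_rng(design.seed, "growth", c)
        noise = rng.normal(0.0, 1.0, size=(t.size, design.n_replicates))
        values = model[:, None] * (1.0 + design.noise_cv * noise)
        values = np.maximum(values, 1e-4)
        out[c] = TimeSeries(times=t, values=values, kind="biomass",
                            condition_label=f"{c:g}", concentration=c)
    return out


def simulate_degradation(design: ExperimentDesign,
                         truth: GroundTruth) -> dict[float, TimeSeries]:
    """Simulate replicated residual-phenol curves; noise truncated at 0."""
    truth.validate_against(design)
    t = np.asarray(design.sample_times)
    out = {}
    for c in design.concentrations:
        model = gompertz_remaining(t, truth.gompertz[c])
        rng = _curve_rng(design.seed, "degradation", c)
        noise = rng.normal(0.0, 1.0, size=(t.size, design.n_replicates))
        values = model[:, None] * (1.0 + design.noise_cv * noise)
        values = np.maximum(values, 0.0)
        out[c] = TimeSeries(times=t, values=values, kind="substrate",
                            condition_label=f"{c:g}", concentration=c)
    return out


def simulate_rate_points(s_grid, truth: GroundTruth,
                         noise_cv: float = DEFAULT_NOISE_CV,
                         seed: int = 0) -> list[RatePoint]:
    """Simulate (S, mu) pairs from the Haldane truth, mu floored at 0."""
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid <= 0):
        raise ValueError("substrate grid must be strictly positive")
    points = []
    for s in s_grid:
        mu = haldane_mu(float(s), truth.haldane)
        rng = _curve_rng(seed, "rate", float(s))
        mu_obs = max(mu * (1.0 + noise_cv * rng.normal()), 0.0)
        points.append(RatePoint(S0=float(s), mu=mu_obs))
    return points


def simulate_dataset(seed: int = 0, noise_cv: float = DEFAULT_NOISE_CV,
                     n_replicates: int = 3,
                     truth: GroundTruth | None = None,
                     rate_grid=(50, 100, 200, 400, 700, 1000, 1200),
                     ) -> SyntheticDataset:
    """One full synthetic experiment: growth + degradation + rate profile."""
    truth = truth if truth is not None else default_truth()
    growth_design = ExperimentDesign(sample_times=DEFAULT_GROWTH_TIMES,
                                     n_replicates=n_replicates,
                                     noise_cv=noise_cv, seed=seed)
    degr_design = ExperimentDesign(sample_times=DEFAULT_DEGRADATION_TIMES,
                                   n_replicates=n_replicates,
                                   noise_cv=noise_cv, seed=seed)
    return SyntheticDataset(
        growth=simulate_growth(growth_design, truth),
        degradation=simulate_degradation(degr_design, truth),
        rate_points=simulate_rate_points(rate_grid, truth,
                                         noise_cv=noise_cv, seed=seed),
        truth=truth,
        seed=seed,
        design=growth_design,
    )
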