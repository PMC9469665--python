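"""Replicated time-series containers for batch-culture measurements."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "RatePoint"]

_KINDS = ("biomass", "substrate")


@dataclass
class TimeSeries:
    """Replicated measurements of one batch condition over time.

    Attributes
    ----------
    times : ndarray, shape (n_times,)
        Sampling times in hours, strictly increasing; at least 4 points.
    values : ndarray, shape (n_times, n_replicates)
        OD600 (kind="biomass", strictly positive) or residual substrate in
        mg/L (kind="substrate", nonnegative).
    kind : str
        "biomass" or "substrate".
    condition_label : str
        Free-text condition identifier, typically the initial phenol level.
    concentration : float or None
        Initial phenol concentration in mg/L for this condition, if known.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    condition_label: str = ""
    concentration: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.times.ndim != 1 or self.times.size < 4:
            raise ValueError("need at least 4 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape[0] != self.times.size:
            raise ValueError(
                f"values rows ({self.values.shape[0]}) must match "
                f"times ({self.times.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all measurements must be finite")
        if self.kind == "biomass" and np.any(self.values <= 0):
            raise ValueError("biomass values must be strictly positive")
        if self.kind == "substrate" and np.any(self.values < 0):
            raise ValueError("substrate values must be nonnegative")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def replicate_mean(self) -> np.ndarray:
        """Per-timepoint mean over replicates."""
        return self.values.mean(axis=1)

    def replicate_sd(self) -> np.ndarray:
        """Per-timepoint sample standard deviation over replicates (ddof=1)."""
        if self.n_replicates < 2:
            return np.zeros(self.times.size)
        return self.values.std(axis=1, ddof=1)


@dataclass(frozen=True)
class RatePoint:
    """One (initial substrate concentration, specific growth rate) pair."""

    S0: float
    mu: float

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValueError("S0 must be strictly positive")
        if self.mu < 0:
            raise ValueError("specific growth rate must be nonnegative")
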