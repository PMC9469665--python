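"""Tidy-CSV readers and writers for batch-culture time series.

Schemas (headers exact, UTF-8, comma-separated, ``.`` decimal):

* growth:       ``condition,phenol_mg_per_l,time_h,replicate,od600``
* degradation:  ``condition,phenol_mg_per_l_initial,time_h,replicate,phenol_mg_per_l``
* rate:         ``phenol_mg_per_l,mu_per_h``

Each (condition, time_h, replicate) key must be unique; parse errors report
the offending CSV line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import RatePoint, TimeSeries

__all__ = [
    "CSVSchemaError",
    "GROWTH_COLUMNS",
    "DEGRADATION_COLUMNS",
    "RATE_COLUMNS",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_rate_csv",
    "write_rate_csv",
]

GROWTH_COLUMNS = ["condition", "phenol_mg_per_l", "time_h", "replicate", "od600"]
DEGRADATION_COLUMNS = ["condition", "phenol_mg_per_l_initial", "time_h",
                       "replicate", "phenol_mg_per_l"]
RATE_COLUMNS = ["phenol_mg_per_l", "mu_per_h"]

_FLOAT_FMT = "%.10g"


class CSVSchemaError(ValueError):
    """The file does not match the declared tidy schema."""


def _schema(kind: str) -> tuple[list[str], str, str]:
    if kind == "biomass":
        return GROWTH_COLUMNS, "phenol_mg_per_l", "od600"
    if kind == "substrate":
        return DEGRADATION_COLUMNS, "phenol_mg_per_l_initial", "phenol_mg_per_l"
    raise ValueError(f"kind must be 'biomass' or 'substrate', got {kind!r}")


def _check_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise CSVSchemaError(
                f"{path}: non-numeric or missing value in column "
                f"{col!r} at line {line}"
            )
        out[col] = coerced
    return out


def read_timeseries_csv(path, kind: str) -> dict[str, TimeSeries]:
    """Read a tidy growth or degradation CSV into one TimeSeries per
    condition, replicates aligned on the shared time grid.

    Parameters
    ----------
    path : path-like
    kind : str
        "biomass" (growth schema) or "substrate" (degradation schema).
    """
    columns, conc_col, value_col = _schema(kind)
    path = Path(path)
    df = pd.read_csv(path, dtype={"condition": str})
    if list(df.columns) != columns:
        raise CSVSchemaError(
            f"{path}: expected header {','.join(columns)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        raise CSVSchemaError(f"{path}: no data rows")
    df = _check_numeric(df, [conc_col, "time_h", "replicate", value_col], path)

    dup = df.duplicated(subset=["condition", "time_h", "replicate"], keep="first")
    if dup.any():
        line = int(dup.idxmax()) + 2
        row = df.loc[dup.idxmax()]
        raise CSVSchemaError(
            f"{path}: duplicate (condition, time_h, replicate) key "
            f"({row['condition']}, {row['time_h']:g}, {row['replicate']:g}) "
            f"at line {line}"
        )

    out: dict[str, TimeSeries] = {}
    for label, grp in df.groupby("condition", sort=True):
        wide = grp.pivot(index="time_h", columns="replicate", values=value_col)
        if wide.isna().any().any():
            raise CSVSchemaError(
                f"{path}: condition {label!r} has replicates not aligned on a "
                "common time grid"
            )
        wide = wide.sort_index()
        conc = grp[conc_col].unique()
        if conc.size != 1:
            raise CSVSchemaError(
                f"{path}: condition {label!r} has conflicting initial "
                f"concentrations {sorted(conc)}"
            )
        out[str(label)] = TimeSeries(
            times=wide.index.to_numpy(dtype=float),
            values=wide.to_numpy(dtype=float),
            kind=kind,
            condition_label=str(label),
            concentration=float(conc[0]),
        )
    return out


def write_timeseries_csv(path, curves: dict[str, TimeSeries], kind: str) -> None:
    """Write TimeSeries back to the tidy schema (inverse of the reader)."""
    columns, conc_col, value_col = _schema(kind)
    rows = []
    for label in sorted(curves, key=lambda k: (curves[k].concentration or 0, k)):
        ts = curves[label]
        if ts.kind != kind:
            raise ValueError(f"series {label!r} has kind {ts.kind!r}, expected {kind!r}")
        conc = ts.concentration if ts.concentration is not None else np.nan
        for i, t in enumerate(ts.times):
            for r in range(ts.n_replicates):
                rows.append({
                    "condition": ts.condition_label or label,
                    conc_col: conc,
                    "time_h": t,
                    "replicate": r + 1,
                    value_col: ts.values[i, r],
                })
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False,
                                               float_format=_FLOAT_FMT)


def read_rate_csv(path) -> list[RatePoint]:
    """Read (S, mu) rate pairs from the two-column rate schema."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != RATE_COLUMNS:
        raise CSVSchemaError(
            f"{path}: expected header {','.join(RATE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    df = _check_numeric(df, RATE_COLUMNS, path)
    return [RatePoint(S0=float(s), mu=float(mu))
            for s, mu in zip(df["phenol_mg_per_l"], df["mu_per_h"])]


def write_rate_csv(path, points) -> None:
    pd.DataFrame(
        [{"phenol_mg_per_l": p.S0, "mu_per_h": p.mu} for p in points],
        columns=RATE_COLUMNS,
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
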