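"""End-to-end analysis pipeline and report tables.

Reads tidy growth/degradation (and optionally rate) CSVs, runs the full
inference chain — logistic fits per concentration, log-phase rate extraction,
the Haldane fit, Gompertz fits, and the fixed-time percent-removal summary —
and emits four report tables (CSV) plus a human-readable summary and a run
manifest.  A failure in one condition is recorded and the rest proceed.

When a rate CSV is supplied the Haldane stage consumes it directly; otherwise
the (S, mu) pairs extracted from the growth curves feed the fit.  The two
sources answer different questions: the rate CSV carries independently
measured specific growth rates, while extraction ties the Haldane fit to the
same OD curves the logistic fits used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import RatePoint, TimeSeries
from .estimation import (
    KineticsFitResult,
    detect_log_phase,
    estimate_specific_growth_rate,
    fit_gompertz,
    fit_haldane,
    fit_logistic,
)
from .io import read_rate_csv, read_timeseries_csv
from .models import percent_removal

__all__ = ["PipelineConfig", "KineticsReport", "removal_summary",
           "run_full_pipeline"]

logger = logging.getLogger("phenolkin")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

_FLOAT_FMT = "%.10g"

REPORT_FILES = {
    "logistic": "logistic_fits.csv",
    "haldane": "haldane_fit.csv",
    "gompertz": "gompertz_fits.csv",
    "removal": "removal_summary.csv",
}


@dataclass
class PipelineConfig:
    """Inputs and settings for one pipeline run."""

    growth_csv: str | Path | None = None
    degradation_csv: str | Path | None = None
    rate_csv: str | Path | None = None
    output_dir: str | Path = "phenolkin_report"
    n_restarts: int = 20
    seed: int = 0
    removal_time_h: float = 48.0
    log_phase_lower_frac: float = 0.05
    log_phase_upper_frac: float = 0.70
    log_phase_min_points: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("growth_csv", "degradation_csv", "rate_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.growth_csv is None and self.degradation_csv is None:
            raise ValueError("at least one of growth_csv/degradation_csv is required")


@dataclass
class KineticsReport:
    """The four report tables plus per-condition errors and fit objects."""

    logistic_table: pd.DataFrame
    haldane_table: pd.DataFrame
    gompertz_table: pd.DataFrame
    removal_table: pd.DataFrame
    rate_points: list[RatePoint] = field(default_factory=list)
    fits: dict = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def write(self, outdir, manifest: dict | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            REPORT_FILES["logistic"]: self.logistic_table,
            REPORT_FILES["haldane"]: self.haldane_table,
            REPORT_FILES["gompertz"]: self.gompertz_table,
            REPORT_FILES["removal"]: self.removal_table,
        }
        for name, table in tables.items():
            table.to_csv(outdir / name, index=False, float_format=_FLOAT_FMT)
        (outdir / "summary.txt").write_text(self.render_summary())
        if manifest is not None:
            (outdir / "run_manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    def render_summary(self) -> str:
        parts = ["Phenol biodegradation kinetics report", "=" * 42]
        for title, table in [
            ("Logistic growth fits", self.logistic_table),
            ("Haldane substrate-inhibition fit", self.haldane_table),
            ("Modified Gompertz degradation fits", self.gompertz_table),
            ("Percent removal", self.removal_table),
        ]:
            parts.append("")
            parts.append(title)
            parts.append("-" * len(title))
            parts.append(table.to_string(index=False) if len(table) else "(empty)")
        if self.errors:
            parts.append("")
            parts.append("Errors")
            parts.append("------")
            for label, msg in sorted(self.errors.items()):
                parts.append(f"{label}: {msg}")
        return "\n".join(parts) + "\n"


def removal_summary(curves: dict[str, TimeSeries], at_time: float) -> pd.DataFrame:
    """Per-condition mean and SD of percent removal at a fixed time.

    Residual substrate at ``at_time`` is taken from each replicate by linear
    interpolation between adjacent sampled times; ``at_time`` must lie inside
    every series' observed range.
    """
    rows = []
    for label in sorted(curves, key=lambda k: (curves[k].concentration or 0, k)):
        ts = curves[label]
        if ts.kind != "substrate":
            raise ValueError(f"removal summary needs substrate series, got {ts.kind!r}")
        if not ts.times[0] <= at_time <= ts.times[-1]:
            raise ValueError(
                f"removal time {at_time} h outside observed range "
                f"[{ts.times[0]}, {ts.times[-1]}] for condition {label!r}"
            )
        s0 = ts.concentration
        if s0 is None:
            raise ValueError(f"condition {label!r} lacks an initial concentration")
        removals = [
            percent_removal(s0, float(np.interp(at_time, ts.times, ts.values[:, r])))
            for r in range(ts.n_replicates)
        ]
        removals = np.asarray(removals)
        rows.append({
            "condition": label,
            "phenol_mg_per_l": s0,
            "time_h": at_time,
            "removal_pct_mean": removals.mean(),
            "removal_pct_sd": removals.std(ddof=1) if len(removals) > 1 else 0.0,
            "n_replicates": ts.n_replicates,
        })
    return pd.DataFrame(rows, columns=["condition", "phenol_mg_per_l", "time_h",
                                       "removal_pct_mean", "removal_pct_sd",
                                       "n_replicates"])


def _sorted_items(curves: dict[str, TimeSeries]):
    return sorted(curves.items(), key=lambda kv: (kv[1].concentration or 0, kv[0]))


def run_full_pipeline(config: PipelineConfig) -> KineticsReport:
    """Run the complete inference chain and write the report.

    Deterministic end to end for a fixed config (including seed); every
    stage logs its parameters and SSR to standard error.
    """
    config.validate()
    t_start = time.perf_counter()
    errors: dict[str, str] = {}
    fits: dict = {}

    logistic_rows, gompertz_rows, haldane_rows = [], [], []
    extracted_points: list[RatePoint] = []
    removal_table = pd.DataFrame(columns=["condition", "phenol_mg_per_l", "time_h",
                                          "removal_pct_mean", "removal_pct_sd",
                                          "n_replicates"])

    # --- growth: logistic fits + log-phase rate extraction -----------------
    if config.growth_csv is not None:
        growth = read_timeseries_csv(config.growth_csv, kind="biomass")
        for label, ts in _sorted_items(growth):
            try:
                res = fit_logistic(ts, n_restarts=config.n_restarts,
                                   seed=config.seed)
                fits[("logistic", label)] = res
                logistic_rows.append({
                    "condition": label,
                    "phenol_mg_per_l": ts.concentration,
                    "X0": res.params.X0,
                    "mu_m_per_h": res.params.mu_m,
                    "X_m": res.params.X_m,
                    "ssr": res.ssr,
                })
                logger.info("logistic[%s]: mu_m=%.4g X_m=%.4g ssr=%.3g",
                            label, res.params.mu_m, res.params.X_m, res.ssr)
            except Exception as exc:  # isolate per-condition failures
                errors[f"logistic:{label}"] = str(exc)
                logger.warning("logistic fit failed for %s: %s", label, exc)
            try:
                window = detect_log_phase(
                    ts,
                    lower_frac=config.log_phase_lower_frac,
                    upper_frac=config.log_phase_upper_frac,
                    min_points=config.log_phase_min_points,
                )
                mu = estimate_specific_growth_rate(ts, window)
                if ts.concentration is not None and mu >= 0:
                    extracted_points.append(RatePoint(S0=ts.concentration, mu=mu))
                    logger.info("rate[%s]: mu=%.4g (window %d..%d, R2=%.4f)",
                                label, mu, window.start_index,
                                window.end_index, window.r_squared)
            except Exception as exc:
                errors[f"rate:{label}"] = str(exc)
                logger.warning("rate extraction failed for %s: %s", label, exc)

    # --- Haldane fit -------------------------------------------------------
    if config.rate_csv is not None:
        rate_points = read_rate_csv(config.rate_csv)
        rate_source = "rate_csv"
    else:
        rate_points = extracted_points
        rate_source = "log_phase_extraction"
    if len(rate_points) >= 4:
        try:
            res = fit_haldane(rate_points, n_restarts=config.n_restarts,
                              seed=config.seed)
            fits[("haldane", "global")] = res
            s_vals = [p.S0 for p in rate_points]
            haldane_rows.append({
                "mu_max_per_h": res.params.mu_max,
                "K_s_mg_per_l": res.params.K_s,
                "K_i_mg_per_l": res.params.K_i,
                "ssr": res.ssr,
                "s_min_mg_per_l": min(s_vals),
                "s_max_mg_per_l": max(s_vals),
                "n_points": len(rate_points),
                "rate_source": rate_source,
            })
            logger.info("haldane: mu_max=%.4g Ks=%.4g Ki=%.4g ssr=%.3g (%s)",
                        res.params.mu_max, res.params.K_s, res.params.K_i,
                        res.ssr, rate_source)
        except Exception as exc:
            errors["haldane"] = str(exc)
            logger.warning("Haldane fit failed: %s", exc)
    else:
        msg = (f"only {len(rate_points)} rate points available (< 4); "
               "Haldane stage skipped")
        errors["haldane"] = msg
        logger.warning(msg)

    # --- degradation: Gompertz fits + removal summary ----------------------
    if config.degradation_csv is not None:
        degradation = read_timeseries_csv(config.degradation_csv, kind="substrate")
        for label, ts in _sorted_items(degradation):
            try:
                res = fit_gompertz(ts, s0=ts.concentration,
                                   n_restarts=config.n_restarts,
                                   seed=config.seed)
                fits[("gompertz", label)] = res
                gompertz_rows.append({
                    "condition": label,
                    "phenol_mg_per_l": ts.concentration,
                    "R_m_mg_per_l_h": res.params.R_m,
                    "lambda_h": res.params.lam,
                    "ssr": res.ssr,
                })
                logger.info("gompertz[%s]: Rm=%.4g lam=%.4g ssr=%.3g",
                            label, res.params.R_m, res.params.lam, res.ssr)
            except Exception as exc:
                errors[f"gompertz:{label}"] = str(exc)
                logger.warning("Gompertz fit failed for %s: %s", label, exc)
        try:
            removal_table = removal_summary(degradation, config.removal_time_h)
        except Exception as exc:
            errors["removal"] = str(exc)
            logger.warning("removal summary failed: %s", exc)

    report = KineticsReport(
        logistic_table=pd.DataFrame(
            logistic_rows, columns=["condition", "phenol_mg_per_l", "X0",
                                    "mu_m_per_h", "X_m", "ssr"]),
        haldane_table=pd.DataFrame(
            haldane_rows, columns=["mu_max_per_h", "K_s_mg_per_l",
                                   "K_i_mg_per_l", "ssr", "s_min_mg_per_l",
                                   "s_max_mg_per_l", "n_points", "rate_source"]),
        gompertz_table=pd.DataFrame(
            gompertz_rows, columns=["condition", "phenol_mg_per_l",
                                    "R_m_mg_per_l_h", "lambda_h", "ssr"]),
        removal_table=removal_table,
        rate_points=rate_points,
        fits=fits,
        errors=errors,
    )

    manifest = {
        "phenolkin_version": __version__,
        "seed": config.seed,
        "n_restarts": config.n_restarts,
        "removal_time_h": config.removal_time_h,
        "inputs": {k: str(getattr(config, k)) for k in
                   ("growth_csv", "degradation_csv", "rate_csv")
                   if getattr(config, k) is not None},
        "rate_source": rate_source,
        "errors": errors,
    }
    report.write(config.output_dir, manifest=manifest)
    logger.info("pipeline finished in %.2f s; report in %s",
                time.perf_counter() - t_start, config.output_dir)
    return report
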