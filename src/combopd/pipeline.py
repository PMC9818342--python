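"""End-to-end analysis pipeline: simulate/load → fit → fix → psi → surface → report.

The stage order reproduces the sequential estimation workflow used for the
cisplatin + cimetidine study:

1. obtain static (72 h endpoint) and time-course viability tables, either by
   simulation from the built-in reference parameters or from user CSVs;
2. fit each drug's static Hill curve on the single-agent arms;
3. fix those estimates and fit the static interaction parameter psi on the
   combination grid;
4. build the additive (psi = 1) response surface and classify combination
   wells above / at-or-below it;
5. fit the control growth constant kg, then each drug's kill model
   (Smax, SC50, tau) with kg fixed;
6. fix all single-agent kill parameters and fit the time-course psi;
7. interpret both psi estimates (synergistic / additive / antagonistic
   within a stated equivalence band) and write a report.

Every stage writes its outputs under the run directory so downstream stages
can be rerun in isolation; the whole run is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import (
    FitResult,
    default_hill_spec,
    default_pd_spec,
    fit_growth,
    fit_hill,
    fit_interaction_static,
    fit_pd_combo,
    fit_pd_single,
)
from .io import read_viability_table, validate_viability_table
from .models import HillParams, PDAgentParams
from .reference import interaction_params, pd_system
from .surface import build_additive_surface, classify_points, plot_surface
from .synthesize import NoiseModel, default_design, generate_static, generate_timecourse, write_dataset

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "interpret_psi"]

log = logging.getLogger("combopd")

SYNERGISTIC = "synergistic"
ADDITIVE = "additive"
ANTAGONISTIC = "antagonistic"


def interpret_psi(psi: float, band: float = 0.1) -> str:
    """Label an interaction estimate relative to the additive null psi = 1.

    ``additive`` within ``|psi - 1| <= band``; ``synergistic`` below the
    band, ``antagonistic`` above it.  The band acknowledges that a psi of,
    say, 0.95 is better read as "additive to modestly synergistic" than as a
    firm synergy call.
    """
    if psi <= 0:
        raise ValueError(f"psi must be > 0, got {psi}")
    if abs(psi - 1.0) <= band:
        return ADDITIVE
    return SYNERGISTIC if psi < 1.0 else ANTAGONISTIC


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    outdir: str = "combopd_run"
    cell_line: str = "Huh7"
    seed: int = 0
    cv_proportional: float = 0.0
    sd_additive: float = 0.0
    band: float = 0.1
    psi_on: str = "both"
    static_csv: str | None = None
    timecourse_csv: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        log verbosity do not change any computed number)."""
        payload = asdict(self)
        payload.pop("outdir")
        payload.pop("log_level")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Everything the pipeline concluded, serializable to JSON."""

    cell_line: str
    hill_cis: dict
    hill_cim: dict
    psi_static: float
    psi_static_label: str
    growth: dict
    pd_cis: dict
    pd_cim: dict
    psi_timecourse: float
    psi_timecourse_label: str
    band: float
    surface_summary: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = [
            f"combopd analysis report — {self.cell_line}",
            "=" * 48,
            "",
            "Static concentration-response (72 h endpoint)",
            f"  CIS Hill fit : {_fmt_est(self.hill_cis)}",
            f"  CIM Hill fit : {_fmt_est(self.hill_cim)}",
            f"  interaction psi (static)      : {self.psi_static:.4g}"
            f"  -> {self.psi_static_label} (band ±{self.band})",
            "",
            "Surface classification vs additive (psi = 1) surface",
            f"  points above surface          : {self.surface_summary['n_above']}"
            f" / {self.surface_summary['n_points']}"
            f" (frac {self.surface_summary['frac_above']:.2f})",
            "",
            "Time-course kill model (0-96 h)",
            f"  growth kg    : {_fmt_est(self.growth)}",
            f"  CIS kill fit : {_fmt_est(self.pd_cis)}",
            f"  CIM kill fit : {_fmt_est(self.pd_cim)}",
            f"  interaction psi (time-course) : {self.psi_timecourse:.4g}"
            f"  -> {self.psi_timecourse_label} (band ±{self.band})",
            "",
            f"provenance: {self.provenance}",
        ]
        return "\n".join(lines)


def _fmt_est(fit_dict: dict) -> str:
    parts = []
    for name, val in fit_dict["estimates"].items():
        rse = fit_dict["rse_pct"].get(name, float("nan"))
        parts.append(f"{name}={val:.4g} ({rse:.2g}% RSE)")
    return ", ".join(parts)


def _hill_params_from_fit(fit: FitResult, fixed: dict[str, float]) -> HillParams:
    merged = dict(fixed)
    merged.update(fit.estimates)
    # imax can graze its upper bound within optimizer roundoff
    merged["imax"] = min(merged["imax"], 1.0)
    return HillParams(
        r0=merged["r0"], imax=merged["imax"], ic50=merged["ic50"], gamma=merged["gamma"]
    )


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


class _Stage:
    """Per-stage timing logger (context manager)."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: FAILED after %.2fs (%s)", self.name, dt, exc)
        return False


def fit_static_stage(
    static: pd.DataFrame, psi_on: str = "both"
) -> tuple[FitResult, FitResult, HillParams, HillParams, FitResult]:
    """Hill fits for both drugs plus the static psi fit on the combination arms.

    CIS follows the potent-full-inhibitor convention (r0 = 100 and gamma = 1
    fixed; imax, ic50 free); the shallower CIM curve frees all four
    parameters.
    """
    cis_rows = static[(static.conc_a_uM > 0) & (static.conc_b_uM == 0)]
    cim_rows = static[(static.conc_b_uM > 0) & (static.conc_a_uM == 0)]
    combo_rows = static[(static.conc_a_uM > 0) & (static.conc_b_uM > 0)]

    spec_cis = default_hill_spec(
        cis_rows.conc_a_uM.to_numpy(), cis_rows.viability_pct.to_numpy(),
        free=("imax", "ic50"),
    )
    fit_cis = fit_hill(cis_rows.conc_a_uM.to_numpy(), cis_rows.viability_pct.to_numpy(), spec_cis)
    spec_cim = default_hill_spec(
        cim_rows.conc_b_uM.to_numpy(), cim_rows.viability_pct.to_numpy(),
        free=("r0", "imax", "ic50", "gamma"),
    )
    fit_cim = fit_hill(cim_rows.conc_b_uM.to_numpy(), cim_rows.viability_pct.to_numpy(), spec_cim)

    hill_cis = _hill_params_from_fit(fit_cis, spec_cis.fixed)
    hill_cim = _hill_params_from_fit(fit_cim, spec_cim.fixed)

    fit_psi = fit_interaction_static(
        combo_rows.conc_a_uM.to_numpy(),
        combo_rows.conc_b_uM.to_numpy(),
        combo_rows.viability_pct.to_numpy(),
        hill_cis,
        hill_cim,
        psi_on=psi_on,
    )
    return fit_cis, fit_cim, hill_cis, hill_cim, fit_psi


def fit_timecourse_stage(
    timecourse: pd.DataFrame,
) -> tuple[FitResult, FitResult, FitResult, FitResult]:
    """Sequential dynamic fits: kg from control, per-drug kill models, then psi."""
    control = timecourse[(timecourse.conc_a_uM == 0) & (timecourse.conc_b_uM == 0)]
    cis_rows = timecourse[timecourse.conc_b_uM == 0]  # includes control
    cim_rows = timecourse[timecourse.conc_a_uM == 0]
    combo_rows = timecourse[(timecourse.conc_a_uM > 0) & (timecourse.conc_b_uM > 0)]

    growth = fit_growth(control.time_h.to_numpy(), control.viability_pct.to_numpy())
    kg = growth.estimates["kg"]

    spec_cis = default_pd_spec(
        cis_rows.conc_a_uM.to_numpy(), free=("smax", "sc50", "tau"),
        fixed_values={"kg": kg, "r0": 100.0},
    )
    pd_cis = fit_pd_single(
        cis_rows.conc_a_uM.to_numpy(), cis_rows.time_h.to_numpy(),
        cis_rows.viability_pct.to_numpy(), spec_cis,
    )
    spec_cim = default_pd_spec(
        cim_rows.conc_b_uM.to_numpy(), free=("smax", "sc50", "tau"),
        fixed_values={"kg": kg, "r0": 100.0},
    )
    pd_cim = fit_pd_single(
        cim_rows.conc_b_uM.to_numpy(), cim_rows.time_h.to_numpy(),
        cim_rows.viability_pct.to_numpy(), spec_cim,
    )

    cis_params = PDAgentParams(
        smax=pd_cis.estimates["smax"], sc50=pd_cis.estimates["sc50"], tau=pd_cis.estimates["tau"]
    )
    cim_params = PDAgentParams(
        smax=pd_cim.estimates["smax"], sc50=pd_cim.estimates["sc50"], tau=pd_cim.estimates["tau"]
    )
    psi_fit = fit_pd_combo(
        combo_rows.conc_a_uM.to_numpy(),
        combo_rows.conc_b_uM.to_numpy(),
        combo_rows.time_h.to_numpy(),
        combo_rows.viability_pct.to_numpy(),
        kg=kg, r0=100.0, cis=cis_params, cim=cim_params,
    )
    return growth, pd_cis, pd_cim, psi_fit


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis; returns the report and writes all artifacts."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _Stage("data"):
        if config.static_csv and config.timecourse_csv:
            static = read_viability_table(config.static_csv)
            timecourse = read_viability_table(config.timecourse_csv)
        elif config.static_csv or config.timecourse_csv:
            raise ValueError("provide both static_csv and timecourse_csv, or neither")
        else:
            design = default_design(config.cell_line)
            noise = NoiseModel(
                cv_proportional=config.cv_proportional,
                sd_additive=config.sd_additive,
                seed=config.seed,
            )
            static = generate_static(design, interaction_params(config.cell_line), noise)
            tc_noise = NoiseModel(
                cv_proportional=config.cv_proportional,
                sd_additive=config.sd_additive,
                seed=config.seed + 1,
            )
            timecourse = generate_timecourse(design, pd_system(config.cell_line), tc_noise)
            write_dataset(static, outdir / "data" / "static.csv", design, noise)
            write_dataset(timecourse, outdir / "data" / "timecourse.csv", design, tc_noise)
        static = validate_viability_table(static)
        timecourse = validate_viability_table(timecourse)

    with _Stage("static_fits"):
        fit_cis, fit_cim, hill_cis, hill_cim, fit_psi_static = fit_static_stage(
            static, psi_on=config.psi_on
        )
        _write_json(fit_cis.to_dict(), outdir / "results" / "hill_cis.json")
        _write_json(fit_cim.to_dict(), outdir / "results" / "hill_cim.json")
        _write_json(fit_psi_static.to_dict(), outdir / "results" / "psi_static.json")

    with _Stage("surface"):
        combo_rows = static[(static.conc_a_uM > 0) & (static.conc_b_uM > 0)]
        calls, summary = classify_points(hill_cis, hill_cim, combo_rows)
        calls.to_csv(outdir / "surface_calls.csv", index=False)
        grid = build_additive_surface(
            hill_cis,
            hill_cim,
            np.geomspace(combo_rows.conc_a_uM.min(), combo_rows.conc_a_uM.max(), 50),
            np.geomspace(combo_rows.conc_b_uM.min(), combo_rows.conc_b_uM.max(), 50),
        )
        plot_surface(grid, calls, outdir / "surface.png")

    with _Stage("timecourse_fits"):
        growth, pd_cis, pd_cim, fit_psi_tc = fit_timecourse_stage(timecourse)
        _write_json(growth.to_dict(), outdir / "results" / "growth.json")
        _write_json(pd_cis.to_dict(), outdir / "results" / "pd_cis.json")
        _write_json(pd_cim.to_dict(), outdir / "results" / "pd_cim.json")
        _write_json(fit_psi_tc.to_dict(), outdir / "results" / "psi_timecourse.json")

    with _Stage("report"):
        psi_s = fit_psi_static.estimates["psi"]
        psi_t = fit_psi_tc.estimates["psi"]
        report = AnalysisReport(
            cell_line=config.cell_line,
            hill_cis=fit_cis.to_dict(),
            hill_cim=fit_cim.to_dict(),
            psi_static=psi_s,
            psi_static_label=interpret_psi(psi_s, config.band),
            growth=growth.to_dict(),
            pd_cis=pd_cis.to_dict(),
            pd_cim=pd_cim.to_dict(),
            psi_timecourse=psi_t,
            psi_timecourse_label=interpret_psi(psi_t, config.band),
            band=config.band,
            surface_summary=summary,
            provenance={
                "config_hash": config.hash(),
                "seed": config.seed,
                "combopd_version": __version__,
                "numpy_version": np.__version__,
            },
        )
        _write_json(report.to_dict(), outdir / "report.json")
        (outdir / "report.txt").write_text(report.to_text() + "\n")
    return report
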