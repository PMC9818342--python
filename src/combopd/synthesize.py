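"""Synthetic CCK-8-style viability datasets.

The generators emulate the structure of 96-well viability experiments for a
cisplatin (CIS) + cimetidine (CIM) combination study:

* **static endpoint grids** — single-agent concentration-response arms for
  each drug plus a full combination grid, read out at one endpoint time
  (72 h by default), and
* **time courses** — control, single-agent and combination arms observed on
  a 0–96 h grid.

The default design mirrors the published study layout: six log-spaced CIS
concentrations from 0.05 to 25 µM, six log-spaced CIM concentrations from
50 to 4000 µM, all 36 static combinations, and 24 time-course combinations
(four CIS levels from 0.05 to 1 µM — the saturating top CIS concentrations
are excluded — crossed with the six CIM levels), in triplicate.

Noise is multiplicative-plus-additive Gaussian on the model prediction,
truncated at zero (viability above 100 % is legitimate — controls grow).
Everything is deterministic given the ``NoiseModel`` seed.

Output is a tidy :class:`pandas.DataFrame` with one row per well:
``cell_line, drug_a, conc_a_uM, drug_b, conc_b_uM, time_h, replicate,
viability_pct``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import (
    ExposureSpec,
    InteractionStaticParams,
    PDSystemParams,
    competitive_interaction_response,
    hill_response,
    simulate_control,
    simulate_pd,
)
from .reference import CELL_LINES

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "default_design",
    "generate_static",
    "generate_timecourse",
    "write_dataset",
]

COLUMNS = [
    "cell_line",
    "drug_a",
    "conc_a_uM",
    "drug_b",
    "conc_b_uM",
    "time_h",
    "replicate",
    "viability_pct",
]


@dataclass(frozen=True)
class StudyDesign:
    """Arm layout of one simulated study for one cell line."""

    cell_line: str
    cis_concs: tuple[float, ...]
    cim_concs: tuple[float, ...]
    combo_pairs: tuple[tuple[float, float], ...]
    timecourse_combo_pairs: tuple[tuple[float, float], ...]
    times: tuple[float, ...]
    replicates: int = 3
    endpoint_time: float = 72.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if 0.0 not in self.times:
            raise ValueError("times must include 0")
        for c in (*self.cis_concs, *self.cim_concs):
            if c < 0:
                raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Proportional + additive Gaussian noise on predicted viability.

    ``viability = pred * (1 + N(0, cv^2)) + N(0, sd^2)``, truncated at 0.
    Defaults reflect typical CCK-8 plate variability (10 % CV, 2 % additive).
    """

    cv_proportional: float = 0.10
    sd_additive: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_proportional < 0 or self.sd_additive < 0:
            raise ValueError("noise magnitudes must be >= 0")


NOISE_FREE = NoiseModel(cv_proportional=0.0, sd_additive=0.0, seed=0)


def default_design(cell_line: str) -> StudyDesign:
    """Standard study design for one of the two supported cell lines."""
    if cell_line not in CELL_LINES:
        raise ValueError(
            f"unknown cell line {cell_line!r}; expected one of {CELL_LINES}"
        )
    cis = tuple(np.geomspace(0.05, 25.0, 6))
    cim = tuple(np.geomspace(50.0, 4000.0, 6))
    cis_tc = tuple(np.geomspace(0.05, 1.0, 4))
    return StudyDesign(
        cell_line=cell_line,
        cis_concs=cis,
        cim_concs=cim,
        combo_pairs=tuple((a, b) for a in cis for b in cim),
        timecourse_combo_pairs=tuple((a, b) for a in cis_tc for b in cim),
        times=(0.0, 24.0, 48.0, 72.0, 96.0),
        replicates=3,
        endpoint_time=72.0,
    )


def _apply_noise(pred: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    v = pred * (1.0 + rng.normal(0.0, noise.cv_proportional, pred.shape))
    v = v + rng.normal(0.0, noise.sd_additive, pred.shape)
    return np.maximum(v, 0.0)


def _rows(
    cell_line: str,
    conc_a: float,
    conc_b: float,
    times,
    preds,
    replicates: int,
    noise: NoiseModel,
    rng: np.random.Generator,
    records: list,
) -> None:
    preds = np.atleast_1d(np.asarray(preds, dtype=float))
    times = np.atleast_1d(np.asarray(times, dtype=float))
    for rep in range(1, replicates + 1):
        noisy = _apply_noise(preds, noise, rng)
        for t, v in zip(times, noisy):
            records.append(
                (cell_line, "CIS", conc_a, "CIM", conc_b, t, rep, v)
            )


def generate_static(
    design: StudyDesign,
    params: InteractionStaticParams,
    noise: NoiseModel = NOISE_FREE,
) -> pd.DataFrame:
    """Endpoint viability table: control, single-agent arms, combination grid.

    Single-agent arms are generated from each drug's own Hill curve (psi does
    not touch a drug given alone); combination arms come from the
    competitive-interaction model with the design's psi.
    """
    rng = np.random.default_rng(noise.seed)
    records: list = []
    t = design.endpoint_time
    reps = design.replicates
    _rows(design.cell_line, 0.0, 0.0, t, 100.0, reps, noise, rng, records)
    for c in design.cis_concs:
        pred = hill_response(params.drug_a, c)
        _rows(design.cell_line, c, 0.0, t, pred, reps, noise, rng, records)
    for c in design.cim_concs:
        pred = hill_response(params.drug_b, c)
        _rows(design.cell_line, 0.0, c, t, pred, reps, noise, rng, records)
    for ca, cb in design.combo_pairs:
        pred = competitive_interaction_response(params, ca, cb)
        _rows(design.cell_line, ca, cb, t, pred, reps, noise, rng, records)
    return pd.DataFrame.from_records(records, columns=COLUMNS)


def generate_timecourse(
    design: StudyDesign,
    system: PDSystemParams,
    noise: NoiseModel = NOISE_FREE,
) -> pd.DataFrame:
    """Time-course viability table: control, single agents, 24 combinations.

    Single-agent arms use the kill model with the other drug absent and
    psi = 1 (the interaction only exists in combination); combination arms
    use the system's psi.  The control arm is pure exponential growth.
    """
    rng = np.random.default_rng(noise.seed)
    records: list = []
    times = np.asarray(design.times, dtype=float)
    t_end = float(times[-1])
    reps = design.replicates
    single = PDSystemParams(
        kg=system.kg, r0=system.r0, cis=system.cis, cim=system.cim, psi=1.0
    )

    preds = simulate_control(system.kg, system.r0, times)
    _rows(design.cell_line, 0.0, 0.0, times, preds, reps, noise, rng, records)
    for c in design.cis_concs:
        preds = simulate_pd(single, ExposureSpec(c, 0.0, t_end), times, method="closed_form")
        _rows(design.cell_line, c, 0.0, times, preds, reps, noise, rng, records)
    for c in design.cim_concs:
        preds = simulate_pd(single, ExposureSpec(0.0, c, t_end), times, method="closed_form")
        _rows(design.cell_line, 0.0, c, times, preds, reps, noise, rng, records)
    for ca, cb in design.timecourse_combo_pairs:
        preds = simulate_pd(system, ExposureSpec(ca, cb, t_end), times, method="closed_form")
        _rows(design.cell_line, ca, cb, times, preds, reps, noise, rng, records)
    return pd.DataFrame.from_records(records, columns=COLUMNS)


def write_dataset(
    df: pd.DataFrame,
    path: str | Path,
    design: StudyDesign | None = None,
    noise: NoiseModel | None = None,
    extra_metadata: dict | None = None,
) -> Path:
    """Write a tidy CSV plus a ``.meta.yaml`` sidecar recording provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta: dict = {"n_rows": int(len(df)), "columns": list(df.columns)}
    if design is not None:
        meta["design"] = asdict(design)
    if noise is not None:
        meta["noise"] = asdict(noise)
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump(_pyify(meta), sort_keys=False))
    return path


def _pyify(obj):
    """Recursively convert numpy scalars/tuples so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
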