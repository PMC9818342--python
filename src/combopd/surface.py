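"""Additive response-surface construction and observation classification.

Under the null hypothesis of additivity (psi = 1), the competitive
interaction model defines a reference viability surface over the
(CIS, CIM) concentration plane.  Observed combination wells are classified
relative to that surface: points **above** it (less kill than additivity
predicts) indicate antagonism; points **at or below** indicate additive or
synergistic interaction.  The classification is always done at the exact
observed concentrations — the dense grid exists only for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import HillParams, InteractionStaticParams, competitive_interaction_response

__all__ = [
    "SurfaceGrid",
    "build_additive_surface",
    "additive_prediction",
    "classify_points",
    "plot_surface",
]

ABOVE = "above"
AT_OR_BELOW = "at_or_below"


@dataclass(frozen=True)
class SurfaceGrid:
    """Viability matrix over ascending concentration grids (rows = drug A)."""

    conc_a: np.ndarray
    conc_b: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        if self.viability.shape != (self.conc_a.size, self.conc_b.size):
            raise ValueError("viability matrix shape must match the grids")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("surface contains non-finite values")


def _check_grid(grid, name: str) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if np.any(g < 0):
        raise ValueError(f"{name} must be non-negative")
    if np.any(np.diff(g) <= 0):
        raise ValueError(f"{name} must be strictly ascending")
    return g


def additive_prediction(
    hill_a: HillParams, hill_b: HillParams, conc_a, conc_b, r0: float = 100.0
) -> np.ndarray:
    """Additive-model (psi = 1) viability at the given concentration pairs."""
    params = InteractionStaticParams(drug_a=hill_a, drug_b=hill_b, psi=1.0)
    return competitive_interaction_response(params, conc_a, conc_b, r0=r0)


def build_additive_surface(
    hill_a: HillParams,
    hill_b: HillParams,
    grid_a,
    grid_b,
    r0: float = 100.0,
) -> SurfaceGrid:
    """Evaluate the additive surface on the outer product of two concentration grids."""
    ga = _check_grid(grid_a, "grid_a")
    gb = _check_grid(grid_b, "grid_b")
    aa, bb = np.meshgrid(ga, gb, indexing="ij")
    v = additive_prediction(hill_a, hill_b, aa, bb, r0=r0)
    return SurfaceGrid(conc_a=ga, conc_b=gb, viability=np.asarray(v, dtype=float))


def classify_points(
    hill_a: HillParams,
    hill_b: HillParams,
    observations: pd.DataFrame,
    *,
    tolerance: float = 0.0,
    r0: float = 100.0,
    use_replicate_means: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Classify observed combination wells against the additive surface.

    ``observations`` needs columns ``conc_a_uM``, ``conc_b_uM``,
    ``viability_pct``, all combination rows (both concentrations > 0).  A
    point is ``above`` when observed - predicted > ``tolerance`` (default 0:
    strict inequality, so a point exactly on the surface is at_or_below).
    With ``use_replicate_means`` the replicates of each concentration pair
    are averaged before classification.

    Returns the per-point table plus summary counts and fractions.
    """
    df = observations[["conc_a_uM", "conc_b_uM", "viability_pct"]].copy()
    if len(df) == 0:
        raise ValueError("no observations to classify")
    if np.any((df["conc_a_uM"] <= 0) | (df["conc_b_uM"] <= 0)):
        raise ValueError("classification requires both concentrations > 0")
    if use_replicate_means:
        df = df.groupby(["conc_a_uM", "conc_b_uM"], as_index=False)["viability_pct"].mean()
    pred = additive_prediction(
        hill_a, hill_b, df["conc_a_uM"].to_numpy(), df["conc_b_uM"].to_numpy(), r0=r0
    )
    df["predicted_additive"] = pred
    df["delta"] = df["viability_pct"] - df["predicted_additive"]
    df["call"] = np.where(df["delta"] > tolerance, ABOVE, AT_OR_BELOW)
    n_above = int((df["call"] == ABOVE).sum())
    summary = {
        "n_points": int(len(df)),
        "n_above": n_above,
        "n_at_or_below": int(len(df) - n_above),
        "frac_above": n_above / len(df),
        "tolerance": float(tolerance),
    }
    return df, summary


def plot_surface(
    grid: SurfaceGrid,
    calls: pd.DataFrame | None = None,
    path: str | Path = "surface.png",
    title: str = "Additive response surface (psi = 1)",
) -> Path:
    """Render the 3D additive surface, optionally with classified observations.

    Concentration axes are log10-scaled; above-surface points are red,
    at-or-below points blue (the standard antagonism/synergy color code).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    la = np.log10(grid.conc_a)
    lb = np.log10(grid.conc_b)
    aa, bb = np.meshgrid(la, lb, indexing="ij")
    ax.plot_surface(aa, bb, grid.viability, cmap="viridis", alpha=0.7, linewidth=0)
    if calls is not None and len(calls):
        colors = np.where(calls["call"] == ABOVE, "red", "blue")
        ax.scatter(
            np.log10(calls["conc_a_uM"]),
            np.log10(calls["conc_b_uM"]),
            calls["viability_pct"],
            c=colors,
            s=18,
            depthshade=False,
        )
    ax.set_xlabel("log10 CIS (µM)")
    ax.set_ylabel("log10 CIM (µM)")
    ax.set_zlabel("viability (%)")
    ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
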