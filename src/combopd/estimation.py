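"""Nonlinear least-squares estimation for the static and dynamic models.

The published analysis workflow is sequential: fit each single agent's
model, fix those estimates, then estimate the single interaction parameter
psi from the combination arms.  Every fit here is ordinary (optionally
proportionally weighted) least squares on % viability, solved with a
bounded trust-region reflective optimizer (:func:`scipy.optimize.least_squares`)
from multiple starting points.  Concentration-scale parameters (IC50, SC50,
tau, psi) are optimized on a log10 scale for conditioning and positivity;
estimates, standard errors and %RSE are reported on the natural scale.

Standard errors come from the residual-variance-scaled inverse of J'J at the
solution (the usual Gauss-Newton approximation), propagated through the log
transform by the delta method; %RSE = 100 * SE / |estimate|, matching the
reporting convention of pharmacometric software.

Replicates are fitted as individual observations, not means, so the
residual degrees of freedom reflect the true n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .models import (
    HillParams,
    IntegrationError,
    InteractionStaticParams,
    PDAgentParams,
    competitive_interaction_response,
    transit_kill_integral,
)

__all__ = [
    "FitSpec",
    "FitResult",
    "DegenerateDataError",
    "fit_hill",
    "fit_growth",
    "fit_interaction_static",
    "fit_pd_single",
    "fit_pd_combo",
    "compute_rse",
    "default_hill_spec",
    "default_pd_spec",
]

_LN10 = math.log(10.0)
_PENALTY = 1e6


class DegenerateDataError(ValueError):
    """Raised when the data carry no information about a requested parameter."""


@dataclass
class FitSpec:
    """Declarative description of one least-squares fit.

    ``free`` maps parameter names to initial values (natural scale);
    ``fixed`` maps the remaining model parameters to their held values.
    ``bounds`` are natural-scale (lower, upper) pairs per free parameter;
    parameters listed in ``log_scale`` are optimized as log10.  ``multistart``
    maps parameter names to lists of alternative starting values; the
    optimizer is launched from the Cartesian product of starts and the best
    solution is kept.
    """

    model: str
    free: dict[str, float]
    fixed: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    log_scale: frozenset[str] = frozenset()
    weighting: str = "none"  # or "proportional"
    multistart: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        if self.weighting not in ("none", "proportional"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        for name, (lo, hi) in self.bounds.items():
            if name in self.free and not (lo <= self.free[name] <= hi):
                raise ValueError(
                    f"initial value of {name} ({self.free[name]}) outside bounds ({lo}, {hi})"
                )


@dataclass
class FitResult:
    """Point estimates with uncertainty and convergence diagnostics."""

    estimates: dict[str, float]
    se: dict[str, float]
    rse_pct: dict[str, float]
    objective: float
    n_obs: int
    converged: bool
    covariance: np.ndarray | None
    free_names: list[str]
    flags: list[str] = field(default_factory=list)
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "rse_pct": {k: float(v) for k, v in self.rse_pct.items()},
            "objective": float(self.objective),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "free_names": list(self.free_names),
            "flags": list(self.flags),
            "message": self.message,
        }


def compute_rse(result: FitResult) -> FitResult:
    """Populate %RSE from standard errors: ``100 * SE / |estimate|`` per free parameter."""
    rse = {}
    for name in result.free_names:
        est = result.estimates[name]
        se = result.se.get(name, float("nan"))
        rse[name] = 100.0 * se / abs(est) if est != 0 and np.isfinite(se) else float("nan")
    result.rse_pct = rse
    return result


def _fit_engine(
    predict,
    y: np.ndarray,
    spec: FitSpec,
) -> FitResult:
    """Run bounded multistart least squares of ``y - predict(params)``.

    ``predict`` maps a complete parameter dict to a prediction vector the
    same length as ``y``.  Integration failures and non-finite predictions
    are penalized, not fatal, so the optimizer can back out of bad regions.
    """
    y = np.asarray(y, dtype=float)
    names = list(spec.free)
    if not names:
        raise ValueError("no free parameters")
    log_mask = np.array([n in spec.log_scale for n in names])

    def to_internal(vals: np.ndarray) -> np.ndarray:
        out = vals.astype(float).copy()
        out[log_mask] = np.log10(out[log_mask])
        return out

    def from_internal(x: np.ndarray) -> np.ndarray:
        out = x.astype(float).copy()
        out[log_mask] = 10.0 ** out[log_mask]
        return out

    lo = np.array([spec.bounds.get(n, (-np.inf, np.inf))[0] for n in names])
    hi = np.array([spec.bounds.get(n, (-np.inf, np.inf))[1] for n in names])
    if np.any(log_mask & (lo <= 0)):
        raise ValueError("log-scale parameters require strictly positive lower bounds")
    lo_i = np.where(log_mask, np.log10(np.where(lo > 0, lo, 1.0)), lo)
    hi_i = np.where(log_mask & np.isfinite(hi), np.log10(np.where(hi > 0, hi, 1.0)), hi)

    def residual(x: np.ndarray) -> np.ndarray:
        params = dict(zip(names, from_internal(x)))
        params.update(spec.fixed)
        try:
            pred = np.asarray(predict(params), dtype=float)
        except IntegrationError:
            return np.full_like(y, _PENALTY)
        res = y - pred
        if spec.weighting == "proportional":
            res = res / np.maximum(np.abs(pred), 1e-8)
        res[~np.isfinite(res)] = _PENALTY
        return res

    starts: list[np.ndarray] = []
    grids = [spec.multistart.get(n, [spec.free[n]]) for n in names]
    for combo in itertools.islice(itertools.product(*grids), 64):
        x0 = to_internal(np.array(combo, dtype=float))
        starts.append(np.clip(x0, lo_i, hi_i))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=(lo_i, hi_i),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                x_scale="jac",
                max_nfev=2000 * len(names),
            )
        except Exception:  # noqa: BLE001 - a bad start must not kill the fit
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    n_obs = y.size
    if best is None:
        nan = {n: float("nan") for n in names}
        return FitResult(
            estimates=nan, se=dict(nan), rse_pct=dict(nan),
            objective=float("nan"), n_obs=n_obs, converged=False,
            covariance=None, free_names=names, flags=["no_solution"],
            message="all optimizer starts failed",
        )

    est_nat = from_internal(best.x)
    estimates = dict(zip(names, est_nat))
    ssq = float(2.0 * best.cost)
    flags: list[str] = []
    # flag estimates near an active bound (advisory: 0.1% of the bounded span)
    for i, n in enumerate(names):
        span = hi_i[i] - lo_i[i]
        tol = 1e-3 * (span if np.isfinite(span) else 1.0)
        if best.x[i] - lo_i[i] <= tol or (np.isfinite(hi_i[i]) and hi_i[i] - best.x[i] <= tol):
            flags.append(f"at_bound:{n}")

    p = len(names)
    se = {n: float("nan") for n in names}
    cov_nat: np.ndarray | None = None
    if n_obs > p:
        s2 = ssq / (n_obs - p)
        jtj = best.jac.T @ best.jac
        try:
            cov_int = s2 * np.linalg.pinv(jtj)
            scale = np.where(log_mask, _LN10 * est_nat, 1.0)
            cov_nat = cov_int * np.outer(scale, scale)
            diag = np.diag(cov_nat)
            se = {n: float(np.sqrt(d)) if d >= 0 else float("nan") for n, d in zip(names, diag)}
        except np.linalg.LinAlgError:
            flags.append("singular_jacobian")

    converged = bool(best.status > 0) and np.all(np.isfinite(est_nat))
    result = FitResult(
        estimates=estimates,
        se=se,
        rse_pct={},
        objective=ssq,
        n_obs=n_obs,
        converged=converged,
        covariance=cov_nat,
        free_names=names,
        flags=flags,
        message=str(best.message),
    )
    return compute_rse(result)


def _geomean(x: np.ndarray) -> float:
    x = x[x > 0]
    return float(np.exp(np.mean(np.log(x)))) if x.size else 1.0


# ---------------------------------------------------------------------------
# Static Hill fit
# ---------------------------------------------------------------------------

def default_hill_spec(
    conc,
    viability,
    free: tuple[str, ...] = ("imax", "ic50"),
    fixed_values: dict[str, float] | None = None,
    weighting: str = "none",
) -> FitSpec:
    """Build a Hill FitSpec with data-driven initial values and multistart.

    Unfixed defaults for held parameters: r0 = 100, imax = 1, gamma = 1
    (the conventional fixing pattern for a potent full-inhibition agent).
    IC50 gets five log-spaced starts spanning the tested concentrations.
    """
    conc = np.asarray(conc, dtype=float)
    viability = np.asarray(viability, dtype=float)
    pos = conc[conc > 0]
    init = {
        "r0": float(np.clip(np.max(viability, initial=100.0), 1.0, 1000.0)),
        "imax": 0.9,
        "ic50": _geomean(conc),
        "gamma": 1.0,
    }
    defaults = {"r0": 100.0, "imax": 1.0, "gamma": 1.0}
    fixed = {n: defaults.get(n, init[n]) for n in init if n not in free}
    if fixed_values:
        fixed.update({k: v for k, v in fixed_values.items() if k in fixed})
    bounds = {
        "r0": (1.0, 1000.0),
        "imax": (1e-6, 1.0),
        "ic50": (1e-6, 1e8),
        "gamma": (0.05, 20.0),
    }
    multistart = {}
    if "ic50" in free and pos.size >= 2:
        multistart["ic50"] = list(np.geomspace(pos.min(), pos.max(), 5))
    return FitSpec(
        model="hill",
        free={n: init[n] for n in init if n in free},
        fixed=fixed,
        bounds={n: bounds[n] for n in free},
        log_scale=frozenset({"ic50"} & set(free)),
        weighting=weighting,
        multistart=multistart,
    )


def fit_hill(conc, viability, spec: FitSpec | None = None) -> FitResult:
    """Fit the inhibitory Hill model to one drug's endpoint concentration-response data.

    ``conc`` and ``viability`` are per-well vectors (replicates as separate
    rows).  Requires at least four distinct concentrations when IC50 is free.
    """
    conc = np.asarray(conc, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if conc.shape != viability.shape:
        raise ValueError("conc and viability must have equal length")
    if np.any(conc < 0):
        raise ValueError("negative concentrations")
    if spec is None:
        spec = default_hill_spec(conc, viability)
    if "ic50" in spec.free and np.unique(conc[conc > 0]).size < 4:
        raise ValueError("need >= 4 distinct positive concentrations to estimate ic50")
    if np.ptp(viability) == 0 and "imax" in spec.free:
        raise DegenerateDataError(
            "responses are identical at every concentration; imax is not identifiable"
        )

    def predict(p: dict) -> np.ndarray:
        hp = HillParams(r0=p["r0"], imax=min(max(p["imax"], 1e-12), 1.0),
                        ic50=p["ic50"], gamma=p["gamma"])
        return hp.r0 * (1.0 - hp.imax * conc ** hp.gamma /
                        (hp.ic50 ** hp.gamma + conc ** hp.gamma))

    return _fit_engine(predict, viability, spec)


# ---------------------------------------------------------------------------
# Control growth fit
# ---------------------------------------------------------------------------

def fit_growth(time_h, viability, r0: float | None = 100.0) -> FitResult:
    """Fit the exponential-growth constant kg to an untreated control time course.

    ``r0=None`` frees the baseline; otherwise it is fixed (100 % by default).
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(viability, dtype=float)
    if t.shape != y.shape:
        raise ValueError("time_h and viability must have equal length")
    free: dict[str, float] = {"kg": 0.01}
    fixed: dict[str, float] = {}
    bounds = {"kg": (1e-6, 1.0)}
    if r0 is None:
        free["r0"] = float(np.median(y[t == t.min()])) if np.any(t == t.min()) else 100.0
        bounds["r0"] = (1.0, 1000.0)
    else:
        fixed["r0"] = float(r0)
    spec = FitSpec(model="growth", free=free, fixed=fixed, bounds=bounds,
                   log_scale=frozenset({"kg"}))

    def predict(p: dict) -> np.ndarray:
        return p["r0"] * np.exp(p["kg"] * t)

    return _fit_engine(predict, y, spec)


# ---------------------------------------------------------------------------
# Static interaction (psi) fit
# ---------------------------------------------------------------------------

def fit_interaction_static(
    conc_a,
    conc_b,
    viability,
    drug_a: HillParams,
    drug_b: HillParams,
    *,
    r0: float = 100.0,
    psi0: float = 1.0,
    psi_bounds: tuple[float, float] = (0.01, 100.0),
    psi_on: str = "both",
    weighting: str = "none",
) -> FitResult:
    """Estimate psi from combination arms with both drugs' Hill parameters fixed.

    Only observations with both concentrations strictly positive are used
    (single-agent arms carry no information about the interaction).
    """
    ca = np.asarray(conc_a, dtype=float)
    cb = np.asarray(conc_b, dtype=float)
    y = np.asarray(viability, dtype=float)
    mask = (ca > 0) & (cb > 0)
    if not np.any(mask):
        raise ValueError("no combination observations (both concentrations > 0)")
    ca, cb, y = ca[mask], cb[mask], y[mask]
    spec = FitSpec(
        model="interaction_static",
        free={"psi": psi0},
        bounds={"psi": psi_bounds},
        log_scale=frozenset({"psi"}),
        weighting=weighting,
        multistart={"psi": [0.3, 1.0, 3.0]},
    )

    def predict(p: dict) -> np.ndarray:
        params = InteractionStaticParams(drug_a=drug_a, drug_b=drug_b, psi=p["psi"])
        return competitive_interaction_response(params, ca, cb, r0=r0, psi_on=psi_on)

    return _fit_engine(predict, y, spec)


# ---------------------------------------------------------------------------
# Dynamic (transit-compartment) fits
# ---------------------------------------------------------------------------

def _pd_single_prediction(p: dict, conc: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Closed-form single-agent trajectory, vectorized over observations."""
    with np.errstate(invalid="ignore"):
        k = np.where(conc > 0, p["smax"] * conc / (p["sc50"] + conc), 0.0)
    u = t / p["tau"]
    with np.errstate(under="ignore", over="ignore"):
        kill = k * (t - 3.0 * p["tau"] + p["tau"] * np.exp(-u) * (3.0 + 2.0 * u + 0.5 * u * u))
        return p["r0"] * np.exp(p["kg"] * t - kill)


def default_pd_spec(
    conc,
    free: tuple[str, ...] = ("kg", "smax", "sc50", "tau"),
    fixed_values: dict[str, float] | None = None,
    weighting: str = "none",
) -> FitSpec:
    """FitSpec for the single-agent kill model with log-scale rate/potency params.

    SC50 gets five log-spaced starts from the lowest tested concentration to
    30x the highest (the half-maximal kill concentration may exceed the
    tested range); tau gets three starts spanning fast to slow transit.
    """
    conc = np.asarray(conc, dtype=float)
    pos = conc[conc > 0]
    cmin = float(pos.min()) if pos.size else 0.1
    cmax = float(pos.max()) if pos.size else 100.0
    init = {"kg": 0.01, "r0": 100.0, "smax": 0.05, "sc50": _geomean(conc), "tau": 1.0}
    fixed = {n: init[n] for n in init if n not in free}
    if fixed_values:
        fixed.update({k: v for k, v in fixed_values.items() if k in fixed})
    bounds = {
        "kg": (1e-6, 1.0),
        "r0": (1.0, 1000.0),
        "smax": (1e-6, 10.0),
        "sc50": (1e-6, 1e8),
        "tau": (1e-3, 1e4),
    }
    multistart: dict[str, list[float]] = {}
    if "sc50" in free:
        multistart["sc50"] = list(np.geomspace(cmin, 30.0 * cmax, 5))
    if "tau" in free:
        multistart["tau"] = [0.5, 2.0, 8.0]
    return FitSpec(
        model="pd_single",
        free={n: init[n] for n in init if n in free},
        fixed=fixed,
        bounds={n: bounds[n] for n in free},
        log_scale=frozenset({"kg", "smax", "sc50", "tau"} & set(free)),
        weighting=weighting,
        multistart=multistart,
    )


def fit_pd_single(conc, time_h, viability, spec: FitSpec | None = None) -> FitResult:
    """Fit the single-agent transit-compartment kill model across all arms at once.

    ``conc`` is the per-observation drug concentration (0 for control wells);
    control rows pin kg when it is free.  Constant exposure makes the exact
    closed-form trajectory available, so no ODE solves occur inside the
    optimization loop.
    """
    conc = np.asarray(conc, dtype=float)
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(viability, dtype=float)
    if not (conc.shape == t.shape == y.shape):
        raise ValueError("conc, time_h and viability must have equal length")
    if spec is None:
        spec = default_pd_spec(conc)
    if "kg" in spec.free and not np.any(conc == 0):
        raise ValueError("kg is free but no control (zero-concentration) rows present")

    def predict(p: dict) -> np.ndarray:
        return _pd_single_prediction(p, conc, t)

    return _fit_engine(predict, y, spec)


def fit_pd_combo(
    conc_cis,
    conc_cim,
    time_h,
    viability,
    *,
    kg: float,
    r0: float,
    cis: PDAgentParams,
    cim: PDAgentParams,
    psi0: float = 1.0,
    psi_bounds: tuple[float, float] = (0.01, 100.0),
    weighting: str = "none",
) -> FitResult:
    """Estimate the time-course psi with all single-agent parameters fixed.

    psi scales the CIS SC50 in the combination kill term.  Only rows with at
    least one drug present inform the fit, but control rows are harmless and
    simply contribute zero-kill predictions.
    """
    ccis = np.asarray(conc_cis, dtype=float)
    ccim = np.asarray(conc_cim, dtype=float)
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(viability, dtype=float)
    if not (ccis.shape == ccim.shape == t.shape == y.shape):
        raise ValueError("inputs must have equal length")
    if not np.any((ccis > 0) & (ccim > 0)):
        raise ValueError("no combination observations (both concentrations > 0)")
    spec = FitSpec(
        model="pd_combo",
        free={"psi": psi0},
        bounds={"psi": psi_bounds},
        log_scale=frozenset({"psi"}),
        weighting=weighting,
        multistart={"psi": [0.3, 1.0, 3.0]},
    )

    def predict(p: dict) -> np.ndarray:
        k_cis = np.where(ccis > 0, cis.smax * ccis / (cis.sc50 * p["psi"] + ccis), 0.0)
        k_cim = np.where(ccim > 0, cim.smax * ccim / (cim.sc50 + ccim), 0.0)
        kill = transit_kill_integral(1.0, cis.tau, t) * k_cis
        kill = kill + transit_kill_integral(1.0, cim.tau, t) * k_cim
        with np.errstate(under="ignore", over="ignore"):
            return r0 * np.exp(kg * t - kill)

    return _fit_engine(predict, y, spec)
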