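"""Core pharmacodynamic models for cisplatin (CIS) + cimetidine (CIM) combinations.

Three model families are implemented as pure functions over small frozen
parameter containers:

1. **Static inhibitory Hill model** — % cell viability after a fixed exposure
   time as a function of a single drug concentration:

   ``R(C) = R0 * (1 - Imax * C^gamma / (IC50^gamma + C^gamma))``

2. **Competitive interaction model** — viability under simultaneous exposure
   to two drugs A and B, with a single interaction parameter ``psi`` scaling
   both potencies.  With ``x = (C_A / (psi * IC50_A))^gamma_A`` and
   ``y = (C_B / (psi * IC50_B))^gamma_B``:

   ``R = R0 * (1 - (Imax_A * x + Imax_B * y) / (x + y + 1))``

   ``psi < 1`` means synergy (combination more potent than additive),
   ``psi = 1`` additivity, ``psi > 1`` antagonism.

3. **Cell-level kill-rate ODE model** — exponential growth of untreated
   cells at first-order rate ``kg``, with each drug driving a saturable
   (Emax-type) kill-rate signal ``K = Smax * C / (SC50 + C)`` through a chain
   of three first-order transit compartments (mean transit time ``tau``) that
   delays the onset of cytotoxicity.  The delayed signal ``K3`` acts as an
   additional first-order loss on viability:

   ``dR/dt = kg * R - (K3_CIS + K3_CIM) * R``

   In the combination variant the interaction parameter ``psi`` scales the
   CIS potency only: ``K_CIS = Smax_CIS * C / (psi * SC50_CIS + C)``.

Drug concentrations are held constant over the exposure (no degradation, no
uptake-driven depletion of the medium), so the transit chain admits a closed
form which is exposed both as :func:`transit_k3_closed_form` and as the
``closed_form`` path of :func:`simulate_pd`.

Units: concentrations in µM, times in hours, rate constants in 1/h,
viability in percent of the untreated baseline at time zero.  Viability is
never clipped — growing controls legitimately exceed 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "HillParams",
    "InteractionStaticParams",
    "PDAgentParams",
    "PDSystemParams",
    "ExposureSpec",
    "IntegrationError",
    "hill_response",
    "competitive_interaction_response",
    "simulate_control",
    "simulate_pd",
    "transit_k3_closed_form",
    "transit_kill_integral",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces non-finite state."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(frozen=True)
class HillParams:
    """Static concentration-response (inhibitory Hill) parameters.

    Attributes
    ----------
    r0 : float
        Baseline viability (%), i.e. the response at zero concentration.
    imax : float
        Maximal fractional inhibition, in (0, 1].
    ic50 : float
        Concentration producing half-maximal inhibition (µM).
    gamma : float
        Hill coefficient (steepness), > 0.
    """

    r0: float
    imax: float
    ic50: float
    gamma: float

    def __post_init__(self) -> None:
        _require(self.r0 > 0, f"r0 must be > 0, got {self.r0}")
        _require(0 < self.imax <= 1, f"imax must be in (0, 1], got {self.imax}")
        _require(self.ic50 > 0, f"ic50 must be > 0, got {self.ic50}")
        _require(self.gamma > 0, f"gamma must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class InteractionStaticParams:
    """Two fixed single-agent Hill parameter sets plus the interaction term psi."""

    drug_a: HillParams
    drug_b: HillParams
    psi: float

    def __post_init__(self) -> None:
        _require(self.psi > 0, f"psi must be > 0, got {self.psi}")


@dataclass(frozen=True)
class PDAgentParams:
    """Per-drug parameters of the dynamic cell-kill model.

    Attributes
    ----------
    smax : float
        Maximal killing rate constant (1/h).
    sc50 : float
        Concentration producing the half-maximal kill rate (µM).  Distinct
        from the static IC50: SC50 shapes a rate, IC50 an endpoint.
    tau : float
        Mean transit time of the three-stage delay chain (h).
    """

    smax: float
    sc50: float
    tau: float

    def __post_init__(self) -> None:
        _require(self.smax > 0, f"smax must be > 0, got {self.smax}")
        _require(self.sc50 > 0, f"sc50 must be > 0, got {self.sc50}")
        _require(self.tau > 0, f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class PDSystemParams:
    """Full dynamic system for one cell line: growth, both drugs, interaction.

    ``psi`` scales the CIS SC50 in the combination model; ``psi = 1``
    recovers the additive combination (and the single-agent model when one
    concentration is zero).
    """

    kg: float
    r0: float
    cis: PDAgentParams
    cim: PDAgentParams
    psi: float = 1.0

    def __post_init__(self) -> None:
        _require(self.kg > 0, f"kg must be > 0, got {self.kg}")
        _require(self.r0 > 0, f"r0 must be > 0, got {self.r0}")
        _require(self.psi > 0, f"psi must be > 0, got {self.psi}")


@dataclass(frozen=True)
class ExposureSpec:
    """Constant-concentration exposure: both drug levels fixed for t in [0, t_end]."""

    conc_cis: float
    conc_cim: float
    t_end: float

    def __post_init__(self) -> None:
        _require(self.conc_cis >= 0, f"conc_cis must be >= 0, got {self.conc_cis}")
        _require(self.conc_cim >= 0, f"conc_cim must be >= 0, got {self.conc_cim}")
        _require(self.t_end > 0, f"t_end must be > 0, got {self.t_end}")


def _as_nonneg_array(conc, name: str) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError(f"{name} must be non-negative")
    return c


def _maybe_scalar(x: np.ndarray, like) -> float | np.ndarray:
    if np.ndim(like) == 0:
        return float(x)
    return x


def hill_response(params: HillParams, conc) -> float | np.ndarray:
    """Viability (%) under the inhibitory Hill model at concentration ``conc`` (µM).

    Monotonically non-increasing in ``conc``; returns ``r0`` at zero dose.
    Accepts scalars or arrays.
    """
    c = _as_nonneg_array(conc, "conc")
    with np.errstate(over="ignore"):
        cg = c ** params.gamma
        frac = params.imax * cg / (params.ic50 ** params.gamma + cg)
    r = params.r0 * (1.0 - frac)
    return _maybe_scalar(r, conc)


def competitive_interaction_response(
    params: InteractionStaticParams,
    conc_a,
    conc_b,
    *,
    r0: float = 100.0,
    psi_on: str = "both",
) -> float | np.ndarray:
    """Viability (%) of the two-drug competitive interaction model.

    Parameters
    ----------
    params
        Single-agent Hill parameters for both drugs plus psi.
    conc_a, conc_b
        Concentrations of drug A and B (µM); scalars or broadcastable arrays.
    r0
        Baseline viability of the combination experiment (default 100 %).
        The single-agent ``r0`` fields are deliberately not reused here: the
        combination model is anchored at the plate's own control.
    psi_on
        ``"both"`` (default) applies psi to both drugs' IC50s; ``"drug_a"``
        applies it to drug A only (alternative convention in the
        competitive-interaction literature).

    At ``conc_a = conc_b = 0`` the result is exactly ``r0`` (no division
    error).  With ``conc_b = 0`` the model reduces to the Hill curve of drug
    A with IC50 replaced by ``psi * IC50_A``.
    """
    if psi_on not in ("both", "drug_a"):
        raise ValueError(f"psi_on must be 'both' or 'drug_a', got {psi_on!r}")
    ca = _as_nonneg_array(conc_a, "conc_a")
    cb = _as_nonneg_array(conc_b, "conc_b")
    pa, pb = params.drug_a, params.drug_b
    psi_b = params.psi if psi_on == "both" else 1.0
    with np.errstate(over="ignore"):
        x = (ca / (params.psi * pa.ic50)) ** pa.gamma
        y = (cb / (psi_b * pb.ic50)) ** pb.gamma
        r = r0 * (1.0 - (pa.imax * x + pb.imax * y) / (x + y + 1.0))
    if np.ndim(conc_a) == 0 and np.ndim(conc_b) == 0:
        return float(r)
    return r


def _check_time_grid(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    return t


def simulate_control(kg: float, r0: float, times) -> np.ndarray:
    """Untreated-control trajectory: exponential growth ``R(t) = r0 * exp(kg * t)``."""
    t = _check_time_grid(times)
    return r0 * np.exp(kg * t)


def transit_k3_closed_form(k: float, tau: float, t) -> float | np.ndarray:
    """Delayed kill signal K3(t) for a constant input ``k`` into the transit chain.

    The three-stage chain with rate 1/tau and zero initial conditions,
    driven by a constant source ``k``, has the analytic solution

    ``K3(t) = k * (1 - exp(-u) * (1 + u + u^2/2))``,  ``u = t / tau``,

    which rises from 0 at t = 0 to the steady state ``k`` as t → ∞.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be non-negative")
    u = tt / tau
    with np.errstate(under="ignore"):
        k3 = k * (1.0 - np.exp(-u) * (1.0 + u + 0.5 * u * u))
    return _maybe_scalar(k3, t)


def transit_kill_integral(k: float, tau: float, t) -> float | np.ndarray:
    """Cumulative kill exposure ``∫₀ᵗ K3(s) ds`` for constant input ``k``.

    Antiderivative of :func:`transit_k3_closed_form`:

    ``k * (t - 3*tau + tau * exp(-u) * (3 + 2u + u^2/2))``, ``u = t/tau``.

    This is the exponent deficit of the closed-form viability solution.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    tt = np.asarray(t, dtype=float)
    u = tt / tau
    with np.errstate(under="ignore"):
        integral = k * (tt - 3.0 * tau + tau * np.exp(-u) * (3.0 + 2.0 * u + 0.5 * u * u))
    return _maybe_scalar(integral, t)


def kill_rate_constants(params: PDSystemParams, exposure: ExposureSpec) -> tuple[float, float]:
    """Constant Emax kill-rate inputs (K_CIS, K_CIM) for a constant exposure.

    psi scales the CIS SC50 only (the CIM term is psi-free).
    """
    k_cis = 0.0
    if exposure.conc_cis > 0:
        k_cis = params.cis.smax * exposure.conc_cis / (
            params.cis.sc50 * params.psi + exposure.conc_cis
        )
    k_cim = 0.0
    if exposure.conc_cim > 0:
        k_cim = params.cim.smax * exposure.conc_cim / (params.cim.sc50 + exposure.conc_cim)
    return k_cis, k_cim


def simulate_pd(
    params: PDSystemParams,
    exposure: ExposureSpec,
    times,
    method: str = "ode",
) -> np.ndarray:
    """Viability trajectory (%) of the transit-compartment kill model.

    Parameters
    ----------
    params
        Growth, per-drug kill and interaction parameters.
    exposure
        Constant CIS/CIM concentrations; set one to 0 for single-agent use.
    times
        Ascending, non-negative observation grid (h).
    method
        ``"ode"`` integrates the seven-state system (six transit states plus
        viability) with LSODA at rtol 1e-8; ``"closed_form"`` evaluates the
        exact solution available for constant exposure,

        ``R(t) = r0 * exp(kg*t - Σ_x ∫₀ᵗ K3_x(s) ds)``.

        Both paths agree to solver tolerance; ``closed_form`` is the fast
        path used inside estimation loops.
    """
    t = _check_time_grid(times)
    if t[-1] > exposure.t_end:
        raise ValueError(
            f"times extend past exposure t_end ({t[-1]} > {exposure.t_end})"
        )
    k_cis, k_cim = kill_rate_constants(params, exposure)

    if method == "closed_form":
        exponent = params.kg * t
        exponent = exponent - transit_kill_integral(k_cis, params.cis.tau, t)
        exponent = exponent - transit_kill_integral(k_cim, params.cim.tau, t)
        return params.r0 * np.exp(exponent)

    if method != "ode":
        raise ValueError(f"method must be 'ode' or 'closed_form', got {method!r}")

    tau_c, tau_m = params.cis.tau, params.cim.tau
    kg = params.kg

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        k1c, k2c, k3c, k1m, k2m, k3m, r = y
        return [
            (k_cis - k1c) / tau_c,
            (k1c - k2c) / tau_c,
            (k2c - k3c) / tau_c,
            (k_cim - k1m) / tau_m,
            (k1m - k2m) / tau_m,
            (k2m - k3m) / tau_m,
            (kg - k3c - k3m) * r,
        ]

    y0 = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, params.r0]
    # tiny absolute tolerance on the viability state so relative accuracy is
    # preserved even deep into exponential decay
    atol = [1e-12] * 6 + [1e-30]
    sol = solve_ivp(
        rhs,
        (0.0, max(t[-1], 1e-9)),
        y0,
        method="LSODA",
        t_eval=t,
        rtol=1e-8,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            "non-finite state during integration "
            f"(params={params}, exposure={exposure})"
        )
    return sol.y[6]
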