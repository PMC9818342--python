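"""Published in vitro parameter estimates for the two study cell lines.

These are the cisplatin (CIS) / cimetidine (CIM) parameter sets reported for
the OCT2-negative hepatocellular carcinoma line Huh7 and the OCT2-positive
breast cancer line MDA-MB-468:

* static inhibitory Hill parameters per drug and cell line (72 h endpoint),
* the static competitive-interaction psi per cell line,
* the dynamic cell-kill system (growth rate kg, per-drug Smax / SC50 / transit
  rate 1/tau) and the time-course psi per cell line.

They serve two purposes: sensible defaults for simulation, and generating
truths for the parameter-recovery test battery (simulate from these values,
fit, and check the estimates come back).

All concentrations are µM (the CIM SC50s, reported in the tens of mM, are
stored as µM: 36886.97 and 21453.95).  Transit times tau are stored directly;
the literature convention of quoting the transit *rate* 1/tau (1.17, 0.101,
1.92, 0.523 1/h) is recovered as ``1 / tau``.
"""

from __future__ import annotations

from .models import HillParams, InteractionStaticParams, PDAgentParams, PDSystemParams

__all__ = [
    "CELL_LINES",
    "HILL_PARAMS",
    "STATIC_PSI",
    "PD_PARAMS",
    "interaction_params",
    "pd_system",
]

CELL_LINES = ("Huh7", "MDA-MB-468")

#: Static Hill parameters keyed by (cell_line, drug).
HILL_PARAMS: dict[tuple[str, str], HillParams] = {
    ("Huh7", "CIS"): HillParams(r0=100.0, imax=1.0, ic50=1.96, gamma=1.0),
    ("MDA-MB-468", "CIS"): HillParams(r0=100.0, imax=1.0, ic50=0.39, gamma=1.0),
    ("Huh7", "CIM"): HillParams(r0=99.5, imax=0.99, ic50=3190.0, gamma=3.12),
    ("MDA-MB-468", "CIM"): HillParams(r0=97.4, imax=1.0, ic50=3280.0, gamma=1.83),
}

#: Static competitive-interaction psi per cell line (72 h combination grids).
STATIC_PSI: dict[str, float] = {"Huh7": 0.95, "MDA-MB-468": 1.27}

#: Dynamic cell-kill system per cell line, including the time-course psi.
PD_PARAMS: dict[str, PDSystemParams] = {
    "Huh7": PDSystemParams(
        kg=0.011,
        r0=100.0,
        cis=PDAgentParams(smax=0.038, sc50=4.27, tau=1.0 / 1.17),
        cim=PDAgentParams(smax=0.106, sc50=36886.97, tau=1.0 / 1.92),
        psi=0.96,
    ),
    "MDA-MB-468": PDSystemParams(
        kg=0.018,
        r0=100.0,
        cis=PDAgentParams(smax=0.108, sc50=2.48, tau=1.0 / 0.101),
        cim=PDAgentParams(smax=0.096, sc50=21453.95, tau=1.0 / 0.523),
        psi=2.2,
    ),
}


def _check_cell_line(cell_line: str) -> None:
    if cell_line not in CELL_LINES:
        raise ValueError(f"unknown cell line {cell_line!r}; expected one of {CELL_LINES}")


def interaction_params(cell_line: str, psi: float | None = None) -> InteractionStaticParams:
    """Static interaction parameter set for ``cell_line`` (CIS as drug A, CIM as B)."""
    _check_cell_line(cell_line)
    return InteractionStaticParams(
        drug_a=HILL_PARAMS[(cell_line, "CIS")],
        drug_b=HILL_PARAMS[(cell_line, "CIM")],
        psi=STATIC_PSI[cell_line] if psi is None else psi,
    )


def pd_system(cell_line: str, psi: float | None = None) -> PDSystemParams:
    """Dynamic kill-model parameters for ``cell_line``, optionally overriding psi."""
    _check_cell_line(cell_line)
    base = PD_PARAMS[cell_line]
    if psi is None:
        return base
    return PDSystemParams(kg=base.kg, r0=base.r0, cis=base.cis, cim=base.cim, psi=psi)
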