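# combopd

In vitro pharmacodynamic analysis of **cisplatin (CIS) + cimetidine (CIM)**
combinations on cancer cell viability: static Hill concentration-response
fitting, competitive-interaction response-surface analysis with an
interaction parameter ψ, and a transit-compartment cell-kill model for
time-course data.

The scientific question the toolkit addresses: cimetidine, an OCT2
transporter inhibitor, is a candidate co-treatment to blunt
cisplatin-induced nephrotoxicity — but does it also blunt cisplatin's
anticancer effect? The answer is quantified for an OCT2-negative
hepatocellular line (Huh7) and an OCT2-positive breast cancer line
(MDA-MB-468) as a single interaction parameter ψ, estimated two independent
ways (static 72-h grids and 0–96 h time courses). ψ < 1 indicates synergy,
ψ = 1 additivity, ψ > 1 antagonism.

The raw viability data of such a study are rarely public, so the package
ships a synthetic-data generator that produces CCK-8-style plate tables with
the same design (6 × 6 static combination grids in triplicate, 24
time-course combinations), making the whole pipeline runnable and testable
end to end as a **parameter-recovery study**: simulate from the published
parameter sets, fit, and check the estimates come back.

## Models

**Static single agent** (per drug and cell line, 72 h endpoint):

    R(C) = R0 · (1 − Imax · C^γ / (IC50^γ + C^γ))

**Static combination** (competitive interaction; x = (C_A/(ψ·IC50_A))^γA,
y = (C_B/(ψ·IC50_B))^γB):

    R = R0 · [1 − (Imax,A·x + Imax,B·y) / (x + y + 1)]

**Time course** — untreated cells grow exponentially at rate k_g; each drug
drives a saturable kill signal K = Smax·C/(SC50 + C) through three
first-order transit compartments (mean transit time τ) that delay
cytotoxicity; the delayed signal K3 is a first-order loss on viability:

    dR/dt = k_g·R − (K3_CIS + K3_CIM)·R,   R(0) = R0

In combination, ψ rescales the CIS potency: K_CIS = Smax·C/(ψ·SC50 + C).
Because concentrations are constant in vitro, the system has an exact
closed-form solution which the estimation code uses (the ODE integrator is
retained and cross-checked against it).

Estimation mirrors the sequential study workflow: fit single agents →
fix → estimate ψ alone, by bounded multistart nonlinear least squares, with
%RSE reported from the residual-variance-scaled inverse of J′J.

## Worked example

```python
from combopd import RunConfig, run_pipeline

report = run_pipeline(RunConfig(outdir="run_huh7", cell_line="Huh7", seed=3))
print(report.to_text())
```

Output (noise-free simulation from the built-in Huh7 reference parameters):

```
combopd analysis report — Huh7
================================================

Static concentration-response (72 h endpoint)
  CIS Hill fit : imax=1 (6e-15% RSE), ic50=1.96 (2.2e-14% RSE)
  CIM Hill fit : r0=99.5 (2.3e-15% RSE), imax=0.99 (3e-13% RSE), ic50=3190 (2.5e-13% RSE), gamma=3.12 (2.1e-13% RSE)
  interaction psi (static)      : 0.95  -> additive (band ±0.1)

Surface classification vs additive (psi = 1) surface
  points above surface          : 0 / 108 (frac 0.00)

Time-course kill model (0-96 h)
  growth kg    : kg=0.011 (7.8e-15% RSE)
  CIS kill fit : smax=0.038 (2.8e-14% RSE), sc50=4.27 (3.3e-14% RSE), tau=0.8547 (3.4e-13% RSE)
  CIM kill fit : smax=0.106 (3e-13% RSE), sc50=3.689e+04 (3.2e-13% RSE), tau=0.5208 (1.1e-12% RSE)
  interaction psi (time-course) : 0.96  -> additive (band ±0.1)
```

Reading it: the CIS IC50 (1.96 µM) and the CIM curve (IC50 3.19 mM, Hill
coefficient 3.12) are recovered exactly from the simulated grids; the static
ψ = 0.95 and time-course ψ = 0.96 both land in the additive band (±0.1), and
every combination well sits at or below the additive surface — the
additive-to-mildly-synergistic Huh7 phenotype. Running the same pipeline
with `cell_line="MDA-MB-468"` yields ψ = 1.27 (static) and ψ = 2.2
(time-course): antagonism in the OCT2-positive line. The near-zero %RSE
values are the expected signature of noise-free data; add noise with
`cv_proportional=0.1, sd_additive=2.0` for realistic uncertainty.

The same stages are available as a CLI
(`combopd simulate | fit-dr | fit-interaction | fit-pd | fit-combo |
surface | report | all`), each reading/writing plain CSV/JSON/PNG files.

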