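# Methods

## Scope and model structure

`combopd` implements three connected pharmacodynamic analyses of a two-drug
combination (cisplatin, CIS; cimetidine, CIM) on cancer cell viability
measured by a CCK-8-type plate assay, plus the machinery to simulate such
experiments and recover parameters from them.

### Static concentration-response (single agents)

Viability at a fixed endpoint (72 h by default) follows an inhibitory Hill
function

R(C) = R0 · (1 − Imax · C^γ / (IC50^γ + C^γ))

with baseline R0 (%), maximal fractional inhibition Imax ∈ (0, 1], potency
IC50 (µM) and steepness γ. CIS curves follow the potent-full-inhibitor
convention (R0 = 100 and γ = 1 fixed; Imax, IC50 estimated); the much
shallower CIM curves free all four parameters. These are per-curve
conventions, overridable through `FitSpec`.

### Static combination (competitive interaction)

Combination wells are described by a competitive-interaction response
surface with a single interaction parameter ψ scaling both drugs' potencies:
with x = (C_A/(ψ·IC50_A))^γA and y = (C_B/(ψ·IC50_B))^γB,

R = R0 · [1 − (Imax,A·x + Imax,B·y)/(x + y + 1)],  R0 = 100.

ψ < 1 means the combination behaves as if each drug were more potent than
its single-agent curve (synergy); ψ > 1 antagonism; ψ = 1 exact additivity.
At zero doses x = y = 0 and R = R0 analytically — there is no division
hazard. With one drug absent the model reduces to the other drug's Hill
curve with IC50 → ψ·IC50, which is the reduction identity the tests pin.

The convention of applying ψ to *both* IC50s is the default. Part of the
competitive-interaction literature applies it to one drug only; this is
available as `psi_on="drug_a"` but is not the default, and the two
conventions are not interchangeable when comparing ψ values across studies.

### Time-course cell-level model

Untreated cells grow exponentially, dR/dt = kg·R, R(0) = R0 — viability
above 100 % is legitimate and is never clipped. Each drug contributes a
saturable kill-rate signal K = Smax·C/(SC50 + C) (maximal kill rate Smax in
1/h; SC50 the concentration at half-maximal *rate*, deliberately distinct
from the endpoint IC50). Cytotoxicity is delayed through three linear
transit compartments with mean transit time τ:

dK1/dt = (K − K1)/τ, dK2/dt = (K1 − K2)/τ, dK3/dt = (K2 − K3)/τ,
all starting at 0, and dR/dt = kg·R − (K3_CIS + K3_CIM)·R.

In combination the interaction parameter multiplies the CIS SC50 only
(K_CIS = Smax·C/(ψ·SC50 + C)); the CIM term is ψ-free. This asymmetric
placement means ψ is exactly a potency rescaling of CIS in the presence of
CIM, which the tests verify as an identity (ψ = 2 equals doubling SC50_CIS).

Drug concentrations are assumed constant over the exposure (no degradation
or depletion), so for each arm K is a constant and the transit chain has the
closed form K3(t) = K·(1 − e^(−u)(1 + u + u²/2)), u = t/τ, with cumulative
kill exposure ∫₀ᵗK3 = K·(t − 3τ + τe^(−u)(3 + 2u + u²/2)), giving the exact
trajectory R(t) = R0·exp(kg·t − Σ_x ∫₀ᵗK3_x). The antiderivative is verified
in the test suite against direct numerical integration of the transit ODEs.
`simulate_pd` exposes both paths; the `ode` path (LSODA, rtol 1e−8, atol
1e−12 on transit states and 1e−30 on viability so relative accuracy survives
deep exponential decay) exists for generality and is held to agree with the
closed form to rtol 1e−6 across randomized parameter draws. Estimation uses
the closed form: it is exact and orders of magnitude faster.

## Estimation

All fits are ordinary least squares on % viability (the original analysis
was run in a population-PK/PD tool whose error model is not part of this
package's contract; OLS on per-well observations is the simplest defensible
objective, with proportional weighting available via `FitSpec.weighting`).
Replicates enter as individual observations, preserving the residual
degrees of freedom.

The solver is SciPy's bounded trust-region-reflective `least_squares` with
tight tolerances (xtol = ftol = gtol = 1e−15). Strictly positive scale
parameters (IC50, SC50, τ, ψ, kg, Smax) are optimized as log10 values, which
enforces positivity and conditions the problem when the data only weakly
bound a potency (the CIM SC50 sits an order of magnitude above the highest
tested concentration and is still recovered). Multistart guards against
local minima: five log-spaced starts for IC50 spanning the tested range,
five for SC50 from the lowest concentration to 30× the highest, three for τ
(0.5, 2, 8 h) and three for ψ (0.3, 1, 3); the best final objective wins.
Integration failures or non-finite predictions during a fit are penalized
(large residuals), not fatal.

The sequential workflow mirrors the study design: (1) fit kg on the control
arm; (2) fit each drug's (Smax, SC50, τ) on control + single-agent arms with
kg fixed; (3) fix everything and estimate ψ alone on the combination arms.
The static branch is analogous: Hill fits per drug, then ψ on the 36
combination wells. Only wells with both concentrations > 0 inform ψ.

Uncertainty: covariance = s²(JᵀJ)⁻¹ at the solution with s² the residual
mean square, mapped to the natural scale by the delta method
(SE_nat = ln 10 · θ̂ · SE_log10); %RSE = 100·SE/|θ̂|. With n ≤ p or a singular
JᵀJ the SEs are reported as NaN rather than fabricated. Estimates within
0.1 % of a bound are flagged `at_bound:<name>` (advisory; e.g. Imax → 0 on
no-effect data). Exactly constant responses with Imax free raise
`DegenerateDataError` instead, since no finite fit is meaningful.

## Surface analysis

The additive reference surface is the competitive-interaction model at
ψ = 1, built from the fitted single-agent Hill parameters. Observed
combination wells are classified **above** the surface when
observed − predicted > tolerance (default tolerance 0, i.e. strict
inequality, so a point exactly on the surface counts as at-or-below —
matching the dichotomy in which at-or-below means additive/synergistic and
above means antagonistic). Classification always happens at the exact
observed concentrations; the dense 50 × 50 log-spaced grid exists only for
the 3D plot. Per-well classification is the default; replicate means are an
option. With symmetric noise around a ψ = 1 truth the fraction above is ~½;
with noise-free data it is a step function of the generating ψ at 1 — both
are tested.

## Synthetic data

The generator reproduces the study design: six log-spaced CIS levels
(0.05–25 µM), six log-spaced CIM levels (50–4000 µM ≡ 0.05–4 mM), the full
6 × 6 static combination grid, and 24 time-course combinations (four CIS
levels, 0.05–1 µM, crossed with six CIM levels — the top CIS arms are
excluded because their responses saturate), on a 0/24/48/72/96 h grid, in
triplicate. Endpoints between the published range limits are log-spaced;
the intermediate levels of the original plates were not published, so
log-spacing is the recorded, reproducible choice and is written to the
dataset's metadata sidecar.

Noise is `pred·(1 + N(0, cv²)) + N(0, sd²)` truncated at zero, with
defaults cv = 0.10 and sd = 2 % — typical CCK-8 plate variability — and
deterministic given the seed. Single-agent arms are generated from each
drug's own single-agent model (ψ never touches a drug given alone);
combination arms from the interaction models.

What the generator does *not* emulate: plate-edge and position effects,
absorbance-stage chemistry and background subtraction, drug degradation or
medium depletion, and inter-experiment batch variation. Passing recovery
tests therefore demonstrates estimator self-consistency under the stated
design and noise model — that the pipeline can find back the parameters
that made the data — not robustness to the structured artifacts of real
plates.

## Interpretation band

ψ estimates are labelled synergistic / additive / antagonistic with an
equivalence band |ψ − 1| ≤ 0.1 by default. The band encodes the judgment
that values like 0.95 are better read as "additive to modestly synergistic"
than as firm synergy; it is reported alongside every label and is
configurable. The band is an interpretation device only — no estimation
step depends on it.

## Numerical choices and degenerate inputs

- Canonical concentration unit is µM everywhere internally; mM columns are
  converted (×1000) at the I/O boundary.
- ODE tolerances rtol 1e−8 / atol (1e−12, viability 1e−30); the transit
  chain is linear and only mildly stiff, but tight tolerances make the
  ODE-vs-closed-form agreement test meaningful at rtol 1e−6.
- Zero concentration is handled analytically in every model (no 0/0).
- Time grids must be non-negative and ascending; t = 0 is drug addition.
- Viability is truncated at 0 by the *noise* model only; model predictions
  themselves are never clipped in either direction.
- Hill evaluation at γ > 1 and C = 0 is exact (0^γ = 0); overflow in
  (C/IC50)^γ for extreme draws is tolerated and cancels in the ratio.

## Problem sizes

The default recovery battery uses the design above: 18 observations per
single-agent static fit, 108 per static ψ fit, 105 per single-agent
time-course fit and 360 per time-course ψ fit; the stochastic-robustness
check runs 50 Monte-Carlo replicates at 10 % CV per ψ value. These sizes
match the emulated study layout; the full suite and the acceptance script
each complete in well under a minute.

## Known limitations

- ψ is a single scalar: it cannot represent interactions that change sign
  across the concentration plane or over time.
- OLS on viability percentages treats all wells homoscedastically unless
  proportional weighting is requested; neither is a claim about the error
  structure of the original instrument.
- The fixed three-compartment transit chain is a structural assumption;
  model selection over chain length is out of scope.
- No population/mixed-effects estimation: parameters are per cell line,
  fitted to pooled wells.
- The static and dynamic branches share data structures but are estimated
  independently; agreement between their ψ estimates is an empirical
  observation, not a constraint.
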