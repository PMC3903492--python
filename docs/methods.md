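# Methods

This note documents the models, conventions and numerical choices behind
`sc2flux`, and what the synthetic-data generators do and do not emulate.

## Interval rate coefficients

An uptake assay samples intracellular lignan concentration U(t) (µM) at
incubation times t ∈ {0, 5, 15, 30, 60, 90, 120} min with the cells in a
medium of known initial total lignan concentration C₀ (default 100 µM).
The kinetic summary is per-interval, not a global fit: for each
consecutive pair of samples,

    k₁(tᵢ) = (Uᵢ − Uᵢ₋₁) / ((tᵢ − tᵢ₋₁) · C₀)     [min⁻¹]

the mean uptake rate over the interval normalised by C₀.  Positive
entries describe the uptake phase, negative entries the post-peak
intracellular decay phase.  The coefficient for (tᵢ₋₁, tᵢ] is reported
at tᵢ.  This discretisation is the one that reproduces the published
reference coefficients for the free schisandrin B series at printed
precision, and it is the package default.  Points flagged as
back-extrapolated (t = 0, 90, 120 min in the reference series) are used
like measured points, since the reference coefficients at 90 and 120 min
are themselves computed from them.

With the peptidoglycan carrier present at dose S the uptake is treated
as second order (first order in lignan and in carrier), and

    k₂(tᵢ) = k₁(tᵢ) / S_nM     [L·mmol⁻¹·min⁻¹]

where S_nM is the carrier dose expressed in nM (S_mM × 10⁶).  The
carrier dose is conventionally quoted in mM (1 mg/mL of the 841-kDa
carrier = 1.1891×10⁻³ mM), but the published second-order column is
numerically consistent only with the nM reading; `sc2flux` adopts that
unit reconciliation and documents it rather than silently renormalising.
Recomputed k₂ values for the later intervals differ from the published
ones by 1–5%, a pattern consistent with the original column having been
computed from unrounded uptake values; no claim is pinned to those rows.

`simulate_uptake_curve` provides the forward direction: extracellular
decay dC/dt = −k·C (order 1) or −k·S·C (order 2, constant S, which
reduces exactly to order 1 with k′ = k·S), uptake U = U₀ + (C₀ − C),
optional first-order intracellular elimination.  The closed-form
solution is evaluated directly, so noiseless simulation is exact; tests
verify agreement with an independent dense ODE integration to 10⁻⁹ µM.

## Dose-response statistics

Viability curves (% of untreated control vs dose in mM) are summarised
by two statistics.

**IC50.**  Default estimator: least-squares four-parameter logistic
v(d) = bottom + (top − bottom)/(1 + (d/IC50)^h), with the IC50 the
inflection dose; bounds keep the asymptotes in [−50, 500]% and the Hill
slope in [0.05, 20].  If the optimiser fails, the estimator falls back
to piecewise-linear interpolation to the 50% crossing in log-dose
(linear dose available, and forced when a zero dose is present).
A curve that never crosses 50% raises unless extrapolation from the
terminal segment is explicitly allowed, and the result then carries an
`extrapolated` flag.  Confidence intervals come from a seeded
parametric bootstrap over replicate noise (default 1000 resamples,
percentile 2.5/97.5), using recorded per-point SDs where present and
the RMS fit residual otherwise.

**Killing capability.**  Defined as cells killed per mM: the OLS slope
of killed(d) = (1 − v(d)/100) × seeded cells against dose, over the
points inside a *declared* linearity range, interpreted as the half-open
interval (lo, hi].  The seeded count defaults to 2×10⁵ (10⁵ cells/mL in
2 mL).  Low-dose proliferative points (v > 100%, observed below
~0.16 mM) contribute negative killed counts and are excluded by
declaring a range that starts above them; the range is always
user-declared because the linearity window is a property of the assay,
not of the estimator.

`compare_pd` reports ΔIC50 (free − combined), the killing-capability
fold change, and a direction label (enhanced / attenuated / unchanged)
decided on the IC50 with a 1% relative tolerance.

## Transport free-energy ledger

The carrier-assisted transport path is resolved into four steps:
(1) carrier + outer membrane → membrane-bound complex, (2) complex +
extracellular lignan → loaded complex, (3) translocation of the lignan
pool from the outer-membrane side (C_om) to the inner-membrane peak
concentration (C_mA′ ≈ C_mA), (4) irreversible intracellular
degradation down to the residual C_mE.  A `TransportState` snapshot
holds the species concentrations in molar units; constructing one
enforces the mass balance C_om + C_mA′ = C₀ to 10⁻⁹.

Each step's pseudo-equilibrium constant is a mass-action quotient over
configured numerator/denominator species; the configuration is data,
not code, because the algebra that originally defined the constants was
published only through its outputs.  Defaults:

| step | quotient | degenerate limit |
|---|---|---|
| 1 | [carrier·membrane complex]/[free carrier] (the membrane pool, in vast excess, is the constant K folded in: K_eq′ = K_eq·K) | free carrier → 0 ⇒ +∞ |
| 2 | [loaded complex]/([complex]·[free lignan]) | finite |
| 3 | C_mA′/C_om | finite |
| 4 | (Ls_in − C_mE)/reverse pool, the reverse pool identically 0 (irreversibility) | +∞ (−∞ if the "degraded" difference is negative) |

Finite published constants for steps 2–3 can be injected as overrides
(`datasets.table6_keq_overrides()`), which is how the published ledger
is reproduced.

**Free-energy conventions.**  The standard convention is
ΔG = −RT·ln K_eq (mode `"ln"`, the default; R = 8.314 J K⁻¹ mol⁻¹,
T = 310 K), with K_eq = +∞ ⇒ ΔG = −∞ and K_eq → 0⁺ ⇒ +∞, and a domain
error for negative K_eq.  The reproduction mode `"table6"` computes
ΔG = −RT·K_eq — a product, not a logarithm.  It exists because the
published ledger's numbers follow that form (−8.314·310·0.9980 =
−2572 J matches the printed −2.572 kJ, the ln form does not) and
because its printed step-3 constant is negative, which no logarithmic
convention admits.  The package implements both honestly instead of
endorsing either: physical analyses should use `"ln"`; `"table6"`
exists to reproduce the published table.  The published step-3 value
(+0.059 kJ) is not reproducible from its printed constant under either
mode (product form gives +0.0487 kJ); nothing is asserted against it.

**Extended reals.**  ±∞ constants and free energies are explicit ledger
states, never floating-point overflow.  The overall path free energy is
an absorbing-infinity sum: any −∞ term (with no +∞ present) makes the
path −∞; a ledger containing both +∞ and −∞ raises an indeterminacy
error rather than returning a number.  The central qualitative result —
complete carrier binding (step 1) and irreversible degradation (step 4)
drive the overall free energy to −∞ regardless of the finite middle
steps, i.e. the membrane-bound carrier acts as a one-way catcher–pitcher
pump — is a theorem of this arithmetic and is tested as such.

**Dose bookkeeping.**  mg/mL ÷ kDa = mM; carrier coverage per cell =
(concentration × volume ÷ molar mass) / cell count, in fmol; particles
per cell = fmol × 10⁻¹⁵ × N_A (6.02×10²³).  All three are linear and
tested for linearity.

## Synthetic-data generators

`gen_uptake` draws from a two-pool scheme with an
instantaneous-adsorption offset: U₀ (default 47 µM, the observed t = 0
uptake) is adsorbed immediately and the remaining extracellular source
C₀ − U₀ transfers at rate k (first-order flavour, default 0.01 min⁻¹)
or at constant rate r (zero-order flavour, for exact estimator-recovery
tests), while the intracellular pool decays at k_e (default
0.005 min⁻¹).  Starting the source at C₀ − U₀ keeps uptake ≤ C₀, which
the naive offset scheme would violate.  Noise is additive Gaussian, SD
3 µM by default (the middle of the 2–5 µM replicate scatter), and the
defaults produce the assay's qualitative shape: nonzero uptake at
t → 0, rise to an interior plateau, late decline.

`gen_dose_response` draws from the descending 4PL (defaults: top 100%,
bottom 0%, Hill 1.5, noise SD 5%) over a two-fold dose series
0.02–2.56 mM, with an optional hormesis bump a·x·e^(1−x),
x = d/0.08 mM, which peaks inside the <0.16 mM proliferative window and
vanishes at dose 0 so the control stays at the top asymptote.

What the generators do *not* emulate: correlated replicate errors,
heteroscedasticity beyond the per-point SDs, plate or edge effects,
compound degradation over incubation, and any mechanistic link between
the uptake and viability models.  Passing recovery tests therefore
demonstrate estimator correctness under idealised noise, not robustness
to real assay artefacts.

## Numerical choices and problem sizes

* Interval coefficients are exact arithmetic; no tolerance applies.
* 4PL fitting: `scipy.optimize.curve_fit` (bounded trust-region), with
  data-driven initial values; interpolation fallback on non-convergence.
* Peak detection breaks ties toward the earliest time (first argmax).
* Recovery experiments in the test suite use 100–200 seeded
  realizations, enough to stabilise a median to well under the 5–10%
  test tolerances while keeping the whole suite a few seconds long.
* Mass-balance construction tolerance 10⁻⁹ (absolute, molar);
  closed-form-vs-ODE agreement asserted at 10⁻⁹ µM (forward simulator)
  and 10⁻⁶ µM (generator vs dense grid).

## Known limitations

* The per-interval coefficient convention is a reconstruction; a
  log-ratio (exponential-decay) convention would give different numbers
  and is not the default because it does not reproduce the reference
  table.
* The second-order unit reconciliation (S in nM) reproduces the
  published column but is dimensionally idiosyncratic; both the mM dose
  and the conversion factor are explicit in the API.
* Step-quotient stoichiometries beyond the default reading are the
  user's responsibility; the ledger cannot validate a configuration
  against the unavailable defining algebra.
* The pipeline's default pharmacodynamic stage analyses one noisy
  synthetic realization per treatment; single-realization IC50
  estimates can deviate noticeably from the generating value (the
  median over many seeds is what the recovery guarantees cover).
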