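# Methods

## Model

The simulator tracks the exchangeable ("exposed") Mg(II) pool in four
compartments: serum, bone, bulk tissue (muscle and soft tissues
bundled, as their Mg concentrations are similar), and the small
tissue zone immediately surrounding the implant(s).  Bound
("unexposed") Mg that cannot exchange between compartments is not
tracked explicitly; it is absorbed into the effective volumes through
the equilibrium ratio constants ξ₁ (serum), ξ₂ (red blood cells,
which equilibrate with serum within minutes and are therefore slaved
to it) and ξ₃ (tissue), and through the exposed-bone volume fraction
ϕ.  All transport is passive and linear: first-order exchange between
serum and bone (μ₁, μ₋₁) and serum and tissue (k₁, k₋₁), first-order
urinary excretion (γCₛ), constant dietary input φ_D and constant
implant release σ.  The resulting system is affine, dC/dt = AC + b,
with A having compartmental sign structure (Metzler matrix), so
trajectories started from nonnegative states stay nonnegative and
converge to C∞ = −A⁻¹b.

Key structural assumptions:

- **Constant release rate σ.**  Real implants corrode unevenly
  (coatings, pitting, corrosion-layer formation); σ(t) and
  implant-mass coupling are out of scope.
- **No active regulation.**  Hormonal control of renal resorption and
  bone exchange is not modelled; excretion responds only linearly to
  serum level.  Predictions are therefore worst-case for healthy
  patients and most representative for patients with impaired
  regulation (chronic kidney disease).
- **Non-overlapping implant zones.**  n implants scale as σ = nσ₀,
  V_I = nV_I0, ξ = nξ₀ with ξ₀ = V_I0/V_T_tot; validity requires
  ξ < 1 (in practice screws spaced more than ~6–8 mm apart).
- **Tissue bookkeeping.**  The bulk-tissue equation uses
  V_T = (1−ξ)V_T_tot, i.e. tissue excluding the implant zones, so
  total tissue volume is conserved.  For every clinically relevant
  case (ξ ≤ 0.023) the distinction changes nothing visible; it is a
  documented convention, not a prediction driver.
- **Normalization.**  Concentrations are reported relative to the
  pre-implant equilibrium; the implant zone, which has no pre-implant
  equilibrium of its own, is normalized by the tissue reference C̄_Tᵉ.

## Parameters

Healthy-adult defaults (days / litres / mmol): volumes Vₛ = 3,
V_r = 2, V_N = 12.3, V_T_tot = 52.7 L; intake φ_D = 6 mmol/day;
excretion γ = 10.9 L/day; exchange μ₁ = 6.05, μ₋₁ = 0.0775, k₁ = 138,
k₋₁ = 34.7 L/day; ϕ = 0.3; ξ₁ = 0.538, ξ₂ = 0.452, ξ₃ = 3.0; clinical
total-serum levels C_hom = 0.85, C_hyp = 1.05, C_sev = 2.9 mmol/L.
Per-implant defaults σ₀ = 0.05 mmol/day and V_I0 = 0.00527 L
represent a 3.2 × 32 mm screw; both vary with alloy, geometry and
site and are overridable.  The homeostatic serum level is always
computed as φ_D/γ = 0.5505 mmol/L; published reference tables print
0.553 because their inputs carry more digits than their rounded
φ_D and γ, so comparisons against printed equilibrium values are made
at 1% relative tolerance.

Interventions: reduced kidney function scales γ by a fraction
γ/γ₀ ∈ (0, 1] **with φ_D covarying** so the patient still starts at
homeostasis (φ_D/γ unchanged) — this is why, counterintuitively, the
steady-state normalized rise 1 + σ/φ_D grows as kidney function
falls.  Dietary control scales intake by ρ ∈ [0, 1];
ρ = 1 − σ/φ_D restores long-run homeostasis and
ρ = C_hyp* − σ/φ_D is the laxest intake that avoids hypermagnesemia
(negative values are flagged infeasible rather than clamped
silently).  The dimensionless kidney parameter Γ = γ/k₁ (healthy
Γ₀ ≈ 0.079) is exposed read-only to avoid inconsistent
parameterizations.

## Derived formulas and their status

The exponential approximations hold for ξ ≪ 1 (a warning is issued
above ξ = 0.05).  Against the full ODE over three years the systemic
components agree to 0.02% (ξ = 10⁻⁴) and 0.3% (ξ = 10⁻³).  Several
derived expressions are ratio products; the adopted readings, fixed
by dimensional analysis and the reference values they reproduce, are
σ/((1−ξ)φ_D) for the systemic rise, (σγ/(k₁φ_D))·(V_T/V_I) for the
local implant-zone excess, σγ/(ξk₁φ_D) for its steady-state form, and
1 + (ρ−1)·γ/k₁ for the intake-reduction serum minimum.

Two quantitative caveats discovered in validation, both documented in
the tests:

- **T_Mg is a capacity estimate, not the exact slowest eigenmode.**
  The slowest eigenvalue of A corresponds to a 124-day time constant
  versus T_Mg = 103.8 days, so the serum gap to steady state at
  5·T_Mg is ~1.3% of the total rise, dropping below 1% between 5 and
  6 buildup times.  The numerically measured 63.2%-rise time still
  matches T_Mg within 5% (faster modes carry part of the amplitude),
  and T_Mg is confirmed independent of σ.
- **The intake-reduction minimum formula describes the early dip.**
  1 + (ρ−1)γ/k₁ is the quasi-plateau the serum falls to within days
  of an intake cut, sustained by tissue and bone reserves.  It is the
  global trajectory minimum exactly when the long-run level
  ρ + σ/φ_D lies above it (then the numeric minimum matches the
  formula to ~0.1%); otherwise the serum continues past the dip
  toward the lower steady state on the T_Mg scale, as in the
  zero-intake member of the diet-control preset (long-run level 0.5).
  At ρ = 0 with healthy parameters the formula gives a 7.9% (~8%)
  maximum drop, above the hypomagnesemia band.

The hypermagnesemia onset formula T_Mg ln(σ/(σ−σ_hyp)) agrees with
the numeric first crossing within 10% over σ = 2–5 mmol/day (measured
3–9%).  The minimum implant count is found by direct integer scan of
the exact steady state 1 + nσ₀/φ_D against C_hyp* (29 at defaults).

## Numerics

- **Integration:** `scipy.integrate.solve_ivp` with LSODA (the system
  is mildly stiff: time constants 0.035, 6, 33, 124 days),
  rtol = 10⁻¹⁰, atol = 10⁻¹², analytic Jacobian.  The tolerances sit
  well below the 10⁻⁶ oracle-agreement requirement because the
  conservation diagnostic differentiates the sampled trajectory and
  would otherwise amplify solver interpolation noise.
- **Oracle:** the matrix-exponential solution via
  `scipy.linalg.expm`; numeric and closed form agree to ~10⁻⁹
  relative on all presets.
- **Default grid:** 200 points, t = 0 plus log-spaced 10⁻³–1095 days.
  The early start resolves the fast serum relaxation (~0.04 days)
  excited when the intake factor switches at t = 0.
- **Conservation diagnostic:** the total exposed mass ΣW_jC_j is
  differentiated with a quintic interpolating spline (cubic below six
  samples) and compared against ρφ_D + σ − γCₛ; the worst scaled
  residual across presets is ~4 × 10⁻⁷ of the total source, against a
  contract of 10⁻⁶.  Second-order differences on the log grid would
  exceed the contract purely through truncation error.
- **Degenerate inputs:** σ ≤ σ_hyp yields a "never reached" onset
  (`None` in the API, NaN in sweep tables); ξ ≥ 1 (overlapping
  zones), nonpositive volumes/rates and inverted clinical thresholds
  are rejected with the violated invariant named.  Time grids must be
  strictly increasing from 0.

## Scenarios

Preset runs: `standard` (one screw), `multi_implant`
(n ∈ {1, 5, 10, 20, 29, 50}, bracketing the threshold count),
`plate` (σ = 10 mmol/day into V_I = 1.2 L, ξ ≈ 0.023 — the
human-scaled analogue of a subcutaneous-plate animal experiment) and
`diet_control` (γ = γ₀/3, n = 20, ρ ∈ {1, 0.833, 0.5, 0}; 0.833 is
the homeostasis factor at healthy intake, 0.5 the value highlighted
for the renal-adjusted case).  The n and ρ lists are package choices
bracketing the documented thresholds, overridable by the caller.
"Long run" is operationalized as three years (settling takes 2–3
years in all cases).  Sweeps default to Γ ∈ [Γ₀/6, 2Γ₀] (25 points,
log-spaced) and σ ∈ [0.05, 5] mmol/day (100 points, i.e. 1–100 screw
equivalents); both grids are user parameters.

## What the tests do and do not show

All quantitative checks run against the model's own reference
parameterization: they demonstrate internal consistency (solver vs
closed form, conservation, formula-vs-ODE agreement) and faithful
reproduction of the derived quantities, **not** clinical validity.
The parameter set is a population-average healthy adult; patient
variation (body size, age, osteoporosis, actual GFR-to-γ mapping) and
active Mg regulation are outside the model, and there is no long-term
human serum-monitoring dataset against which the trajectories could
be validated.  Predictions are best read as worst-case bounds for
healthy patients and first-order estimates for renally impaired
ones.
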