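# Methods

## Scope and data model

The package correlates equilibrium mole-fraction solubility y₂ of a solid
solute in supercritical CO2 against temperature T (K), pressure P (MPa at
the data boundary) and solvent density ρ₁ (kg/m³).  A dataset is an ordered
set of `(T, P, ρ₁, y₂[, S, sd])` records, unique on (T, P); solubility can
equivalently be carried as the mass concentration S (g per litre of
solvent), related by

    S = ρ₁ (M₂/M₁) y₂/(1 − y₂)

with M₂, M₁ the solute and solvent molecular weights.  The bundled
empagliflozin dataset (24 points, four isotherms 308–338 K at six pressures
12–27 MPa, NIST CO2 densities) ships as packaged CSV/YAML together with the
solute property record: M₂ = 450.9 g/mol, Tm = 426.1 K,
ΔHᵐ = 60 238 J/mol, Tc = 870.367 K, Pc = 18.7565 bar (the property table
prints "Pa" but the CO2 row value 73.8 makes bar unambiguous), ω = 0.479,
solid molar volume Vs = 184.397×10⁻⁶ m³/mol, Wilson-model molar volume
V₂ = 3.2699×10⁻⁴ m³/mol, and sublimation pressures
{308: 0.0034, 318: 0.0089, 328: 0.022, 338: 0.0508} Pa.  Two distinct
molar volumes are deliberately kept: the solid volume enters the EoS
Poynting correction, the larger value the Wilson activity model; the source
tables give both and each is used where its model uses it.

Sublimation pressure between tabulated temperatures is interpolated as
ln P linear in 1/T (Clausius–Clapeyron); extrapolation outside 308–338 K is
refused because only that range is certified.

R = 8.314 J/(mol·K) throughout; it reproduces the enthalpy arithmetic of
the source correlation tables to the printed digit.

## Density-based models

Eleven standard correlations are registered behind one interface
`evaluate(params, T, P, rho1, solute, solvent) → y2`.  Unit conventions
(each was validated by checking that published constants for the bundled
dataset reproduce the measured magnitudes):

| model | form (y₂ unless noted) | convention |
|---|---|---|
| Chrastil | g/(1+g), g = ρ₁^(κ−1) e^(A+B/T) | fitted in mole-fraction form |
| Reformulated Chrastil | (RTρ₁/(M_CF f°))^(κ′−1) e^(A+B/T) | M_CF = 44.01, f° = 1 (A absorbs the reference constants; AARD and B are convention-independent) |
| Bartle | (Pref/P) e^(A+B/T+C(ρ₁−ρref)) | Pref = 0.1 MPa, ρref = 700 kg/m³ |
| Bian | ρ₁^(A+Bρ₁) e^(C/T+Dρ₁/T+E) | ρ₁ in kg/m³ |
| Kumar–Johnstone | ln y₂ = A + Bρ₁ + C/T | fit-only (published constants corrupted) |
| Méndez-Santiago–Teja | T ln(y₂P) = A + Bρ₁ + CT | P in bar |
| Garlapati–Madras | ln y₂ = A + (B+Cρ₁)ln ρ₁ + D/T + E ln(ρ₁T) | fit-only |
| Alwi–Garlapati | e^(A+B/Tr+Cρr)/(ρrTr) | Tr = T/304.18 K, ρr = ρ₁/467.6 kg/m³ |
| Mahesh–Garlapati | ln y₂ = A + BρrTr + CρrTr³ | reduced state as above |
| Sodeifian | 6-term ln y₂ expansion | fit-only |
| Tippana–Garlapati | (A+BPr+CPr²)Tr² + (D+EPr+FPr²) | Pr = P/7.38 MPa |

CO2 reducing constants: Tc = 304.18 K and ρc = 467.6 kg/m³ (the standard
reference critical density; needed wherever ρr appears).

Three published constant sets (Kumar–Johnstone, Garlapati–Madras,
Sodeifian) and the Tippana–Garlapati set do not reproduce their published
AARD under any unit convention tried (kg/m³, g/cm³, mol/L; for
Tippana–Garlapati the constants match only a Tr¹ variant of the printed Tr²
form).  These models are therefore exercised by refitting only; the other
seven reproduce their published AARD within 1.5 percentage points, which is
the evaluation test the suite runs.

## SLE–Wilson model

Solid–liquid equilibrium with the supercritical phase treated as an
expanded liquid:

    y₂ = exp[(ΔHᵐ/(RT))(T/Tm − 1)] / γ₂^∞

The heat-capacity contribution to the fugacity ratio is omitted (it is much
smaller than the melting-enthalpy term and its retention is not supported by
the available property data).  The Wilson infinite-dilution activity
coefficient, with 1/V₁ identified with the solvent density, is

    γ₂^∞ = exp[1 + ln(ρ₁V₂) + a₁₂/(RT) − ρ₁V₂ exp(−a₂₁/(RT))]

with density-power-law energy parameters a₁₂ = A ρr^B, a₂₁ = C ρr^D — four
temperature-independent fitted constants.  Note the explicit model is
implemented with A·ρr^B in the additive position and C·ρr^D inside the
exponential, exactly as the published explicit form places them (the
published intermediate equations place them the other way around; the swap
is a pure relabeling of fitted constants and the explicit form is what the
published constants belong to).

**Density product convention.** ρ₁V₂ is evaluated as the numeric product of
the density in kg/m³ with V₂ = 3.2699×10⁻⁴, giving values of order 0.1–0.3
on the bundled data.  Dimensionally this is a mass-basis volume fraction,
not the molar product ρ₁V₂/M₁ (which would be ≈ 5.7 at 308 K/769 kg/m³ and
drives γ^∞ → 0, i.e. nonsense).  It is the only convention under which the
published four constants reproduce the measured solubilities, so it is the
default ("paper" convention); the strict molar convention is available as
`convention="molar"` and requires refitting.

## RK EoS with Kwak–Mansoori mixing rules

Classic Redlich–Kwong pressure form with Ωa = 0.42748, Ωb = 0.08664:

    P = RT/(v−b) − a/(√T v(v+b)),  a = Ωa R²Tc^2.5/Pc,  b = Ωb RTc/Pc

Kwak–Mansoori mixture parameters

    α = ΣΣ xᵢxⱼ aᵢⱼ^{2/3} bᵢⱼ^{1/3},  b = ΣΣ xᵢxⱼ bᵢⱼ,  a = α^{3/2}/b^{1/2}

with aᵢⱼ = (1−kᵢⱼ)√(aᵢᵢaⱼⱼ) and bᵢⱼ = (1−lᵢⱼ)(bᵢᵢ^{1/3}+bⱼⱼ^{1/3})³/8.
(The denominator of the mixture-a rule is sometimes typeset with stray
exponents; the form above is the one that reduces to the pure parameters at
x = (1,0), which is non-negotiable.)  The component fugacity coefficient is
derived analytically from the residual-volume integral

    ln φ̂ᵢ = (1/RT)∫_v^∞ [(∂P/∂Nᵢ)_{T,V,Nⱼ} − RT/v] dv − ln Z

rather than transcribed from a closed form, because printed versions of that
closed form are typographically unreliable.  The derivation gives

    ln φ̂ᵢ = ln(v/(v−b)) + b̄ᵢ/(v−b) − ln Z
             − āᵢ/(RT^{3/2}b) ln(1+b/v)
             + a b̄ᵢ/(RT^{3/2}) [ln(1+b/v)/b² − 1/(b(v+b))]

with partial-molar combinations b̄ᵢ = 2Σⱼxⱼbᵢⱼ − b and
āᵢ = 3√α(Σⱼxⱼqᵢⱼ)/√b − α^{3/2}(Σⱼxⱼbᵢⱼ)/b^{3/2}, qᵢⱼ = aᵢⱼ^{2/3}bᵢⱼ^{1/3}.
A numerical oracle (central-difference ∂P/∂Nᵢ fed into adaptive quadrature
of the integral) is the arbiter in the test suite; agreement is ~2×10⁻⁸
relative over the working grid, and the pure limit collapses to the
standard pure-RK fugacity coefficient to machine precision.

Solid solubility solves y₂ = (Pˢᵘᵇ/(Pφ̂₂)) exp[(P−Pˢᵘᵇ)Vs/(RT)] with the
solid-phase fugacity coefficient set to one.  Pressures are in Pa inside
the EoS; dataset MPa are converted at the interface.

## Fitting and statistics

* Objective: OF = Σ|y₂ᵉˣᵖ−y₂ᶜᵃˡᶜ|/y₂ᵉˣᵖ; AARD% = 100·OF/N.  Parameter
  vectors that produce non-finite or out-of-(0,1) solubilities receive a
  finite penalty of 10⁶ so the simplex search remains well defined; model
  evaluation itself never clips.
* Optimizer: Nelder–Mead (the direct-search analogue of the original
  fminsearch regressions), 100 starts by default, fixed seed 42.  Models
  that are linear in their parameters after a log transform contribute an
  ordinary-least-squares "smart start"; the remaining starts are a seeded
  Latin-hypercube sample, over explicit boxes for the SLE–Wilson constants
  (energies 10³–10⁵ J/mol, exponents in (−0.9, 0.9)) and the interaction
  constants (|k|, |l| < 0.9), or over a box of halfwidth 1+|θ₀| around the
  linearized solution otherwise.  The best few basins are polished by
  restarted Nelder–Mead (restarting a collapsed simplex at its own optimum
  reliably tightens it).  Tolerances 10⁻¹² on the objective and 10⁻¹⁰ on
  parameters.  Everything is deterministic given the seed; the suite
  checks bit-reproducibility.
* Statistics, all on the mole-fraction scale: SSE, RMSE = √(SSE/N),
  R² = 1 − SSE/SST (SST about the experimental mean; the source tables do
  not define R², this is the usual choice), adjusted
  R² = 1 − (1−R²)(N−1)/(N−Q−1), AIC = N ln(SSE/N) + 2Q and
  AICc = AIC + 2Q(Q+1)/(N−Q−1), undefined (error) for N ≤ Q+1.  These
  definitions reproduce the published statistic rows exactly (e.g.
  SSE = 4.635×10⁻¹¹, N = 24, Q = 4 → AIC = −639.35, AICc = −637.24).
* Ranking: ascending AICc, ties broken by AARD then by parameter count.

## Derived analyses

* **Enthalpies.** ΔH = −B·R from the temperature coefficient B of a
  Chrastil-type model (total enthalpy) and of the Bartle model (sublimation
  enthalpy); solvation enthalpy is their difference, an identity asserted in
  the report object.  Reported in kJ/mol.
* **Crossover pressure.** For a fitted model, the two isotherm curves
  y₂(T, P, ρ(P)) are built with the isotherm densities cubically
  interpolated from the measured (P, ρ) pairs, and the intersection is
  bisected to better than 0.01 MPa; no sign change raises a "no crossover"
  error.  A model-free variant intersects cubic splines through the measured
  y₂(P) isotherms themselves — this is the observable that corresponds to
  reading a crossover region off a solubility plot, and on the bundled data
  it gives 15.95 MPa while fitted-model crossings range over roughly
  14.3–15.7 MPa depending on the model (the two extreme measured isotherms
  cross between 15 and 18 MPa; the exact location is poorly conditioned
  because the curves intersect at a shallow angle).  The CLI reports both.
* **MT self-consistency.** Ordinary least squares of T ln(y₂P) on ρ₁ and T
  (pressure in bar); the R² of that collapse measures how well the data obey
  the Méndez-Santiago–Teja form.  With fewer than four points the fit is
  exact and flagged underdetermined.

## Synthetic data

`generate_synthetic` evaluates any registered model at given conditions and
applies multiplicative lognormal noise, y₂ → y₂·exp(ε), ε ~ N(0, cv):
solubility is strictly positive and residuals in this field are judged in
relative terms, so relative noise is the natural corruption.  Default
conditions in the tests are the bundled 24-point grid; noise levels of
0 and 5% are used for recovery experiments (5% is a typical experimental
relative standard deviation for this kind of measurement; the bundled
dataset's own sd/y₂ ratios are 1–5%).  The generator emulates a correlation
surface plus homoscedastic relative noise; it does not emulate isotherm-
correlated errors, density uncertainty, or the heteroscedasticity of real
UV quantification, so a green recovery test establishes optimizer and
implementation correctness, not robustness to structured experimental
error.

## Numerical choices

* Cubic volume roots by the Cardano/trigonometric closed form followed by
  two Newton polish steps (validated against `np.roots` on random and
  physical coefficients); the largest real root above the covolume is the
  supercritical/vapour branch used throughout, matching a single-phase
  ScCO2 system.
* The solubility fixed point y ← Pˢᵘᵇ/(Pφ̂₂(y))·Poynting starts at
  y = Pˢᵘᵇ/P and iterates undamped — the map is almost constant in y at
  y ≪ 1 so this converges in a handful of steps — with the step damping
  halved adaptively if an iteration fails to contract; tolerance 10⁻¹⁰
  relative, 200 iterations maximum, non-convergence raises.
* Scalar activity-coefficient evaluation raises `OverflowError` on exponent
  overflow instead of returning inf; the vectorized fitting path lets
  non-finite values flow to the objective penalty instead.

## Known limitations

* Single binary system data ships with the package; nothing prevents use
  with other solutes, but the property loader expects the same YAML schema
  and sublimation pressures are required for the EoS route.
* The published constants of four density models are corrupted in the
  source tables (see above); their printed-parameter behaviour cannot be
  reproduced, only their refits.
* The bundled table itself carries two internal inconsistencies that the
  test suite documents rather than hides: one printed S value (318 K,
  24 MPa) disagrees with its own printed y₂ by 1.8%, and the best
  published Bian AARD (5.1%) is below the global optimum of that model
  form on the printed data (≈6.24% by exhaustive global search).
* No weighting, no bootstrap uncertainty, no cross-validation: the
  regression reproduces the unweighted relative-deviation methodology of
  the source correlations.
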