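# sco2sol

Correlation of solid-solute solubility in supercritical CO2 (ScCO2).

Solubility of a crystalline drug in ScCO2 is the basic design quantity for
supercritical processing (particle micronization, extraction, impregnation).
Measuring it at every condition is expensive, so practice relies on
semi-empirical correlations fitted to a handful of isotherms.  `sco2sol` is
a small toolkit for exactly that workflow: it bundles a measured
empagliflozin dataset (24 points, 308–338 K, 12–27 MPa), implements the
standard battery of density-based models plus two thermodynamic ones, fits
them by multistart direct search, and ranks them with small-sample
information criteria.

## Models

**Eleven density-based models** (Chrastil, reformulated Chrastil, Bartle,
Bian, Kumar–Johnstone, Méndez-Santiago–Teja, Garlapati–Madras,
Alwi–Garlapati, Mahesh–Garlapati, Sodeifian, Tippana–Garlapati), all of the
form y₂ = f(T, P, ρ₁; θ) with 3–6 fitted constants θ and the CO2 density
ρ₁ in kg/m³.  For example Chrastil, in mole-fraction form:

    y₂ = g/(1+g),   g = ρ₁^(κ−1) · exp(A + B/T)

where κ is the solvent association number and −B·R the total enthalpy.

**An explicit solid–liquid-equilibrium (SLE) model** treating the
supercritical phase as an expanded liquid: y₂ = (f₂ˢ/f₂ᴸ)/γ₂^∞ with

    f₂ˢ/f₂ᴸ = exp[(ΔH₂ᵐ/RT)(T/Tm − 1)]
    γ₂^∞   = exp[1 + ln(ρ₁V₂) + A·ρr^B/(RT) − ρ₁V₂·exp(−C·ρr^D/(RT))]

a Wilson activity coefficient at infinite dilution whose two energy
parameters are power laws of the reduced solvent density ρr = ρ₁/ρc.  Four
temperature-independent constants A, B, C, D.

**A Redlich–Kwong equation of state with Kwak–Mansoori mixing rules**: the
solute fugacity coefficient φ̂₂ comes from the residual-volume integral of
the RK pressure form, and solubility solves the equifugacity condition

    y₂ = (P₂ˢᵘᵇ / (P·φ̂₂)) · exp[(P − P₂ˢᵘᵇ)·Vs/(RT)]

with two fitted binary interaction constants k₁₂ (energy) and l₁₂ (size).

All models are fitted by minimizing the relative objective
OF = Σ|y₂ᵉˣᵖ − y₂ᶜᵃˡᶜ|/y₂ᵉˣᵖ (AARD% = 100·OF/N) with 100 seeded
Latin-hypercube Nelder–Mead starts, and compared by
AICc = N·ln(SSE/N) + 2Q + 2Q(Q+1)/(N−Q−1).

## Worked example

```sh
$ sco2sol fit --model sle_wilson --quiet
     model                                           params  AARD%    R2  R2_adj  SSE*1e11  RMSE*1e6  N  Q     AIC    AICc
sle_wilson A=36116.3; B=-0.0867443; C=-9584.78; D=-0.156267   6.75 0.944   0.933     4.886     1.427 24  4 -638.08 -635.98
```

The four-constant SLE–Wilson model correlates the 24 bundled empagliflozin
points to 6.75% average absolute relative deviation; the positive A and
negative C are the density-scaled solute–solvent interaction energies, and
AICc ≈ −636 puts it among the best models of the battery despite the extra
parameter.

```sh
$ sco2sol analyze --quiet
dH_total =   27.571 kJ/mol  (Chrastil temperature coefficient)
dH_sub   =   49.455 kJ/mol  (Bartle temperature coefficient)
dH_solv  =  -21.884 kJ/mol  (difference dH_total - dH_sub)
crossover (bian fit): 14.33 MPa
crossover (measured isotherms): 15.95 MPa
MT self-consistency: T ln(y2 P) = -7778 + 2.358*rho + 12.7*T  (R2 = 0.9712)
```

The Chrastil temperature coefficient gives the total (solvation +
sublimation) enthalpy, the Bartle coefficient the sublimation enthalpy, and
their difference the (exothermic) solvation enthalpy.  The crossover
pressure — below which solubility falls with temperature (density effect)
and above which it rises (vapour-pressure effect) — is reported both from a
fitted model and directly from splines through the measured isotherms.  The
Méndez-Santiago–Teja (MT) collapse of T·ln(y₂P) against density is the
standard self-consistency check on the data (R² ≈ 0.97 here).

Other verbs: `compare` (fit and rank the full 13-model battery), `predict`
(evaluate a model at arbitrary state points, optionally as g/L), `simulate`
(noisy synthetic datasets for recovery studies), `convert` (fill in the
y₂ ↔ S columns of a CSV).  Use the library directly for anything finer:

```python
import sco2sol as sc
dataset, solute, solvent = sc.empagliflozin_fixture()
result = sc.fit("chrastil", dataset, solute, solvent)
print(result.aard_pct, dict(zip(result.param_names, result.params)))
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
refits the SLE–Wilson, Bian and RK+KM models to the bundled dataset from
scratch (multistart Nelder–Mead with the given seed) and locates the
crossover pressure of the fitted Bian isotherms, writing the measured
AARD% values and the crossover pressure (MPa) as JSON.
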