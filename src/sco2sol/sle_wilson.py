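"""Explicit solubility model from solid-liquid equilibrium plus a Wilson
activity coefficient at infinite dilution.

The supercritical phase is treated as an expanded liquid.  Solubility is the
ratio of the solid/liquid fugacity ratio of the pure solute to its activity
coefficient at infinite dilution:

    y2 = exp[(dHm/(R T))(T/Tm - 1)] / gamma2_inf

The fugacity ratio keeps only the melting-enthalpy term (the heat-capacity
correction is much smaller and is omitted).  gamma2_inf comes from the Wilson
local-composition model in the infinite-dilution limit, with the two energy
parameters taken as power laws of the reduced solvent density:

    a12 = A * rho_r**B,   a21 = C * rho_r**D

    gamma2_inf = exp[1 + ln(rho1*V2) + A*rho_r**B/(R T)
                     - rho1*V2*exp(-C*rho_r**D/(R T))]

giving four temperature-independent adjustable constants A, B, C, D.

The dimensionless product ``rho1*V2`` is evaluated, by default, as the
numeric product of the density in kg/m^3 and V2 = 3.2699e-4 ("paper"
convention: effectively a mass-basis volume fraction).  Under the strict
molar convention (rho1/M1 * V2, "molar") the same functional form applies
but the constants must be refit; both conventions are exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import R_GAS, SoluteProperties, SolventProperties, SolubilityDataset
from .density_models import ModelSpec, register

__all__ = [
    "WilsonModelParams",
    "fugacity_ratio",
    "gamma_infinity",
    "predict_y2",
    "fit_new_model",
]

#: maximum |exponent| accepted before the scalar API raises instead of
#: returning inf (vectorized fitting paths let inf flow to the penalty).
_EXP_LIMIT = 700.0


@dataclass(frozen=True)
class WilsonModelParams:
    """The four adjustable constants of the model.

    A and C are energy-like (J/mol scale); B and D are dimensionless
    reduced-density exponents, typically in (-1, 1) when fitted.
    """

    A: float
    B: float
    C: float
    D: float

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D])


def _density_product(rho1, V2: float, M1_g_mol: float | None,
                     convention: str) -> np.ndarray:
    if convention == "paper":
        return np.asarray(rho1) * V2
    if convention == "molar":
        # molar density mol/m^3 = rho[kg/m^3] * 1000 / M[g/mol]
        return np.asarray(rho1) * 1000.0 / M1_g_mol * V2
    raise ValueError(f"unknown convention {convention!r}")


def fugacity_ratio(T, Tm: float, dHm: float):
    """Solid/liquid fugacity ratio exp[(dHm/(R T))(T/Tm - 1)].

    Equals 1 at the melting point (and for dHm = 0) and is <= 1 below it;
    strictly increasing in T for dHm > 0.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or Tm <= 0:
        raise ValueError("temperatures must be positive")
    out = np.exp(dHm / (R_GAS * T) * (T / Tm - 1.0))
    return float(out) if out.ndim == 0 else out


def gamma_infinity(T, rho1, rho_r, V2: float, params: WilsonModelParams,
                   M1_g_mol: float | None = None, convention: str = "paper"):
    """Wilson infinite-dilution activity coefficient with density-power-law
    energy parameters.  Raises ``OverflowError`` on exponent overflow rather
    than returning inf."""
    T = np.asarray(T, dtype=float)
    rho_r = np.asarray(rho_r, dtype=float)
    if np.any(T <= 0) or np.any(np.asarray(rho1) <= 0) or np.any(rho_r <= 0) or V2 <= 0:
        raise ValueError("T, rho1, rho_r, V2 must be positive")
    rv = _density_product(rho1, V2, M1_g_mol, convention)
    rt = R_GAS * T
    inner = -params.C * rho_r**params.D / rt
    if np.any(np.abs(inner) > _EXP_LIMIT):
        raise OverflowError("exponent overflow in Wilson a21 term")
    expo = 1.0 + np.log(rv) + params.A * rho_r**params.B / rt - rv * np.exp(inner)
    if np.any(np.abs(expo) > _EXP_LIMIT):
        raise OverflowError("exponent overflow in activity coefficient")
    out = np.exp(expo)
    return float(out) if out.ndim == 0 else out


def predict_y2(T, rho1, solute: SoluteProperties, solvent: SolventProperties,
               params: WilsonModelParams, convention: str = "paper"):
    """Mole-fraction solubility: fugacity_ratio / gamma_infinity."""
    rho_r = np.asarray(rho1, dtype=float) / solvent.rho_c
    gamma = gamma_infinity(T, rho1, rho_r, solute.V2, params,
                           M1_g_mol=solvent.M, convention=convention)
    return fugacity_ratio(T, solute.Tm, solute.dHm) / gamma


def _evaluate_vec(pvec, T, P, rho1, solute, solvent, convention="paper"):
    """Registry evaluator: no raising, invalid values flow to the objective."""
    A, B, C, D = pvec
    rho_r = rho1 / solvent.rho_c
    rv = _density_product(rho1, solute.V2, solvent.M, convention)
    rt = R_GAS * T
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        expo = 1.0 + np.log(rv) + A * rho_r**B / rt - rv * np.exp(-C * rho_r**D / rt)
        gamma = np.exp(expo)
        fug = np.exp(solute.dHm / rt * (T / solute.Tm - 1.0))
        return fug / gamma


def fit_new_model(dataset: SolubilityDataset, solute: SoluteProperties,
                  solvent: SolventProperties, convention: str = "paper",
                  **fit_options):
    """Fit A, B, C, D to a dataset by multistart Nelder-Mead on the relative
    objective.  V2 is held constant; the constants are temperature
    independent.  Returns a :class:`sco2sol.fitting.FitResult`."""
    from .fitting import fit  # deferred: fitting imports the registry

    spec = MODEL_SPEC if convention == "paper" else _molar_spec()
    return fit(spec, dataset, solute, solvent, **fit_options)


# LHS sampling box for the four constants: energies on the 1e4-1e5 J/mol
# scale seen for solute-solvent interaction terms, exponents within (-1, 1).
_START_BOUNDS = ((1e3, 1e5), (-0.9, 0.9), (-5e4, -1e2), (-0.9, 0.9))

MODEL_SPEC = register(ModelSpec(
    "sle_wilson", 4, ("A", "B", "C", "D"), _evaluate_vec,
    frozenset({"density", "reduced_state", "properties"}),
    smart_start=None, start_bounds=_START_BOUNDS,
    convention="rho1*V2 as numeric product rho1[kg/m^3]*V2[m^3/mol]",
))


def _molar_spec() -> ModelSpec:
    def ev(pvec, T, P, rho1, solute, solvent):
        return _evaluate_vec(pvec, T, P, rho1, solute, solvent,
                             convention="molar")
    return ModelSpec("sle_wilson_molar", 4, ("A", "B", "C", "D"), ev,
                     frozenset({"density", "reduced_state", "properties"}),
                     smart_start=None, start_bounds=_START_BOUNDS)
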