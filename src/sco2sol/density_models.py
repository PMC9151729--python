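"""Eleven empirical/semi-empirical density-based solubility models.

Each model maps fitted constants and a state point (T, P, solvent density) to
a mole-fraction solubility.  All evaluators are vectorized over state points
and registered in :data:`MODEL_REGISTRY` behind a uniform :class:`ModelSpec`
interface so the fitter, the synthetic generator and the CLI can address any
model by name.

Unit conventions (validated against the printed correlation constants):
density in kg/m^3 everywhere; Mendez-Teja uses pressure in bar; Bartle uses
the standard reference state Pref = 0.1 MPa, rho_ref = 700 kg/m^3; the
reformulated Chrastil model uses M_CF = 44.01 g/mol with a unit reference
fugacity (the printed A absorbs the remaining constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import R_GAS, SoluteProperties, SolventProperties, SolubilityDataset

__all__ = [
    "ModelSpec",
    "MODEL_REGISTRY",
    "register",
    "get_model",
    "alwi_garlapati",
    "bartle",
    "bian",
    "chrastil",
    "garlapati_madras",
    "kumar_johnstone",
    "mahesh_garlapati",
    "mendez_teja",
    "sodeifian",
    "reformulated_chrastil",
    "tippana_garlapati",
]

# Bartle reference state (the usual convention for this correlation).
BARTLE_P_REF_MPA = 0.1
BARTLE_RHO_REF = 700.0
# Reformulated Chrastil reference constants; A absorbs them, so AARD and the
# temperature coefficient B are convention-independent.
REF_CHRASTIL_M_CF = 44.01
REF_CHRASTIL_F0 = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """A named solubility model behind the uniform evaluation interface.

    ``evaluate(params, T, P, rho1, solute, solvent)`` returns mole fractions;
    it never clips, so out-of-range values propagate to the fit objective.
    ``smart_start`` (optional) produces a linearized least-squares initial
    guess; ``start_bounds`` is the Latin-hypercube sampling box used when no
    such guess exists.
    """

    name: str
    n_params: int
    param_names: tuple[str, ...]
    evaluate: Callable[..., np.ndarray]
    needs: frozenset[str] = frozenset({"density"})
    smart_start: Callable[..., np.ndarray] | None = None
    start_bounds: tuple[tuple[float, float], ...] | None = None
    convention: str = "rho1 in kg/m^3"

    def __post_init__(self):
        if len(self.param_names) != self.n_params:
            raise ValueError(f"{self.name}: param_names/n_params mismatch")


MODEL_REGISTRY: dict[str, ModelSpec] = {}


def register(spec: ModelSpec) -> ModelSpec:
    MODEL_REGISTRY[spec.name] = spec
    return spec


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


def _ols(columns: Sequence[np.ndarray], target: np.ndarray) -> np.ndarray:
    X = np.column_stack(columns)
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    return beta


# ---------------------------------------------------------------------------
# model functions (natural arguments, vectorized)
# ---------------------------------------------------------------------------


def alwi_garlapati(params, Tr, rho_r):
    """y2 = exp(A + B/Tr + C*rho_r) / (rho_r*Tr)."""
    A, B, C = params
    with np.errstate(over="ignore"):
        return np.exp(A + B / Tr + C * rho_r) / (rho_r * Tr)


def bartle(params, T, P, rho, P_ref=BARTLE_P_REF_MPA, rho_ref=BARTLE_RHO_REF):
    """ln(y2*P/Pref) = A + B/T + C*(rho - rho_ref); P in MPa, rho in kg/m^3.

    The temperature coefficient B carries the sublimation enthalpy,
    dH_sub = -B*R, independently of the reference-state convention.
    """
    A, B, C = params
    with np.errstate(over="ignore"):
        return (P_ref / P) * np.exp(A + B / T + C * (rho - rho_ref))


def bian(params, T, rho1):
    """y2 = rho1^(A + B*rho1) * exp(C/T + D*rho1/T + E)."""
    A, B, C, D, E = params
    with np.errstate(over="ignore"):
        return np.exp((A + B * rho1) * np.log(rho1) + C / T + D * rho1 / T + E)


def chrastil(params, T, rho1):
    """Chrastil association model in mole-fraction form.

    y2 = g/(1 + g) with g = rho1^(kappa-1) * exp(A + B/T); kappa is the
    solvent association number, B carries the total enthalpy (-B*R).
    """
    kappa, A, B = params
    with np.errstate(over="ignore"):
        g = np.exp((kappa - 1.0) * np.log(rho1) + A + B / T)
        return g / (1.0 + g)


def chrastil_concentration(params, T, rho1):
    """Original concentration form c2 = rho1^kappa * exp(A + B/T), g/L."""
    kappa, A, B = params
    with np.errstate(over="ignore"):
        return np.exp(kappa * np.log(rho1) + A + B / T)


def garlapati_madras(params, T, rho1):
    """ln y2 = A + (B + C*rho1)*ln(rho1) + D/T + E*ln(rho1*T)."""
    A, B, C, D, E = params
    with np.errstate(over="ignore"):
        return np.exp(A + (B + C * rho1) * np.log(rho1) + D / T
                      + E * np.log(rho1 * T))


def kumar_johnstone(params, T, rho):
    """ln y2 = A + B*rho + C/T."""
    A, B, C = params
    with np.errstate(over="ignore"):
        return np.exp(A + B * rho + C / T)


def mahesh_garlapati(params, Tr, rho_r):
    """ln y2 = A + B*(rho_r*Tr) + C*(rho_r*Tr^3)."""
    A, B, C = params
    with np.errstate(over="ignore"):
        return np.exp(A + B * rho_r * Tr + C * rho_r * Tr**3)


def mendez_teja(params, T, P_bar, rho):
    """T*ln(y2*P) = A + B*rho + C*T with P in bar."""
    A, B, C = params
    with np.errstate(over="ignore"):
        return np.exp((A + B * rho + C * T) / T) / P_bar


def sodeifian(params, T, P, rho1):
    """ln y2 = A + B*P^2/T + C*ln(rho1*T) + D*rho1*ln(rho1) + E*P*ln(T)
    + F*ln(rho1)/T; P in MPa, rho1 in kg/m^3."""
    A, B, C, D, E, F = params
    ln_rho = np.log(rho1)
    with np.errstate(over="ignore"):
        return np.exp(A + B * P**2 / T + C * np.log(rho1 * T)
                      + D * rho1 * ln_rho + E * P * np.log(T) + F * ln_rho / T)


def reformulated_chrastil(params, T, rho1, M_cf=REF_CHRASTIL_M_CF,
                          f0=REF_CHRASTIL_F0):
    """y2 = (R*T*rho1/(M_cf*f0))^(kappa'-1) * exp(A + B/T)."""
    kappa_p, A, B = params
    with np.errstate(over="ignore"):
        x = R_GAS * T * rho1 / (M_cf * f0)
        return np.exp((kappa_p - 1.0) * np.log(x) + A + B / T)


def tippana_garlapati(params, Tr, Pr):
    """y2 = (A + B*Pr + C*Pr^2)*Tr^2 + (D + E*Pr + F*Pr^2)."""
    A, B, C, D, E, F = params
    return (A + B * Pr + C * Pr**2) * Tr**2 + (D + E * Pr + F * Pr**2)


# ---------------------------------------------------------------------------
# registry wiring: uniform evaluate + linearized least-squares starts
# ---------------------------------------------------------------------------


def _reduced(T, rho, solvent):
    return T / solvent.Tc, rho / solvent.rho_c


def _ev_alwi(params, T, P, rho1, solute, solvent):
    Tr, rho_r = _reduced(T, rho1, solvent)
    return alwi_garlapati(params, Tr, rho_r)


def _ss_alwi(ds, solute, solvent):
    Tr, rho_r = _reduced(ds.T, ds.rho1, solvent)
    y = np.log(ds.y2 * rho_r * Tr)
    return _ols([np.ones_like(Tr), 1.0 / Tr, rho_r], y)


def _ev_bartle(params, T, P, rho1, solute, solvent):
    return bartle(params, T, P, rho1)


def _ss_bartle(ds, solute, solvent):
    y = np.log(ds.y2 * ds.P / BARTLE_P_REF_MPA)
    return _ols([np.ones_like(y), 1.0 / ds.T, ds.rho1 - BARTLE_RHO_REF], y)


def _ev_bian(params, T, P, rho1, solute, solvent):
    return bian(params, T, rho1)


def _ss_bian(ds, solute, solvent):
    ln_rho = np.log(ds.rho1)
    y = np.log(ds.y2)
    return _ols([ln_rho, ds.rho1 * ln_rho, 1.0 / ds.T, ds.rho1 / ds.T,
                 np.ones_like(y)], y)


def _ev_chrastil(params, T, P, rho1, solute, solvent):
    return chrastil(params, T, rho1)


def _ss_chrastil(ds, solute, solvent):
    # y2 << 1 on solubility data, so ln y2 ~ (kappa-1) ln rho + A + B/T
    y = np.log(ds.y2)
    beta = _ols([np.log(ds.rho1), np.ones_like(y), 1.0 / ds.T], y)
    return np.array([beta[0] + 1.0, beta[1], beta[2]])


def _ev_gm(params, T, P, rho1, solute, solvent):
    return garlapati_madras(params, T, rho1)


def _ss_gm(ds, solute, solvent):
    ln_rho = np.log(ds.rho1)
    y = np.log(ds.y2)
    return _ols([np.ones_like(y), ln_rho, ds.rho1 * ln_rho, 1.0 / ds.T,
                 np.log(ds.rho1 * ds.T)], y)


def _ev_kj(params, T, P, rho1, solute, solvent):
    return kumar_johnstone(params, T, rho1)


def _ss_kj(ds, solute, solvent):
    y = np.log(ds.y2)
    return _ols([np.ones_like(y), ds.rho1, 1.0 / ds.T], y)


def _ev_mg(params, T, P, rho1, solute, solvent):
    Tr, rho_r = _reduced(T, rho1, solvent)
    return mahesh_garlapati(params, Tr, rho_r)


def _ss_mg(ds, solute, solvent):
    Tr, rho_r = _reduced(ds.T, ds.rho1, solvent)
    y = np.log(ds.y2)
    return _ols([np.ones_like(y), rho_r * Tr, rho_r * Tr**3], y)


def _ev_mt(params, T, P, rho1, solute, solvent):
    return mendez_teja(params, T, 10.0 * P, rho1)  # MPa -> bar


def _ss_mt(ds, solute, solvent):
    y = ds.T * np.log(ds.y2 * 10.0 * ds.P)
    return _ols([np.ones_like(y), ds.rho1, ds.T], y)


def _ev_sod(params, T, P, rho1, solute, solvent):
    return sodeifian(params, T, P, rho1)


def _ss_sod(ds, solute, solvent):
    ln_rho = np.log(ds.rho1)
    y = np.log(ds.y2)
    return _ols([np.ones_like(y), ds.P**2 / ds.T, np.log(ds.rho1 * ds.T),
                 ds.rho1 * ln_rho, ds.P * np.log(ds.T), ln_rho / ds.T], y)


def _ev_rc(params, T, P, rho1, solute, solvent):
    return reformulated_chrastil(params, T, rho1)


def _ss_rc(ds, solute, solvent):
    x = np.log(R_GAS * ds.T * ds.rho1 / (REF_CHRASTIL_M_CF * REF_CHRASTIL_F0))
    y = np.log(ds.y2)
    beta = _ols([x, np.ones_like(y), 1.0 / ds.T], y)
    return np.array([beta[0] + 1.0, beta[1], beta[2]])


def _ev_tg(params, T, P, rho1, solute, solvent):
    Tr = T / solvent.Tc
    Pr = P / (solvent.Pc / 1e6)  # both in MPa
    return tippana_garlapati(params, Tr, Pr)


def _ss_tg(ds, solute, solvent):
    Tr = ds.T / solvent.Tc
    Pr = ds.P / (solvent.Pc / 1e6)
    cols = [Tr**2, Pr * Tr**2, Pr**2 * Tr**2, np.ones_like(Tr), Pr, Pr**2]
    return _ols(cols, ds.y2)


register(ModelSpec("alwi_garlapati", 3, ("A", "B", "C"), _ev_alwi,
                   frozenset({"reduced_state"}), _ss_alwi))
register(ModelSpec("bartle", 3, ("A", "B", "C"), _ev_bartle,
                   frozenset({"pressure", "density"}), _ss_bartle,
                   convention="rho1 in kg/m^3; Pref=0.1 MPa, rhoref=700 kg/m^3"))
register(ModelSpec("bian", 5, ("A", "B", "C", "D", "E"), _ev_bian,
                   frozenset({"density"}), _ss_bian))
register(ModelSpec("chrastil", 3, ("kappa", "A", "B"), _ev_chrastil,
                   frozenset({"density"}), _ss_chrastil))
register(ModelSpec("garlapati_madras", 5, ("A", "B", "C", "D", "E"), _ev_gm,
                   frozenset({"density"}), _ss_gm))
register(ModelSpec("kumar_johnstone", 3, ("A", "B", "C"), _ev_kj,
                   frozenset({"density"}), _ss_kj))
register(ModelSpec("mahesh_garlapati", 3, ("A", "B", "C"), _ev_mg,
                   frozenset({"reduced_state"}), _ss_mg))
register(ModelSpec("mendez_teja", 3, ("A", "B", "C"), _ev_mt,
                   frozenset({"pressure", "density"}), _ss_mt,
                   convention="rho1 in kg/m^3; P in bar"))
register(ModelSpec("sodeifian", 6, ("A", "B", "C", "D", "E", "F"), _ev_sod,
                   frozenset({"pressure", "density"}), _ss_sod))
register(ModelSpec("reformulated_chrastil", 3, ("kappa_p", "A", "B"), _ev_rc,
                   frozenset({"density"}), _ss_rc,
                   convention="rho1 in kg/m^3; M_CF=44.01 g/mol, f0=1"))
register(ModelSpec("tippana_garlapati", 6, ("A", "B", "C", "D", "E", "F"),
                   _ev_tg, frozenset({"pressure", "reduced_state"}), _ss_tg))
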