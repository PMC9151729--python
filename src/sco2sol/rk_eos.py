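"""Redlich-Kwong equation of state with Kwak-Mansoori mixing rules.

The solvent-rich supercritical phase is described by the classic RK pressure
form

    P = R*T/(v - b) - a / (sqrt(T) * v * (v + b))

with pure-component parameters a = 0.42748 R^2 Tc^2.5 / Pc and
b = 0.08664 R Tc / Pc.  Mixture parameters follow Kwak-Mansoori:

    alpha = sum_ij x_i x_j a_ij^(2/3) b_ij^(1/3)
    b     = sum_ij x_i x_j b_ij
    a     = alpha^(3/2) / b^(1/2)

with combining rules a_ij = (1 - k_ij) sqrt(a_ii a_jj) and
b_ij = (1 - l_ij) ((b_ii^(1/3) + b_jj^(1/3))^3) / 8.  The two binary
interaction constants k_ij and l_ij are the only adjustables.

The component fugacity coefficient is obtained analytically from the
isothermal residual-volume integral

    ln phi_i = (1/RT) * int_v^inf [ (dP/dN_i)_{T,V,Nj} - RT/v ] dv - ln Z

carried out for the RK form above with composition-dependent a(x), b(x):

    ln phi_i = ln(v/(v-b)) + bbar_i/(v-b) - ln Z
               - abar_i/(R T^1.5 b) * ln(1 + b/v)
               + a*bbar_i/(R T^1.5) * [ln(1 + b/v)/b^2 - 1/(b(v+b))]

with the partial-molar combinations

    bbar_i = 2 sum_j x_j b_ij - b
    abar_i = 3 sqrt(alpha) (sum_j x_j q_ij)/sqrt(b)
             - alpha^(3/2) (sum_j x_j b_ij)/b^(3/2),     q_ij = a_ij^(2/3) b_ij^(1/3)

(for a pure component abar = 2a, bbar = b and the expression collapses to
the standard pure-RK fugacity coefficient).

Solid solubility solves

    y2 = (Psub / (P * phi2)) * exp[(P - Psub) * Vs / (R T)]

by damped successive substitution, with the solid-phase fugacity coefficient
taken as unity and the Poynting correction using the solid molar volume Vs.
All pressures in this module are in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import R_GAS, SoluteProperties, SolventProperties, SolubilityDataset
from .density_models import ModelSpec, register

__all__ = [
    "OMEGA_A",
    "OMEGA_B",
    "PureRkParams",
    "BinaryInteraction",
    "EosMixtureState",
    "pure_params",
    "cross_params",
    "mixture_params",
    "solve_volume",
    "pressure_rk",
    "mixture_state",
    "fugacity_coeff",
    "solubility_eos",
    "fit_interaction",
]

OMEGA_A = 0.42748
OMEGA_B = 0.08664


@dataclass(frozen=True)
class PureRkParams:
    """Pure-component RK constants: a in Pa m^6 K^0.5 / mol^2, b in m^3/mol."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")


@dataclass(frozen=True)
class BinaryInteraction:
    """Adjustable energy (kij) and size (lij) binary interaction constants."""

    kij: float = 0.0
    lij: float = 0.0


@dataclass(frozen=True)
class EosMixtureState:
    """Solved mixture state at (T, P, x)."""

    a_mix: float
    b_mix: float
    v: float          # molar volume, m^3/mol
    Z: float          # compressibility, P v / (R T)
    phi: np.ndarray   # per-component fugacity coefficients


def pure_params(Tc: float, Pc: float) -> PureRkParams:
    """Classic RK constants from critical temperature (K) and pressure (Pa)."""
    if Tc <= 0 or Pc <= 0:
        raise ValueError("Tc and Pc must be positive")
    a = OMEGA_A * R_GAS**2 * Tc**2.5 / Pc
    b = OMEGA_B * R_GAS * Tc / Pc
    return PureRkParams(a=a, b=b)


def cross_params(p_i: PureRkParams, p_j: PureRkParams,
                 inter: BinaryInteraction) -> tuple[float, float]:
    """Kwak-Mansoori combining rules for the unlike pair."""
    a_ij = (1.0 - inter.kij) * math.sqrt(p_i.a * p_j.a)
    b_ij = (1.0 - inter.lij) * (p_i.b ** (1 / 3) + p_j.b ** (1 / 3)) ** 3 / 8.0
    return a_ij, b_ij


def _pair_matrices(pures, inter):
    n = len(pures)
    a = np.empty((n, n))
    b = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                a[i, j], b[i, j] = pures[i].a, pures[i].b
            else:
                a[i, j], b[i, j] = cross_params(pures[i], pures[j], inter)
    return a, b


def mixture_params(x, pures, inter: BinaryInteraction):
    """Mixture (a, b, alpha) under the KM rules; x must sum to 1."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-10:
        raise ValueError("composition must be non-negative and sum to 1")
    a_ij, b_ij = _pair_matrices(pures, inter)
    q_ij = a_ij ** (2 / 3) * b_ij ** (1 / 3)
    alpha = float(x @ q_ij @ x)
    b_mix = float(x @ b_ij @ x)
    a_mix = alpha ** 1.5 / math.sqrt(b_mix)
    return a_mix, b_mix, alpha


def pressure_rk(T: float, v, a: float, b: float):
    """RK pressure (Pa) at molar volume v (m^3/mol)."""
    v = np.asarray(v, dtype=float)
    out = R_GAS * T / (v - b) - a / (math.sqrt(T) * v * (v + b))
    return float(out) if out.ndim == 0 else out


def _largest_real_root(c2, c1, c0):
    """Largest real root of Z^3 + c2 Z^2 + c1 Z + c0 = 0, vectorized.

    Cardano/trigonometric closed form followed by two Newton polish steps,
    so the root satisfies the cubic to near machine precision."""
    c2, c1, c0 = np.broadcast_arrays(np.asarray(c2, float), c1, c0)
    p = c1 - c2**2 / 3.0
    q = 2.0 * c2**3 / 27.0 - c2 * c1 / 3.0 + c0
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    with np.errstate(invalid="ignore", divide="ignore"):
        # one real root (disc > 0): Cardano
        sq = np.sqrt(np.maximum(disc, 0.0))
        t_one = np.cbrt(-q / 2.0 + sq) + np.cbrt(-q / 2.0 - sq)
        # three real roots (disc <= 0): largest is 2*sqrt(-p/3)*cos(theta/3)
        m = np.sqrt(np.maximum(-p / 3.0, 0.0))
        cos_arg = np.clip(np.where(m > 0, 3.0 * q / (2.0 * p * np.where(m > 0, m, 1.0)), 1.0), -1.0, 1.0)
        t_three = 2.0 * m * np.cos(np.arccos(cos_arg) / 3.0)
    z = np.where(disc > 0, t_one, t_three) - c2 / 3.0
    for _ in range(2):  # Newton polish
        f = ((z + c2) * z + c1) * z + c0
        df = (3.0 * z + 2.0 * c2) * z + c1
        z = z - np.where(np.abs(df) > 0, f / np.where(df != 0, df, 1.0), 0.0)
    return z


def solve_volume(T, P, a_mix, b_mix):
    """Molar volume on the vapor-like/supercritical branch: the largest real
    root v > b of the RK cubic.  Vectorized; raises if no such root."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0):
        raise ValueError("T and P must be positive")
    A = a_mix * P / (R_GAS**2 * T**2.5)
    B = np.asarray(b_mix) * P / (R_GAS * T)
    Z = _largest_real_root(-np.ones_like(A), A - B - B**2, -A * B)
    if np.any(~np.isfinite(Z)) or np.any(Z <= B):
        raise ValueError("no volume root above the covolume")
    v = Z * R_GAS * T / P
    return float(v) if v.ndim == 0 else v


def mixture_state(T: float, P: float, x, pures,
                  inter: BinaryInteraction) -> EosMixtureState:
    """Solve the mixture at (T, P, x) and evaluate all fugacity coefficients."""
    x = np.asarray(x, dtype=float)
    a_mix, b_mix, alpha = mixture_params(x, pures, inter)
    v = float(solve_volume(T, P, a_mix, b_mix))
    Z = P * v / (R_GAS * T)
    a_ij, b_ij = _pair_matrices(pures, inter)
    q_ij = a_ij ** (2 / 3) * b_ij ** (1 / 3)
    sq = q_ij @ x      # sum_j x_j q_ij, per component i
    sb = b_ij @ x
    bbar = 2.0 * sb - b_mix
    abar = (3.0 * math.sqrt(alpha) * sq / math.sqrt(b_mix)
            - alpha ** 1.5 * sb / b_mix ** 1.5)
    rt32 = R_GAS * T ** 1.5
    log_term = math.log1p(b_mix / v)
    ln_phi = (math.log(v / (v - b_mix)) + bbar / (v - b_mix) - math.log(Z)
              - abar / (rt32 * b_mix) * log_term
              + a_mix * bbar / rt32 * (log_term / b_mix**2
                                       - 1.0 / (b_mix * (v + b_mix))))
    return EosMixtureState(a_mix=a_mix, b_mix=b_mix, v=v, Z=Z,
                           phi=np.exp(ln_phi))


def fugacity_coeff(T: float, P: float, x, pures,
                   inter: BinaryInteraction) -> np.ndarray:
    """Per-component fugacity coefficients at (T, P, x)."""
    return mixture_state(T, P, x, pures, inter).phi


# ---------------------------------------------------------------------------
# vectorized binary-mixture path used by the solubility solve and the fitter
# ---------------------------------------------------------------------------


def _phi2_binary(T, P, y2, p1: PureRkParams, p2: PureRkParams,
                 inter: BinaryInteraction):
    """Solute fugacity coefficient, vectorized over state points (binary
    CO2(1)/solute(2) mixture).  Returns nan where the state is unphysical."""
    a12, b12 = cross_params(p1, p2, inter)
    if b12 <= 0 or a12 < 0:
        return np.full_like(np.asarray(T, float), np.nan)
    x1 = 1.0 - y2
    q11 = p1.a ** (2 / 3) * p1.b ** (1 / 3)
    q22 = p2.a ** (2 / 3) * p2.b ** (1 / 3)
    q12 = a12 ** (2 / 3) * b12 ** (1 / 3)
    alpha = x1**2 * q11 + 2 * x1 * y2 * q12 + y2**2 * q22
    b_mix = x1**2 * p1.b + 2 * x1 * y2 * b12 + y2**2 * p2.b
    a_mix = alpha**1.5 / np.sqrt(b_mix)
    A = a_mix * P / (R_GAS**2 * T**2.5)
    B = b_mix * P / (R_GAS * T)
    Z = _largest_real_root(-np.ones_like(A), A - B - B**2, -A * B)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = Z * R_GAS * T / P
        sq2 = x1 * q12 + y2 * q22
        sb2 = x1 * b12 + y2 * p2.b
        bbar2 = 2.0 * sb2 - b_mix
        abar2 = (3.0 * np.sqrt(alpha) * sq2 / np.sqrt(b_mix)
                 - alpha**1.5 * sb2 / b_mix**1.5)
        rt32 = R_GAS * T**1.5
        log_term = np.log1p(b_mix / v)
        ln_phi2 = (np.log(v / (v - b_mix)) + bbar2 / (v - b_mix) - np.log(Z)
                   - abar2 / (rt32 * b_mix) * log_term
                   + a_mix * bbar2 / rt32 * (log_term / b_mix**2
                                             - 1.0 / (b_mix * (v + b_mix))))
        phi2 = np.exp(ln_phi2)
    phi2 = np.where(np.isfinite(phi2) & (Z > B) & (phi2 > 0), phi2, np.nan)
    return phi2


def solubility_eos(T, P, solute: SoluteProperties, solvent: SolventProperties,
                   inter: BinaryInteraction, psub=None, damping: float = 1.0,
                   tol: float = 1e-10, maxiter: int = 200):
    """Solid solubility y2 from the equifugacity condition, pressures in Pa.

    Solves y2 = (Psub/(P*phi2(y2))) * exp[(P - Psub)*Vs/(R T)] by successive
    substitution from y2 = Psub/P.  The solute fugacity coefficient depends
    only weakly on composition at y2 << 1, so the undamped iteration
    converges in a handful of steps; the working damping factor is halved
    whenever a step fails to contract.  ``psub`` (Pa) overrides the solute's
    tabulated sublimation pressure.  Vectorized over state points.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    P = np.atleast_1d(np.asarray(P, dtype=float))
    T, P = np.broadcast_arrays(T, P)
    if psub is None:
        psub = np.array([solute.sublimation_pressure(t) for t in T.ravel()]
                        ).reshape(T.shape)
    else:
        psub = np.broadcast_to(np.asarray(psub, dtype=float), T.shape)
    p1 = pure_params(solvent.Tc, solvent.Pc)
    p2 = pure_params(solute.Tc, solute.Pc)
    poynting = np.exp((P - psub) * solute.Vs / (R_GAS * T))
    y = psub / P
    converged = False
    lam = damping
    prev_step = np.inf
    for _ in range(maxiter):
        phi2 = _phi2_binary(T, P, y, p1, p2, inter)
        if np.any(~np.isfinite(phi2)):
            return np.full(T.shape, np.nan) if T.size > 1 else float("nan")
        y_new = psub / (P * phi2) * poynting
        if np.any(y_new >= 1.0) or np.any(y_new <= 0):
            return np.full(T.shape, np.nan) if T.size > 1 else float("nan")
        step = y_new - y
        step_size = float(np.max(np.abs(step)))
        if step_size > prev_step:  # not contracting: damp harder
            lam = max(0.5 * lam, 1.0 / 64.0)
        prev_step = step_size
        y = y + lam * step
        if np.max(np.abs(step) / np.maximum(y_new, 1e-300)) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError("solubility fixed point did not converge "
                           f"within {maxiter} iterations")
    return y if y.size > 1 else float(y[0])


def _ev_rk(pvec, T, P, rho1, solute, solvent):
    """Registry evaluator: params (kij, lij); dataset pressure MPa -> Pa."""
    inter = BinaryInteraction(kij=float(pvec[0]), lij=float(pvec[1]))
    try:
        y = solubility_eos(T, P * 1e6, solute, solvent, inter)
    except (RuntimeError, ValueError):
        return np.full_like(np.asarray(T, float), np.nan)
    return np.atleast_1d(y)


MODEL_SPEC = register(ModelSpec(
    "rk_km", 2, ("kij", "lij"), _ev_rk,
    frozenset({"pressure", "properties"}),
    smart_start=None, start_bounds=((-0.9, 0.9), (-0.9, 0.9)),
    convention="P in Pa inside the EoS (dataset MPa converted)",
))


def fit_interaction(dataset: SolubilityDataset, solute: SoluteProperties,
                    solvent: SolventProperties, **fit_options):
    """Fit (kij, lij) to a dataset by multistart Nelder-Mead on the relative
    objective; returns a :class:`sco2sol.fitting.FitResult`."""
    from .fitting import fit

    return fit(MODEL_SPEC, dataset, solute, solvent, **fit_options)
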