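"""Regression, goodness-of-fit statistics, model selection and derived
thermodynamic analyses.

All models are fitted by minimizing the relative-deviation objective

    OF = sum_i |y2_exp,i - y2_calc,i| / y2_exp,i

with multistart Nelder-Mead (100 Latin-hypercube starts by default, fixed
seed), the direct-search analogue of the original fminsearch regression.
Goodness of fit is reported as AARD% = 100*OF/N together with SSE, RMSE,
R^2, adjusted R^2 and the information criteria

    AIC  = N ln(SSE/N) + 2Q,      AICc = AIC + 2Q(Q+1)/(N-Q-1)

computed on the mole-fraction scale; models are ranked by ascending AICc.

Temperature coefficients of the Chrastil-type and Bartle correlations carry
the total and sublimation enthalpies (dH = -B*R); their difference is the
solvation enthalpy.  The crossover pressure, where two solubility isotherms
intersect, is located by bisection on a fitted model with isotherm densities
interpolated from the measured (P, rho) pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize
from scipy.stats import qmc

from .data import R_GAS, SoluteProperties, SolventProperties, SolubilityDataset
from .density_models import MODEL_REGISTRY, ModelSpec, get_model

__all__ = [
    "FitResult",
    "EnthalpyReport",
    "GofStatistics",
    "MtConsistency",
    "NoCrossoverError",
    "objective",
    "aard_pct",
    "statistics",
    "fit",
    "fit_battery",
    "rank_models",
    "enthalpies",
    "crossover_pressure",
    "crossover_pressure_data",
    "mt_self_consistency",
]

#: finite penalty returned by the objective when a parameter vector produces
#: non-finite or out-of-range solubilities; keeps Nelder-Mead well defined.
PENALTY = 1e6

DEFAULT_N_STARTS = 100
DEFAULT_SEED = 42


class NoCrossoverError(ValueError):
    """The two isotherms do not intersect inside the pressure range."""


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with goodness-of-fit statistics and provenance."""

    model_name: str
    params: np.ndarray
    param_names: tuple[str, ...]
    aard_pct: float
    sse: float
    rmse: float
    r2: float
    adj_r2: float
    aic: float
    aicc: float
    n_obs: int
    n_params: int
    n_starts: int
    seed: int
    converged: bool
    convention: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "convention": self.convention,
            "params": {k: float(v) for k, v in zip(self.param_names, self.params)},
            "aard_pct": self.aard_pct,
            "sse": self.sse,
            "rmse": self.rmse,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "aic": self.aic,
            "aicc": self.aicc,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class EnthalpyReport:
    """Total, sublimation and solvation enthalpies in kJ/mol."""

    dH_total: float
    dH_sub: float
    dH_solv: float = field(default=float("nan"))

    def __post_init__(self):
        object.__setattr__(self, "dH_solv", self.dH_total - self.dH_sub)


class GofStatistics(NamedTuple):
    sse: float
    rmse: float
    r2: float
    adj_r2: float
    aic: float
    aicc: float


@dataclass(frozen=True)
class MtConsistency:
    """OLS collapse of T ln(y2 P) against density and temperature."""

    intercept: float      # A
    slope_rho: float      # B
    slope_T: float        # C
    r2: float
    underdetermined: bool


# ---------------------------------------------------------------------------
# objective and statistics
# ---------------------------------------------------------------------------


def objective(y_exp, y_calc) -> float:
    """Sum of absolute relative deviations sum|y_exp - y_calc|/y_exp."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if y_exp.shape != y_calc.shape:
        raise ValueError("y_exp and y_calc must have equal length")
    if np.any(y_exp <= 0):
        raise ValueError("experimental solubilities must be positive")
    return float(np.sum(np.abs(y_exp - y_calc) / y_exp))


def aard_pct(y_exp, y_calc) -> float:
    """Average absolute relative deviation, percent: 100/N * objective."""
    return 100.0 / len(np.asarray(y_exp)) * objective(y_exp, y_calc)


def statistics(y_exp, y_calc, Q: int) -> GofStatistics:
    """SSE, RMSE, R^2, adjusted R^2, AIC and AICc on the mole-fraction scale.

    AIC = N ln(SSE/N) + 2Q; the small-sample correction requires N > Q + 1.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    n = len(y_exp)
    if n <= Q + 1:
        raise ValueError(f"AICc undefined for N={n} observations and Q={Q}")
    sse = float(np.sum((y_exp - y_calc) ** 2))
    rmse = math.sqrt(sse / n)
    sst = float(np.sum((y_exp - y_exp.mean()) ** 2))
    r2 = 1.0 - sse / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - Q - 1)
    aic = n * math.log(sse / n) + 2 * Q
    aicc = aic + 2 * Q * (Q + 1) / (n - Q - 1)
    return GofStatistics(sse, rmse, r2, adj_r2, aic, aicc)


# ---------------------------------------------------------------------------
# multistart fitting
# ---------------------------------------------------------------------------


def _penalized_objective(model: ModelSpec, dataset: SolubilityDataset,
                         solute, solvent):
    T, P, rho, y_exp = dataset.T, dataset.P, dataset.rho1, dataset.y2

    def f(pvec: np.ndarray) -> float:
        y_calc = model.evaluate(pvec, T, P, rho, solute, solvent)
        y_calc = np.asarray(y_calc, dtype=float)
        if (y_calc.shape != y_exp.shape or np.any(~np.isfinite(y_calc))
                or np.any(y_calc <= 0.0) or np.any(y_calc >= 1.0)):
            return PENALTY
        return float(np.sum(np.abs(y_exp - y_calc) / y_exp))

    return f


def _starts(model: ModelSpec, dataset, solute, solvent,
            n_starts: int, seed: int) -> list[np.ndarray]:
    starts: list[np.ndarray] = []
    center = None
    if model.smart_start is not None:
        center = np.asarray(model.smart_start(dataset, solute, solvent), float)
        starts.append(center)
    n_lhs = max(0, n_starts - len(starts))
    if n_lhs:
        if model.start_bounds is not None:
            lo = np.array([b[0] for b in model.start_bounds])
            hi = np.array([b[1] for b in model.start_bounds])
        else:
            # box around the linearized solution, wide enough to explore
            half = 1.0 + np.abs(center)
            lo, hi = center - half, center + half
        sampler = qmc.LatinHypercube(d=model.n_params, seed=seed)
        starts.extend(qmc.scale(sampler.random(n_lhs), lo, hi))
    return starts


def fit(model: ModelSpec | str, dataset: SolubilityDataset,
        solute: SoluteProperties, solvent: SolventProperties,
        n_starts: int = DEFAULT_N_STARTS, seed: int = DEFAULT_SEED,
        xatol: float = 1e-10, fatol: float = 1e-12,
        maxiter_factor: int = 400) -> FitResult:
    """Multistart Nelder-Mead fit of a registered model to a dataset.

    The best of ``n_starts`` local searches (a linearized least-squares
    start, when the model has one, plus seeded Latin-hypercube samples) is
    polished by a restarted Nelder-Mead run.  Deterministic for fixed seed.
    """
    if isinstance(model, str):
        model = get_model(model)
    obj = _penalized_objective(model, dataset, solute, solvent)
    options = {"xatol": xatol, "fatol": fatol,
               "maxiter": maxiter_factor * model.n_params,
               "maxfev": maxiter_factor * model.n_params}
    candidates = []
    diagnostics = []
    for x0 in _starts(model, dataset, solute, solvent, n_starts, seed):
        res = minimize(obj, x0, method="Nelder-Mead", options=options)
        diagnostics.append((res.fun, res.message))
        if np.isfinite(res.fun) and res.fun < PENALTY:
            candidates.append((res.fun, res.x))
    if not candidates:
        raise RuntimeError(
            f"{model.name}: no start converged to a feasible fit; "
            f"per-start results: {diagnostics[:5]}..."
        )
    # restart-polish the best few basins: NM re-started at its own optimum
    # tightens the collapsed simplex and distinguishes nearby local minima
    candidates.sort(key=lambda c: c[0])
    best_f, best_x = candidates[0]
    converged = True
    for fun, x in candidates[:5]:
        for _ in range(3):
            polish = minimize(obj, x, method="Nelder-Mead", options=options)
            improved = polish.fun < fun - fatol
            fun, x = min(fun, polish.fun), (polish.x if polish.fun <= fun
                                            else x)
            if fun < best_f:
                best_f, best_x = fun, x
                converged = bool(polish.success)
            if not improved:
                break
    y_calc = np.asarray(
        model.evaluate(best_x, dataset.T, dataset.P, dataset.rho1,
                       solute, solvent), dtype=float)
    stats = statistics(dataset.y2, y_calc, model.n_params)
    return FitResult(
        model_name=model.name, params=np.asarray(best_x),
        param_names=model.param_names,
        aard_pct=aard_pct(dataset.y2, y_calc),
        sse=stats.sse, rmse=stats.rmse, r2=stats.r2, adj_r2=stats.adj_r2,
        aic=stats.aic, aicc=stats.aicc,
        n_obs=len(dataset), n_params=model.n_params,
        n_starts=n_starts, seed=seed, converged=converged,
        convention=model.convention,
    )


def fit_battery(dataset, solute, solvent, names: Sequence[str] | None = None,
                **fit_options) -> list[FitResult]:
    """Fit every requested registered model (default: all) to the dataset."""
    if names is None:
        names = sorted(MODEL_REGISTRY)
    return [fit(name, dataset, solute, solvent, **fit_options)
            for name in names]


def rank_models(results: Sequence[FitResult]) -> list[FitResult]:
    """Ascending AICc (best first); ties broken by AARD, then by Q."""
    if not results:
        raise ValueError("need at least one fit result")
    return sorted(results, key=lambda r: (r.aicc, r.aard_pct, r.n_params))


# ---------------------------------------------------------------------------
# derived analyses
# ---------------------------------------------------------------------------


def enthalpies(chrastil_B: float, bartle_B: float) -> EnthalpyReport:
    """Total / sublimation / solvation enthalpies (kJ/mol) from the
    temperature coefficients B of a Chrastil-type and the Bartle model:
    dH = -B*R, and dH_solv = dH_total - dH_sub."""
    dh_total = -chrastil_B * R_GAS / 1000.0
    dh_sub = -bartle_B * R_GAS / 1000.0
    return EnthalpyReport(dH_total=dh_total, dH_sub=dh_sub)


def crossover_pressure(model_fit: FitResult, dataset: SolubilityDataset,
                       solute: SoluteProperties, solvent: SolventProperties,
                       T_low: float | None = None, T_high: float | None = None,
                       xtol: float = 0.001) -> float:
    """Pressure (MPa) where the fitted isotherms at T_low and T_high cross.

    Densities at intermediate pressures come from cubic interpolation of each
    measured isotherm's (P, rho) points; the root is bisected to better than
    0.01 MPa.  Raises :class:`NoCrossoverError` when the isotherms do not
    intersect within the common pressure range.
    """
    temps = dataset.temperatures()
    if T_low is None:
        T_low = float(temps.min())
    if T_high is None:
        T_high = float(temps.max())
    model = get_model(model_fit.model_name)

    def iso_curve(T):
        iso = dataset.isotherm(T)
        order = np.argsort(iso.P)
        spline = CubicSpline(iso.P[order], iso.rho1[order])
        return iso, spline

    iso_lo, rho_lo = iso_curve(T_low)
    iso_hi, rho_hi = iso_curve(T_high)
    p_min = max(iso_lo.P.min(), iso_hi.P.min())
    p_max = min(iso_lo.P.max(), iso_hi.P.max())

    def diff(p):
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        y_lo = model.evaluate(model_fit.params, np.full_like(p_arr, T_low),
                              p_arr, rho_lo(p_arr), solute, solvent)
        y_hi = model.evaluate(model_fit.params, np.full_like(p_arr, T_high),
                              p_arr, rho_hi(p_arr), solute, solvent)
        d = np.asarray(y_lo) - np.asarray(y_hi)
        return d if np.ndim(p) else float(d[0])

    grid = np.linspace(p_min, p_max, 256)
    values = diff(grid)
    scale = np.max(np.abs(values))
    if scale == 0 or not np.isfinite(scale):
        raise NoCrossoverError("isotherms are identical or undefined in range")
    sign = np.sign(values)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise NoCrossoverError(
            f"no crossover between {T_low} K and {T_high} K in "
            f"[{p_min}, {p_max}] MPa"
        )
    i = idx[0]
    return float(brentq(diff, grid[i], grid[i + 1], xtol=xtol))


def crossover_pressure_data(dataset: SolubilityDataset,
                            T_low: float | None = None,
                            T_high: float | None = None,
                            xtol: float = 0.001) -> float:
    """Model-free crossover: pressure (MPa) where cubic splines through the
    two measured y2(P) isotherms intersect.  This is the observable quantity
    behind an eyeballed crossover region on a solubility-vs-pressure plot."""
    temps = dataset.temperatures()
    if T_low is None:
        T_low = float(temps.min())
    if T_high is None:
        T_high = float(temps.max())
    iso_lo = dataset.isotherm(T_low)
    iso_hi = dataset.isotherm(T_high)
    s_lo = CubicSpline(np.sort(iso_lo.P), iso_lo.y2[np.argsort(iso_lo.P)])
    s_hi = CubicSpline(np.sort(iso_hi.P), iso_hi.y2[np.argsort(iso_hi.P)])
    p_min = max(iso_lo.P.min(), iso_hi.P.min())
    p_max = min(iso_lo.P.max(), iso_hi.P.max())
    diff = lambda p: s_lo(p) - s_hi(p)
    grid = np.linspace(p_min, p_max, 256)
    sign = np.sign(diff(grid))
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise NoCrossoverError(
            f"no crossover between {T_low} K and {T_high} K in "
            f"[{p_min}, {p_max}] MPa"
        )
    return float(brentq(diff, grid[idx[0]], grid[idx[0] + 1], xtol=xtol))


def mt_self_consistency(dataset: SolubilityDataset) -> MtConsistency:
    """Ordinary least squares of T ln(y2 P) on solvent density and T.

    Measures how tightly the data collapse onto the three-constant
    density-linear form T ln(y2 P) = A + B rho + C T (pressure in bar).
    Flagged underdetermined when there are no residual degrees of freedom.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least two points")
    y = dataset.T * np.log(dataset.y2 * 10.0 * dataset.P)
    X = np.column_stack([np.ones(n), dataset.rho1, dataset.T])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return MtConsistency(intercept=float(beta[0]), slope_rho=float(beta[1]),
                         slope_T=float(beta[2]), r2=r2,
                         underdetermined=n <= 3)
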