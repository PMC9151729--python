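"""Domain types, unit conventions and I/O for solid-solute solubility in ScCO2.

Conventions used throughout the package:

* temperature in K, pressure in MPa at the data boundary (Pa inside the EoS),
* solvent density in kg/m^3 (numerically equal to g/L),
* solubility as mole fraction ``y2`` (dimensionless) or as the equilibrium
  mass concentration ``S`` in g per litre of solvent,
* molar volumes in m^3/mol, enthalpies in J/mol.

The bundled empagliflozin dataset (24 points, four isotherms 308-338 K at
12-27 MPa) and the solute/solvent property record ship as packaged CSV/YAML
files and are exposed through :func:`empagliflozin_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "R_GAS",
    "SolubilityRecord",
    "SolubilityDataset",
    "SoluteProperties",
    "SolventProperties",
    "SyntheticSpec",
    "y2_from_counts",
    "s_from_y2",
    "y2_from_s",
    "reduced_state",
    "load_dataset",
    "save_dataset",
    "load_properties",
    "empagliflozin_fixture",
    "generate_synthetic",
]

#: Universal gas constant, J/(mol K).  8.314 matches the enthalpy arithmetic
#: used for the Chrastil/Bartle temperature coefficients to the printed digit.
R_GAS = 8.314

_REQUIRED_COLUMNS = ("T_K", "P_MPa", "rho_kg_m3")
_KNOWN_COLUMNS = ("T_K", "P_MPa", "rho_kg_m3", "y2", "sd_y2", "S_g_L")


class DataValidationError(ValueError):
    """Raised when a record or CSV file violates the dataset contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolubilityRecord:
    """A single measured equilibrium point.

    Attributes
    ----------
    T : float
        Temperature, K.
    P : float
        Pressure, MPa.
    rho1 : float
        Solvent (CO2) density, kg/m^3.
    y2 : float
        Mole-fraction solubility of the solute.
    S : float, optional
        Equilibrium mass concentration, g/L.
    sd_y2 : float, optional
        Experimental standard deviation of ``y2``.
    """

    T: float
    P: float
    rho1: float
    y2: float
    S: float | None = None
    sd_y2: float | None = None

    def __post_init__(self) -> None:
        if not (self.T > 0 and self.P > 0 and self.rho1 > 0):
            raise DataValidationError(
                f"T, P, rho1 must be positive, got ({self.T}, {self.P}, {self.rho1})"
            )
        if not (0 < self.y2 < 1):
            raise DataValidationError(f"y2 must lie in (0, 1), got {self.y2}")
        if self.S is not None and self.S <= 0:
            raise DataValidationError(f"S must be positive when given, got {self.S}")


@dataclass
class SolubilityDataset:
    """Ordered collection of solubility records for one solute."""

    records: list[SolubilityRecord]
    solute_id: str = ""
    source: str = ""
    extra: pd.DataFrame | None = None  # unrecognized CSV columns, row-aligned

    def __post_init__(self) -> None:
        if not self.records:
            raise DataValidationError("no records")
        seen: set[tuple[float, float]] = set()
        for i, rec in enumerate(self.records):
            key = (rec.T, rec.P)
            if key in seen:
                raise DataValidationError(f"duplicate (T, P) = {key} at record {i}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolubilityRecord]:
        return iter(self.records)

    @property
    def T(self) -> np.ndarray:
        return np.array([r.T for r in self.records])

    @property
    def P(self) -> np.ndarray:
        return np.array([r.P for r in self.records])

    @property
    def rho1(self) -> np.ndarray:
        return np.array([r.rho1 for r in self.records])

    @property
    def y2(self) -> np.ndarray:
        return np.array([r.y2 for r in self.records])

    def temperatures(self) -> np.ndarray:
        """Distinct temperatures, ascending."""
        return np.unique(self.T)

    def isotherm(self, T: float, atol: float = 1e-9) -> "SolubilityDataset":
        recs = [r for r in self.records if abs(r.T - T) <= atol]
        if not recs:
            raise KeyError(f"no records at T = {T} K")
        return SolubilityDataset(recs, self.solute_id, f"{self.source} [T={T} K]")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "T_K": self.T,
                "P_MPa": self.P,
                "rho_kg_m3": self.rho1,
                "y2": self.y2,
                "sd_y2": [r.sd_y2 for r in self.records],
                "S_g_L": [r.S for r in self.records],
            }
        )
        if self.extra is not None:
            frame = pd.concat([frame, self.extra.reset_index(drop=True)], axis=1)
        return frame


@dataclass(frozen=True)
class SoluteProperties:
    """Physical constants of the solid solute.

    ``Vs`` is the solid molar volume used in the EoS Poynting correction;
    ``V2`` is the (distinct) solute molar volume used by the Wilson activity
    model.  ``Psub`` maps temperature (K) to sublimation pressure (Pa).
    """

    M: float
    Tm: float
    dHm: float
    Tc: float
    Pc: float
    omega: float
    Vs: float
    V2: float
    Psub: Mapping[float, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("M", "Tm", "dHm", "Tc", "Pc", "omega", "Vs", "V2"):
            if getattr(self, attr) <= 0:
                raise DataValidationError(f"{attr} must be positive")
        if self.Tm >= self.Tc:
            raise DataValidationError("Tm must be below Tc")
        ts = sorted(self.Psub)
        ps = [self.Psub[t] for t in ts]
        if any(p2 <= p1 for p1, p2 in zip(ps, ps[1:])):
            raise DataValidationError("Psub must be strictly increasing in T")

    def sublimation_pressure(self, T: float) -> float:
        """Sublimation pressure (Pa) at ``T`` by ln(Psub) vs 1/T interpolation.

        Only the tabulated temperature range is certified; extrapolation
        raises ``ValueError``.
        """
        if not self.Psub:
            raise ValueError("no sublimation-pressure table available")
        ts = sorted(self.Psub)
        if not (ts[0] <= T <= ts[-1]):
            raise ValueError(
                f"T={T} K outside tabulated sublimation range [{ts[0]}, {ts[-1]}] K"
            )
        if T in self.Psub:
            return float(self.Psub[T])
        # ln P linear in 1/T (Clausius-Clapeyron); np.interp needs ascending x
        inv_t = np.array([1.0 / t for t in ts])[::-1]
        ln_p = np.log([self.Psub[t] for t in ts])[::-1]
        return float(math.exp(np.interp(1.0 / T, inv_t, ln_p)))


@dataclass(frozen=True)
class SolventProperties:
    """Solvent (CO2) molecular weight, critical constants and acentric factor."""

    M: float
    Tc: float
    Pc: float
    rho_c: float
    omega: float
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("M", "Tc", "Pc", "rho_c", "omega"):
            if getattr(self, attr) <= 0:
                raise DataValidationError(f"{attr} must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a model-generated dataset with multiplicative lognormal noise."""

    model_name: str
    true_params: Sequence[float]
    conditions: Sequence[tuple[float, float, float]]  # (T, P, rho1)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise DataValidationError("noise_cv must be non-negative")
        if not self.conditions:
            raise DataValidationError("conditions must be non-empty")


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------


def y2_from_counts(
    Cs: float,
    Vs_vial: float,
    V_loop: float,
    rho: float,
    M_solute: float,
    M_co2: float,
) -> float:
    """Mole fraction from the sampling mass balance.

    ``n_drug = Cs*Vs_vial/M_solute`` and ``n_CO2 = V_loop*rho/M_co2``; the
    caller must supply mass-consistent units (volumes in L with Cs in g/L and
    rho in kg/m^3 = g/L works).  ``Cs = 0`` is allowed and gives ``y2 = 0``.
    """
    if Cs < 0:
        raise DataValidationError("Cs must be non-negative")
    for name, val in (("Vs_vial", Vs_vial), ("V_loop", V_loop), ("rho", rho),
                      ("M_solute", M_solute), ("M_co2", M_co2)):
        if val <= 0:
            raise DataValidationError(f"{name} must be positive, got {val}")
    n_drug = Cs * Vs_vial / M_solute
    n_co2 = V_loop * rho / M_co2
    return n_drug / (n_drug + n_co2)


def s_from_y2(y2: float, rho: float, M_solute: float, M_co2: float) -> float:
    """Mass concentration S (g/L) from mole fraction: S = rho*(M2/M1)*y2/(1-y2)."""
    if not 0 <= y2 < 1:
        raise DataValidationError(f"y2 must lie in [0, 1), got {y2}")
    return rho * (M_solute / M_co2) * y2 / (1.0 - y2)


def y2_from_s(S: float, rho: float, M_solute: float, M_co2: float) -> float:
    """Exact algebraic inverse of :func:`s_from_y2`."""
    if S < 0:
        raise DataValidationError(f"S must be non-negative, got {S}")
    q = S * M_co2 / (rho * M_solute)
    return q / (1.0 + q)


def reduced_state(T, rho, solvent: SolventProperties):
    """Reduced temperature and density ``(T/Tc, rho/rho_c)`` of the solvent."""
    return np.asarray(T) / solvent.Tc, np.asarray(rho) / solvent.rho_c


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def load_dataset(
    path,
    solute: SoluteProperties | None = None,
    solvent: SolventProperties | None = None,
    solute_id: str = "",
) -> SolubilityDataset:
    """Read a solubility CSV (headers ``T_K, P_MPa, rho_kg_m3`` and ``y2``
    and/or ``S_g_L``; optional ``sd_y2``; extra columns preserved).

    If only ``S_g_L`` is present, ``solute`` and ``solvent`` must be given so
    mole fractions can be derived through the concentration relation.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"{path}: no records") from None
    if frame.empty:
        raise DataValidationError(f"{path}: no records")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required column(s) {missing}")
    if "y2" not in frame.columns and "S_g_L" not in frame.columns:
        raise DataValidationError(f"{path}: needs a 'y2' or 'S_g_L' column")
    if "y2" not in frame.columns and (solute is None or solvent is None):
        raise DataValidationError(
            f"{path}: converting S to mole fraction requires solute and solvent properties"
        )

    numeric_cols = [c for c in _KNOWN_COLUMNS if c in frame.columns]
    for col in numeric_cols:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise DataValidationError(
                f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        frame[col] = parsed

    records = []
    for i, row in frame.iterrows():
        s_val = row.get("S_g_L")
        s_val = None if s_val is None or pd.isna(s_val) else float(s_val)
        if "y2" in frame.columns and not pd.isna(row["y2"]):
            y2 = float(row["y2"])
        else:
            y2 = y2_from_s(s_val, float(row["rho_kg_m3"]), solute.M, solvent.M)
        sd = row.get("sd_y2")
        sd = None if sd is None or pd.isna(sd) else float(sd)
        try:
            records.append(
                SolubilityRecord(
                    T=float(row["T_K"]), P=float(row["P_MPa"]),
                    rho1=float(row["rho_kg_m3"]), y2=y2, S=s_val, sd_y2=sd,
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path}: row {i + 2}: {exc}") from None

    extra_cols = [c for c in frame.columns if c not in _KNOWN_COLUMNS]
    extra = frame[extra_cols].copy() if extra_cols else None
    try:
        return SolubilityDataset(records, solute_id=solute_id or path.stem,
                                 source=str(path), extra=extra)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from None


def save_dataset(dataset: SolubilityDataset, path) -> None:
    """Write a dataset back to CSV, preserving any extra columns."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False)


def load_properties(path) -> tuple[SoluteProperties, SolventProperties]:
    """Read a solute/solvent property YAML (same layout as the bundled fixture)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sol = dict(raw["solute"])
    sol["Psub"] = {float(k): float(v) for k, v in sol.get("Psub", {}).items()}
    solvent = dict(raw["solvent"])
    return (
        SoluteProperties(**sol),
        SolventProperties(**solvent),
    )


# ---------------------------------------------------------------------------
# bundled fixture
# ---------------------------------------------------------------------------


def _fixture_path(name: str):
    return resources.files("sco2sol") / "fixtures" / name


def empagliflozin_fixture() -> tuple[SolubilityDataset, SoluteProperties, SolventProperties]:
    """The bundled empagliflozin-in-ScCO2 dataset and property records.

    24 measured points (308-338 K, 12-27 MPa) with NIST CO2 densities, plus
    the solute constants from group-contribution estimates.  Mole fractions
    are stored on the absolute scale (5.14e-6 ... 25.9e-6).
    """
    with resources.as_file(_fixture_path("empagliflozin_properties.yaml")) as p:
        solute, solvent = load_properties(p)
    with resources.as_file(_fixture_path("empagliflozin_solubility.csv")) as p:
        dataset = load_dataset(p, solute=solute, solvent=solvent,
                               solute_id="empagliflozin")
    return dataset, solute, solvent


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------


def generate_synthetic(spec: SyntheticSpec, registry=None) -> SolubilityDataset:
    """Model-generated isotherms with multiplicative lognormal noise.

    ``y2 = model(true_params, T, P, rho1) * exp(eps)`` with
    ``eps ~ Normal(0, noise_cv)``: solubility is strictly positive and model
    residuals are judged in relative terms, so relative noise is the natural
    corruption.  Reproducible for a fixed ``spec.seed``.
    """
    from . import density_models  # deferred: registry lives with the models

    if registry is None:
        registry = density_models.MODEL_REGISTRY
    try:
        model = registry[spec.model_name]
    except KeyError:
        raise KeyError(f"unknown model {spec.model_name!r}") from None
    if len(spec.true_params) != model.n_params:
        raise DataValidationError(
            f"{spec.model_name} expects {model.n_params} parameters, "
            f"got {len(spec.true_params)}"
        )
    _, solute, solvent = empagliflozin_fixture()
    rng = np.random.default_rng(spec.seed)
    records = []
    for (T, P, rho1) in spec.conditions:
        y_true = float(
            model.evaluate(np.asarray(spec.true_params, dtype=float),
                           np.array([T]), np.array([P]), np.array([rho1]),
                           solute, solvent)[0]
        )
        y_noisy = y_true * math.exp(rng.normal(0.0, spec.noise_cv)) if spec.noise_cv > 0 else y_true
        records.append(SolubilityRecord(T=T, P=P, rho1=rho1, y2=y_noisy))
    return SolubilityDataset(
        records,
        solute_id=f"synthetic:{spec.model_name}",
        source=f"generate_synthetic(seed={spec.seed}, noise_cv={spec.noise_cv})",
    )
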