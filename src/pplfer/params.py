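"""Domain types, physical constants and the built-in system-parameter registry.

The package predicts six physical-chemical properties of neutral organic
solutes — the octanol-water (wet and dry), air-water and octanol-air partition
ratios, liquid vapor pressure, and liquid-state solubility in water and octanol
— from Abraham solute descriptors using poly-parameter linear free energy
relationships (PPLFERs).  A PPLFER is a linear model

    log K = s*S + a*A + b*B + v*V + l*L + c                     (partitioning)
    log S = s*S + a*A + b*B + d*sqrt(A*B) + v*V + l*L + c       (pure phase)

whose lower-case system parameters are specific to the two phases of the
endpoint and whose upper-case solute descriptors are specific to the chemical.

This module holds the dataclasses shared by the rest of the package and the
registry of calibrated and thermodynamic-cycle-derived system parameters for
the nine supported endpoints, bundled as a versioned YAML resource.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "Endpoint",
    "State",
    "PARTITION_ENDPOINTS",
    "SOLUBILITY_ENDPOINTS",
    "ENDPOINT_UNITS",
    "PhysicalConstants",
    "CONSTANTS",
    "SoluteDescriptors",
    "SystemParameters",
    "ThermalProperties",
    "PropertyPrediction",
    "EvaluationRecord",
    "builtin_system_parameters",
    "builtin_registry",
    "load_registry",
    "save_registry",
]


class Endpoint(str, Enum):
    """Supported PPLFER endpoints.

    Partition ratios are log10 of a dimensionless concentration ratio;
    solubilities are log10(mol/L); vapor pressure is log10(Pa).  ``SA``
    (solubility in air) is a unit conversion of vapor pressure and has no
    system parameters of its own.
    """

    KAW = "KAW"
    KOA = "KOA"
    KOW_WET = "KOW_wet"
    KOW_DRY = "KOW_dry"
    KOO = "KOO"
    VP_LIQUID = "VP_liquid"
    SW_LIQUID = "SW_liquid"
    SO_DRY_LIQUID = "SO_dry_liquid"
    SO_WET_LIQUID = "SO_wet_liquid"
    SA = "SA"


PARTITION_ENDPOINTS = frozenset(
    {Endpoint.KAW, Endpoint.KOA, Endpoint.KOW_WET, Endpoint.KOW_DRY, Endpoint.KOO}
)
#: Endpoints whose equation carries the d*sqrt(A*B) pure-phase term.
SOLUBILITY_ENDPOINTS = frozenset(
    {
        Endpoint.VP_LIQUID,
        Endpoint.SW_LIQUID,
        Endpoint.SO_DRY_LIQUID,
        Endpoint.SO_WET_LIQUID,
    }
)

DIMENSIONLESS = "log10(dimensionless ratio)"
UNITS_PA = "log10(Pa)"
UNITS_MOLAR = "log10(mol/L)"

ENDPOINT_UNITS = {
    Endpoint.KAW: DIMENSIONLESS,
    Endpoint.KOA: DIMENSIONLESS,
    Endpoint.KOW_WET: DIMENSIONLESS,
    Endpoint.KOW_DRY: DIMENSIONLESS,
    Endpoint.KOO: DIMENSIONLESS,
    Endpoint.VP_LIQUID: UNITS_PA,
    Endpoint.SW_LIQUID: UNITS_MOLAR,
    Endpoint.SO_DRY_LIQUID: UNITS_MOLAR,
    Endpoint.SO_WET_LIQUID: UNITS_MOLAR,
    Endpoint.SA: UNITS_MOLAR,
}


class State(str, Enum):
    """Predicted physical state of the pure chemical at system temperature."""

    GAS = "gas"
    LIQUID = "liquid"
    MAYBE_SOLID = "maybe_solid"
    SOLID = "solid"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable physical constants used throughout the package."""

    R: float = 8.314  # ideal gas constant, Pa m^3 / (mol K)  (== J / (mol K))
    T_default: float = 298.15  # K
    P_atm: float = 101325.0  # Pa
    z95: float = 1.96  # two-sided 95% normal quantile


CONSTANTS = PhysicalConstants()

LN10 = math.log(10.0)

COEFFICIENT_NAMES = ("s", "a", "b", "d", "v", "l", "c")


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"descriptor {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class SoluteDescriptors:
    """Abraham solute descriptors for one neutral solute.

    S: dipolarity/polarizability; A: hydrogen-bond donor capacity;
    B: hydrogen-bond acceptor capacity; V: McGowan volume (cm^3/mol / 100);
    L: log hexadecane-air partition coefficient.
    """

    S: float
    A: float
    B: float
    V: float
    L: float

    def __post_init__(self) -> None:
        for name in ("S", "A", "B", "V", "L"):
            _require_finite(name, getattr(self, name))
        if self.A < 0:
            raise ValueError(f"descriptor 'A' must be >= 0, got {self.A}")
        if self.B < 0:
            raise ValueError(f"descriptor 'B' must be >= 0, got {self.B}")
        # V = 0 is admitted for the degenerate all-zero (intercept-only)
        # descriptor set; any real solute has V > 0.
        if self.V < 0:
            raise ValueError(f"descriptor 'V' must be >= 0, got {self.V}")


@dataclass(frozen=True)
class SystemParameters:
    """PPLFER system parameters and standard errors for one endpoint.

    ``d`` is the coefficient of the sqrt(A*B) pure-phase hydrogen-bonding
    term; it is stored as 0 with zero standard error for partition endpoints
    so every endpoint shares one evaluation path.
    """

    endpoint: Endpoint
    s: float
    a: float
    b: float
    v: float
    l: float
    c: float
    d: float = 0.0
    se_s: float = 0.0
    se_a: float = 0.0
    se_b: float = 0.0
    se_d: float = 0.0
    se_v: float = 0.0
    se_l: float = 0.0
    se_c: float = 0.0
    total_se: float = 0.0
    units: str = DIMENSIONLESS

    def __post_init__(self) -> None:
        for name in COEFFICIENT_NAMES:
            _require_finite(name, getattr(self, name))
        for name in COEFFICIENT_NAMES:
            se = getattr(self, f"se_{name}")
            if se < 0 or not math.isfinite(se):
                raise ValueError(f"se_{name} must be finite and >= 0, got {se}")
        if self.total_se < 0 or not math.isfinite(self.total_se):
            raise ValueError(f"total_se must be finite and >= 0, got {self.total_se}")
        if self.endpoint in PARTITION_ENDPOINTS and (self.d != 0.0 or self.se_d != 0.0):
            raise ValueError(
                f"partition endpoint {self.endpoint.value} must have d = se_d = 0"
            )

    def coefficients(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COEFFICIENT_NAMES}

    def standard_errors(self) -> dict[str, float]:
        return {name: getattr(self, f"se_{name}") for name in COEFFICIENT_NAMES}


@dataclass(frozen=True)
class ThermalProperties:
    """Melting/boiling temperatures, entropy of fusion and liquid molar volume.

    All fields optional; consumers fall back to rule defaults (flagged) or to
    the ``unknown`` state when data are absent.  MV is in L/mol because the
    solubility cap is the molarity of the pure liquid, 1/MV.
    """

    T_M: Optional[float] = None  # K
    T_B: Optional[float] = None  # K
    dS_M: Optional[float] = None  # J / (mol K)
    MV: Optional[float] = None  # L / mol

    def __post_init__(self) -> None:
        if self.T_M is not None and self.T_B is not None and not self.T_M < self.T_B:
            raise ValueError(f"require T_M < T_B, got T_M={self.T_M}, T_B={self.T_B}")
        if self.MV is not None and not self.MV > 0:
            raise ValueError(f"MV must be > 0, got {self.MV}")
        if self.dS_M is not None and not self.dS_M > 0:
            raise ValueError(f"dS_M must be > 0, got {self.dS_M}")


#: Provenance flags attached to predictions.
FLAG_CAPPED = "capped"
FLAG_VANT_HOFF = "vant_hoff_applied"
FLAG_INTERCEPT_ONLY = "intercept_only"
FLAG_UNCALIBRATED = "uncalibrated_substructure"
FLAG_MV_FALLBACK = "mv_fallback"
FLAG_DEFAULT_DSM = "default_dS_M"


@dataclass(frozen=True)
class PropertyPrediction:
    """One endpoint prediction with its uncertainty bookkeeping.

    ``rmsep`` is the adjusted root-mean-squared error of prediction used to
    build the symmetric 95% prediction interval [pi_low, pi_high].
    """

    endpoint: Endpoint
    value: float
    ul: int
    rmsep: float
    pi_low: float
    pi_high: float
    state: State = State.UNKNOWN
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.ul <= 6:
            raise ValueError(f"ul must be in 0..6, got {self.ul}")
        if not (self.pi_low <= self.value <= self.pi_high):
            raise ValueError("require pi_low <= value <= pi_high")
        if not math.isclose(
            self.pi_high - self.value, self.value - self.pi_low,
            rel_tol=1e-9, abs_tol=1e-9,
        ):
            raise ValueError("prediction interval must be symmetric about value")

    def with_(self, **changes) -> "PropertyPrediction":
        return replace(self, **changes)


@dataclass(frozen=True)
class EvaluationRecord:
    """Experimental/predicted pair for validation statistics."""

    id: str
    y_exp: float
    y_pred: float
    ul: int
    state: State = State.UNKNOWN
    endpoint: Optional[Endpoint] = None
    membership: Optional[str] = None  # training | validation | external
    pKa_acid: Optional[float] = None
    pKa_base: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.y_exp) and math.isfinite(self.y_pred)):
            raise ValueError(f"record {self.id!r}: y values must be finite")
        if not 0 <= self.ul <= 6:
            raise ValueError(f"record {self.id!r}: ul must be in 0..6, got {self.ul}")

    @property
    def residual(self) -> float:
        return self.y_exp - self.y_pred


# ---------------------------------------------------------------------------
# Registry (de)serialization
# ---------------------------------------------------------------------------

_REGISTRY_RESOURCE = "system_parameters.yaml"
_REGISTRY_SCHEMA = 1


def _params_to_dict(sp: SystemParameters) -> dict:
    return {
        "coef": {k: float(v) for k, v in sp.coefficients().items()},
        "se": {k: float(v) for k, v in sp.standard_errors().items()},
        "total_se": float(sp.total_se),
        "units": sp.units,
    }


def _params_from_dict(endpoint: Endpoint, entry: dict) -> SystemParameters:
    coef = entry["coef"]
    se = entry.get("se", {})
    return SystemParameters(
        endpoint=endpoint,
        units=entry.get("units", ENDPOINT_UNITS[endpoint]),
        total_se=float(entry.get("total_se", 0.0)),
        **{k: float(coef.get(k, 0.0)) for k in COEFFICIENT_NAMES},
        **{f"se_{k}": float(se.get(k, 0.0)) for k in COEFFICIENT_NAMES},
    )


def save_registry(registry: dict[Endpoint, SystemParameters], path: str | Path) -> None:
    """Write a parameter registry to YAML (schema-versioned)."""
    doc = {
        "schema_version": _REGISTRY_SCHEMA,
        "endpoints": {ep.value: _params_to_dict(sp) for ep, sp in registry.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_registry(path: str | Path | None = None) -> dict[Endpoint, SystemParameters]:
    """Load a parameter registry from YAML; default is the bundled resource."""
    if path is None:
        text = (
            resources.files("pplfer").joinpath("data", _REGISTRY_RESOURCE).read_text()
        )
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc.get("schema_version") != _REGISTRY_SCHEMA:
        raise ValueError(f"unsupported registry schema: {doc.get('schema_version')!r}")
    registry = {}
    for name, entry in doc["endpoints"].items():
        try:
            endpoint = Endpoint(name)
        except ValueError as exc:
            raise ValueError(f"unknown endpoint {name!r} in registry") from exc
        registry[endpoint] = _params_from_dict(endpoint, entry)
    return registry


_BUILTIN_CACHE: dict[Endpoint, SystemParameters] | None = None


def builtin_registry() -> dict[Endpoint, SystemParameters]:
    """The bundled registry of the nine calibrated/derived endpoints."""
    global _BUILTIN_CACHE
    if _BUILTIN_CACHE is None:
        _BUILTIN_CACHE = load_registry(None)
    return dict(_BUILTIN_CACHE)


def builtin_system_parameters(endpoint: Endpoint | str) -> SystemParameters:
    """Return the bundled system parameters for one endpoint.

    Derived endpoints (dry K_OW, K_OO and both octanol solubilities) are
    stored at the published 2-decimal precision; they reproduce their
    thermodynamic-cycle derivation from the calibrated rows to that rounding
    (see :func:`pplfer.cycles.check_cycle_consistency`).
    """
    try:
        endpoint = Endpoint(endpoint)
    except ValueError as exc:
        raise KeyError(f"unknown endpoint: {endpoint!r}") from exc
    registry = builtin_registry()
    if endpoint not in registry:
        raise KeyError(f"no bundled system parameters for endpoint {endpoint.value!r}")
    return registry[endpoint]
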