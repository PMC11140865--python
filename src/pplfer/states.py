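"""Physical state classification, Van't Hoff solid correction, boundary caps.

Fate and transport models treat all chemicals as (supercooled) liquids, so
the PPLFER equations predict liquid-state values.  For chemicals that are
solid at system temperature the liquid value can be converted to the solid
value with the Van't Hoff approximation

    log X_solid = log X_liquid - dS_M * (T_M - T) / (ln 10 * R * T)

using the entropy of fusion dS_M and melting point T_M.  State at system
temperature is decided by a transparent threshold rule on T_M and T_B with a
configurable ``maybe_solid`` band around T_M ~ T.

Predictions of solubility and vapor pressure are bounded: a solubility
cannot exceed the molarity of the pure liquid (1/MV) and an environmental
vapor pressure cannot exceed atmospheric pressure.  Predictions beyond these
bounds are capped, flagged and assigned uncertainty level 6 while retaining
the RMSEP of the uncertainty level they originally received.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import (
    CONSTANTS,
    FLAG_CAPPED,
    LN10,
    Endpoint,
    PropertyPrediction,
    State,
    ThermalProperties,
)

__all__ = [
    "StateConfig",
    "classify_state",
    "vant_hoff_correct",
    "apply_caps",
    "solubility_cap",
    "VP_CAP",
]


@dataclass(frozen=True)
class StateConfig:
    """Tunable rule thresholds and defaults for state handling.

    system_T_K: system temperature (default 25 C).
    state_margin_K: half-width of the maybe-solid band around T_M = T.
    default_dS_M: Walden's-rule entropy of fusion used when dS_M is missing
        (56.5 J/(mol K)), always flagged.
    enable_MV_fallback: allow estimating a missing molar volume as
        mv_per_mcgowan * V (L/mol per McGowan volume unit), always flagged.
    """

    system_T_K: float = CONSTANTS.T_default
    state_margin_K: float = 10.0
    default_dS_M: float = 56.5
    enable_MV_fallback: bool = False
    mv_per_mcgowan: float = 1.27


def classify_state(
    tp: ThermalProperties,
    T: float = CONSTANTS.T_default,
    margin: float = 10.0,
) -> State:
    """Rule-based state at temperature ``T``.

    gas if T_B <= T; solid if T_M >= T + margin; maybe_solid if
    |T_M - T| < margin; liquid if T_M <= T - margin and T_B is known to
    exceed T; unknown when the deciding inputs are absent.  Total: never
    raises for a valid ThermalProperties.
    """
    if T <= 0:
        raise ValueError(f"T must be > 0 K, got {T}")
    if tp.T_B is not None and tp.T_B <= T:
        return State.GAS
    if tp.T_M is None:
        return State.UNKNOWN
    if tp.T_M >= T + margin:
        return State.SOLID
    if abs(tp.T_M - T) < margin:
        return State.MAYBE_SOLID
    # T_M well below T: liquid, provided we know it does not boil below T.
    if tp.T_B is not None:
        return State.LIQUID
    return State.UNKNOWN


def vant_hoff_correct(
    log_value_liquid: float,
    dS_M: float,
    T_M: float,
    T: float = CONSTANTS.T_default,
    direction: str = "liquid_to_solid",
) -> float:
    """Van't Hoff conversion between liquid and solid-phase log values.

    For T_M > T the solid value is lower by dS_M*(T_M - T)/(ln10 * R * T);
    for T_M <= T the chemical is liquid at T and the value is unchanged.
    ``direction`` "solid_to_liquid" applies the inverse (sign-flipped)
    correction to a solid-phase input.
    """
    if dS_M <= 0:
        raise ValueError(f"dS_M must be > 0, got {dS_M}")
    if T <= 0:
        raise ValueError(f"T must be > 0 K, got {T}")
    if direction not in ("liquid_to_solid", "solid_to_liquid"):
        raise ValueError(f"unknown direction {direction!r}")
    if T_M <= T:
        return log_value_liquid
    correction = dS_M * (T_M - T) / (LN10 * CONSTANTS.R * T)
    if direction == "liquid_to_solid":
        return log_value_liquid - correction
    return log_value_liquid + correction


#: Cap for vapor pressure predictions: standard atmospheric pressure.
VP_CAP = math.log10(CONSTANTS.P_atm)

_SOLUBILITY_ENDPOINTS = {
    Endpoint.SW_LIQUID,
    Endpoint.SO_DRY_LIQUID,
    Endpoint.SO_WET_LIQUID,
}
_CAPPABLE = _SOLUBILITY_ENDPOINTS | {Endpoint.VP_LIQUID}


def solubility_cap(MV: float) -> float:
    """log10 of the molarity of the pure liquid, 1/MV (MV in L/mol)."""
    if MV <= 0:
        raise ValueError(f"MV must be > 0 L/mol, got {MV}")
    return -math.log10(MV)


def apply_caps(pred: PropertyPrediction, tp: ThermalProperties) -> PropertyPrediction:
    """Cap a VP or solubility prediction at its physical upper bound.

    Capped predictions keep the RMSEP (and so the interval half-width) of
    their pre-cap uncertainty level; the interval is re-centered on the
    capped value.  Idempotent; predictions at or below the cap pass through
    unchanged.
    """
    if pred.endpoint not in _CAPPABLE:
        raise ValueError(
            f"apply_caps handles VP and solubility endpoints, got {pred.endpoint.value}"
        )
    if pred.endpoint is Endpoint.VP_LIQUID:
        cap = VP_CAP
    else:
        if tp.MV is None:
            raise ValueError(
                f"solubility cap for {pred.endpoint.value} requires MV"
            )
        cap = solubility_cap(tp.MV)
    if pred.value <= cap:
        return pred
    half_width = pred.pi_high - pred.value
    return pred.with_(
        value=cap,
        ul=6,
        pi_low=cap - half_width,
        pi_high=cap + half_width,
        flags=pred.flags | {FLAG_CAPPED},
    )
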