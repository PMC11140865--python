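"""Evaluation of PPLFER equations and the Raoult's-law vapor-pressure route.

Partition ratios use the six-term equation

    log K = s*S + a*A + b*B + v*V + l*L + c

and pure-phase endpoints (vapor pressure and the three solubilities) add a
hydrogen-bonding self-interaction term d*sqrt(A*B), which accounts for
hydrogen bonds between molecules of the chemical in its own pure phase.

The indirect vapor-pressure route predicts the partitioning of a solute
between air and its own pure liquid phase (log K_kAk) from per-solute system
parameters and converts it to VP by rearranging Raoult's law:

    log VP = log10( R*T / (gamma * K_kAk * MV) )

with gamma the activity coefficient (unity in the pure phase) and MV the
liquid molar volume.  VP converts to solubility in air S_A by the ideal gas
law at the same temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .params import (
    CONSTANTS,
    PARTITION_ENDPOINTS,
    SOLUBILITY_ENDPOINTS,
    SoluteDescriptors,
    State,
    SystemParameters,
)

__all__ = [
    "KkAkParameters",
    "IndirectSolidWarning",
    "evaluate_partition",
    "evaluate_solubility",
    "evaluate",
    "evaluate_kkak",
    "vp_from_kkak",
    "vp_to_sa",
]


@dataclass(frozen=True)
class KkAkParameters:
    """Per-solute system parameters for the solute's own liquid phase vs air.

    These come from empirical regressions of solvent-air system parameters on
    solute descriptors (calibrated in prior work); the six coefficients are
    accepted at the interface rather than re-fit here.
    """

    s: float
    a: float
    b: float
    v: float
    l: float
    c: float

    def __post_init__(self) -> None:
        for name in ("s", "a", "b", "v", "l", "c"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"KkAk coefficient {name!r} must be finite")


class IndirectSolidWarning(UserWarning):
    """The indirect VP route is only validated for liquids."""


def _linear_terms(sp, sd: SoluteDescriptors) -> float:
    return sp.s * sd.S + sp.a * sd.A + sp.b * sd.B + sp.v * sd.V + sp.l * sd.L + sp.c


def evaluate_partition(sp: SystemParameters, sd: SoluteDescriptors) -> float:
    """log K for a partition endpoint: s*S + a*A + b*B + v*V + l*L + c."""
    if sp.endpoint not in PARTITION_ENDPOINTS:
        raise ValueError(
            f"{sp.endpoint.value} is not a partition endpoint; "
            "use evaluate_solubility"
        )
    return _linear_terms(sp, sd)


def evaluate_solubility(sp: SystemParameters, sd: SoluteDescriptors) -> float:
    """log S (or log VP) for a pure-phase endpoint, including d*sqrt(A*B)."""
    if sp.endpoint not in SOLUBILITY_ENDPOINTS:
        raise ValueError(
            f"{sp.endpoint.value} is not a solubility/VP endpoint; "
            "use evaluate_partition"
        )
    # SoluteDescriptors enforces A, B >= 0, so the sqrt is always defined.
    return _linear_terms(sp, sd) + sp.d * math.sqrt(sd.A * sd.B)


def evaluate(sp: SystemParameters, sd: SoluteDescriptors) -> float:
    """Dispatch to the partition or pure-phase equation by endpoint."""
    if sp.endpoint in PARTITION_ENDPOINTS:
        return evaluate_partition(sp, sd)
    return evaluate_solubility(sp, sd)


def evaluate_kkak(kp: KkAkParameters, sd: SoluteDescriptors) -> float:
    """log K_kAk: partitioning between air and the solute's own liquid phase."""
    return kp.s * sd.S + kp.a * sd.A + kp.b * sd.B + kp.v * sd.V + kp.l * sd.L + kp.c


def vp_from_kkak(
    log_kkak: float,
    MV: float,
    T: float = CONSTANTS.T_default,
    gamma: float = 1.0,
    state: State | None = None,
) -> float:
    """Raoult's-law vapor pressure (log10 Pa) from log K_kAk.

    Parameters
    ----------
    log_kkak : partition ratio between air and the pure liquid phase (log10).
    MV : liquid molar volume in L/mol (converted to m^3/mol internally).
    T : temperature in K.
    gamma : activity coefficient of the solute in its pure phase (default 1).
    state : if given and solid/maybe-solid, an :class:`IndirectSolidWarning`
        is emitted — the indirect route is validated for liquids only.
    """
    if MV <= 0:
        raise ValueError(f"MV must be > 0 L/mol, got {MV}")
    if T <= 0:
        raise ValueError(f"T must be > 0 K, got {T}")
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if state in (State.SOLID, State.MAYBE_SOLID):
        warnings.warn(
            "indirect VP route applied to a predicted solid; results for "
            "solids are unreliable",
            IndirectSolidWarning,
            stacklevel=2,
        )
    mv_m3 = MV * 1e-3
    return math.log10(CONSTANTS.R * T) - math.log10(gamma) - log_kkak - math.log10(mv_m3)


def vp_to_sa(log_vp: float, T: float = CONSTANTS.T_default) -> float:
    """Convert log VP (log10 Pa) to solubility in air S_A (log10 mol/L).

    Ideal gas: S_A = P / (R*T) in mol/m^3, divided by 1000 for mol/L.
    """
    if T <= 0:
        raise ValueError(f"T must be > 0 K, got {T}")
    return log_vp - math.log10(1000.0 * CONSTANTS.R * T)
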