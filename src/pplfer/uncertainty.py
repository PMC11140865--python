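"""Applicability domain, uncertainty levels, aggregation, prediction intervals.

Three complementary applicability-domain (AD) checks grade how far a query
chemical sits from the training data of a fragment-count QSPR:

* leverage ``h = x^T (X^T X)^{-1} x`` — extrapolation from the training
  design X (hat-matrix diagonal for training rows);
* chemical similarity score (CSS) — mean similarity of the k nearest
  training rows under a count-vector Tanimoto (or cosine) similarity;
* a negative-domain check — atom/bond substructure codes present in the
  query but never seen in training.

They combine into an ordinal uncertainty level (UL):

    UL 0  in AD, no warnings
    UL 1  in AD, borderline leverage/CSS warning
    UL 2  out of AD, leverage/CSS warning
    UL 3  out of AD, egregious leverage extrapolation
    UL 4  prediction is intercept-only (all fragment counts zero)
    UL 5  uncalibrated atom/bond types (negative-domain hit)
    UL 6  boundary-cap violation — assigned downstream when a prediction is
          capped, never here

Meta-models that consume outputs of other QSPRs aggregate component RMSEPs
in quadrature and component ULs by maximum.  The 95% prediction interval is
M +/- 1.96 * adjusted RMSEP, where the adjustment ladder (global 1.25;
1.67 for VP of solids; 1.25 for S_W of solids; a further 1.25 for VP at UL
2/3/5) was calibrated so that the intervals cover at least 95% of external
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .params import CONSTANTS, Endpoint, State

__all__ = [
    "ADContext",
    "AdjustmentFactors",
    "RMSEPTable",
    "leverage",
    "css",
    "assign_ul",
    "aggregate_meta",
    "adjusted_rmsep",
    "prediction_interval",
]


@dataclass
class ADContext:
    """Training design and cut-offs for AD assessment.

    Leverage thresholds default to multiples of the mean training leverage
    p/n (1.5, 3 and 10 for warn / out / egregious); CSS thresholds default
    to 0.5 (warn) and 0.25 (out).  The cut-off scheme is fixed; the values
    are configuration.
    """

    training_design: np.ndarray
    leverage_warn: Optional[float] = None
    leverage_out: Optional[float] = None
    leverage_egregious: Optional[float] = None
    css_warn: float = 0.5
    css_out: float = 0.25
    known_substructures: frozenset = frozenset()
    similarity: str = "tanimoto"  # or "cosine"
    k_neighbours: int = 3

    def __post_init__(self) -> None:
        X = np.asarray(self.training_design, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("training_design must be a nonempty 2-D array")
        self.training_design = X
        n, p = X.shape
        if self.leverage_warn is None:
            self.leverage_warn = 1.5 * p / n
        if self.leverage_out is None:
            self.leverage_out = 3.0 * p / n
        if self.leverage_egregious is None:
            self.leverage_egregious = 10.0 * p / n
        if not (self.leverage_warn <= self.leverage_out <= self.leverage_egregious):
            raise ValueError("leverage thresholds must be ordered warn <= out <= egregious")
        if not (0 <= self.css_out <= self.css_warn <= 1):
            raise ValueError("CSS thresholds must satisfy 0 <= out <= warn <= 1")
        self.known_substructures = frozenset(self.known_substructures)
        self._xtx_inv = np.linalg.pinv(X.T @ X)

    def leverage_of(self, x: np.ndarray) -> float:
        return leverage(x, self.training_design, _xtx_inv=self._xtx_inv)

    def css_of(self, x: np.ndarray, k: Optional[int] = None) -> float:
        return css(x, self.training_design, k or self.k_neighbours,
                   metric=self.similarity)


def leverage(
    x: Sequence[float],
    training_design: np.ndarray,
    _xtx_inv: np.ndarray | None = None,
) -> float:
    """Hat-matrix leverage of ``x`` w.r.t. the training design.

    Uses the Moore-Penrose pseudo-inverse of X^T X, so rank-deficient
    designs degrade gracefully instead of failing.
    """
    X = np.asarray(training_design, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != (X.shape[1],):
        raise ValueError(
            f"feature vector has length {x.shape[0] if x.ndim else 'scalar'}, "
            f"training design has {X.shape[1]} columns"
        )
    if _xtx_inv is None:
        _xtx_inv = np.linalg.pinv(X.T @ X)
    return float(x @ _xtx_inv @ x)


def _tanimoto(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    # Generalised Tanimoto for nonnegative count vectors:
    # sum(min) / sum(max); 1 for identical rows, 0 for disjoint support.
    mins = np.minimum(x, Y).sum(axis=1)
    maxs = np.maximum(x, Y).sum(axis=1)
    out = np.zeros(len(Y))
    nz = maxs > 0
    out[nz] = mins[nz] / maxs[nz]
    return out


def _cosine(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xn = np.linalg.norm(x)
    yn = np.linalg.norm(Y, axis=1)
    out = np.zeros(len(Y))
    nz = (xn > 0) & (yn > 0)
    out[nz] = (Y[nz] @ x) / (yn[nz] * xn)
    return out


def css(
    x: Sequence[float],
    training_design: np.ndarray,
    k: int = 3,
    metric: str = "tanimoto",
) -> float:
    """Chemical similarity score: mean similarity of the k nearest rows."""
    X = np.asarray(training_design, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("training set must be a nonempty 2-D array")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    x = np.asarray(x, dtype=float)
    if x.shape != (X.shape[1],):
        raise ValueError("feature vector length does not match training design")
    if metric == "tanimoto":
        sims = _tanimoto(x, X)
    elif metric == "cosine":
        sims = _cosine(x, X)
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    k = min(k, len(sims))
    top = np.sort(sims)[-k:]
    return float(top.mean())


def assign_ul(
    leverage_value: float,
    css_value: float,
    ctx: ADContext,
    fragment_counts: Sequence[float],
    substructures: Iterable,
    bounds_violated: bool = False,
) -> int:
    """Combine AD diagnostics into an uncertainty level 0-5.

    Precedence: unseen substructures (UL 5) beat everything; intercept-only
    (UL 4) beats leverage/CSS grades; then egregious leverage (UL 3),
    out-of-AD warnings (UL 2), borderline warnings (UL 1), else UL 0.
    ``bounds_violated`` is accepted for completeness but does not change the
    result: UL 6 is assigned downstream when a prediction is capped.
    """
    if not frozenset(substructures) <= ctx.known_substructures:
        return 5
    counts = np.asarray(fragment_counts, dtype=float)
    if counts.size and not np.any(counts != 0):
        return 4
    if leverage_value > ctx.leverage_egregious:
        return 3
    if leverage_value > ctx.leverage_out or css_value < ctx.css_out:
        return 2
    if leverage_value > ctx.leverage_warn or css_value < ctx.css_warn:
        return 1
    return 0


def aggregate_meta(
    uls: Sequence[int],
    rmseps: Sequence[float],
    extra_se: Sequence[float] = (),
    ul4_in_ad: bool = True,
) -> tuple[int, float]:
    """Aggregate component ULs and RMSEPs for a meta-model prediction.

    RMSEPs (and any fixed extra standard errors, e.g. of system parameters
    written into the model) combine in quadrature.  The aggregate UL is the
    maximum component UL; with ``ul4_in_ad`` (default) an intercept-only
    component counts as in-AD (UL 0) unless every component is UL 4.
    """
    if len(uls) == 0 or len(rmseps) == 0:
        raise ValueError("aggregate_meta requires nonempty inputs")
    if any(not 0 <= u <= 6 for u in uls):
        raise ValueError("component ULs must be in 0..6")
    if any(r < 0 for r in rmseps) or any(s < 0 for s in extra_se):
        raise ValueError("RMSEPs and standard errors must be >= 0")
    rmsep = math.sqrt(sum(r * r for r in rmseps) + sum(s * s for s in extra_se))
    if ul4_in_ad and any(u != 4 for u in uls):
        effective = [0 if u == 4 else u for u in uls]
    else:
        effective = list(uls)
    return max(effective), rmsep


@dataclass(frozen=True)
class AdjustmentFactors:
    """Multiplicative RMSEP adjustments calibrated on external data.

    ``global_factor`` applies to every prediction; ``vp_solid`` / ``sw_solid``
    apply to vapor pressure / water solubility of chemicals identified as
    maybe or likely solids; ``vp_high_ul`` applies additionally to vapor
    pressure at the listed high uncertainty levels.
    """

    global_factor: float = 1.25
    vp_solid: float = 1.67
    sw_solid: float = 1.25
    vp_high_ul: float = 1.25
    high_uls: frozenset = frozenset({2, 3, 5})
    z: float = CONSTANTS.z95

    def __post_init__(self) -> None:
        for name in ("global_factor", "vp_solid", "sw_solid", "vp_high_ul"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


DEFAULT_FACTORS = AdjustmentFactors()
#: Factors with every adjustment disabled (bare 1.96 * RMSEP intervals).
UNADJUSTED = AdjustmentFactors(global_factor=1.0, vp_solid=1.0, sw_solid=1.0,
                               vp_high_ul=1.0)

_SOLIDISH = (State.MAYBE_SOLID, State.SOLID)


def adjusted_rmsep(
    rmsep: float,
    endpoint: Endpoint,
    ul: int,
    state: State,
    factors: AdjustmentFactors = DEFAULT_FACTORS,
) -> float:
    """Apply the adjustment ladder to an estimated RMSEP."""
    if rmsep < 0:
        raise ValueError(f"rmsep must be >= 0, got {rmsep}")
    out = rmsep * factors.global_factor
    if endpoint is Endpoint.VP_LIQUID and state in _SOLIDISH:
        out *= factors.vp_solid
    if endpoint is Endpoint.SW_LIQUID and state in _SOLIDISH:
        out *= factors.sw_solid
    if endpoint is Endpoint.VP_LIQUID and ul in factors.high_uls:
        out *= factors.vp_high_ul
    return out


def prediction_interval(
    M: float,
    rmsep: float,
    endpoint: Endpoint,
    ul: int = 0,
    state: State = State.UNKNOWN,
    factors: AdjustmentFactors = DEFAULT_FACTORS,
) -> tuple[float, float]:
    """Symmetric 95% prediction interval M -/+ 1.96 * adjusted RMSEP."""
    adj = adjusted_rmsep(rmsep, endpoint, ul, state, factors)
    return M - factors.z * adj, M + factors.z * adj


@dataclass
class RMSEPTable:
    """Estimated RMSEP per (endpoint, UL), with the adjustment factors.

    Lookups for UL 6 follow the boundary-cap convention: the RMSEP of the UL
    originally assigned to the prediction is used, so callers pass that
    original UL (the table itself holds ULs 0-5).  A per-endpoint fallback
    covers ULs without their own entry.
    """

    values: dict = field(default_factory=dict)  # (Endpoint, int) -> float
    fallback: dict = field(default_factory=dict)  # Endpoint -> float
    factors: AdjustmentFactors = DEFAULT_FACTORS

    def lookup(self, endpoint: Endpoint, ul: int) -> float:
        key = (endpoint, ul)
        if key in self.values:
            return self.values[key]
        if endpoint in self.fallback:
            return self.fallback[endpoint]
        raise KeyError(f"no RMSEP estimate for {endpoint.value} at UL {ul}")

    @classmethod
    def from_registry(cls, registry: Mapping,
                      factors: AdjustmentFactors = DEFAULT_FACTORS) -> "RMSEPTable":
        """Baseline table using each endpoint's total calibration s.e."""
        return cls(values={}, fallback={ep: sp.total_se for ep, sp in registry.items()},
                   factors=factors)
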