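"""Validation statistics: RMSEP, stratified tables, coverage calibration,
ionizable-chemical filtering.

The root mean squared error of prediction over an external dataset,

    RMSEP = sqrt( sum_i (y_i - yhat_i)^2 / n ),

is the package's predictivity metric and the basis of the 95% prediction
interval M +/- 1.96*RMSEP.  Validation tables stratify RMSEP, the percent of
experimental values falling inside their estimated interval, and counts by
uncertainty level, physical state or dataset membership.  When estimated
intervals undercover, a multiplicative adjustment factor is calibrated on a
geometric ladder (1, 1.25, 1.25^2, ...) until coverage reaches the target.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import CONSTANTS, Endpoint, EvaluationRecord, State

__all__ = [
    "rmsep",
    "stratified_stats",
    "calibrate_adjustments",
    "filter_ionizable",
]

STRONG_ACID_PKA = 4.0
STRONG_BASE_PKA = 10.0


def rmsep(records: Sequence[EvaluationRecord]) -> float:
    """Eq.-style RMSEP with divide-by-n (population form)."""
    if len(records) == 0:
        raise ValueError("rmsep requires at least one record")
    sq = [(r.y_exp - r.y_pred) ** 2 for r in records]
    return math.sqrt(sum(sq) / len(sq))


def _resolve_estimate(record: EvaluationRecord, estimates) -> float:
    """Estimated RMSEP for one record from a table/dict/callable/scalar.

    Dict keys may be (endpoint, ul) or plain ul.  UL-6 records follow the
    boundary-cap convention (the RMSEP of the originally assigned UL): the
    caller's table must carry an entry for them.
    """
    if callable(getattr(estimates, "lookup", None)):
        return estimates.lookup(record.endpoint, record.ul)
    if callable(estimates):
        return estimates(record)
    if isinstance(estimates, Mapping):
        for key in ((record.endpoint, record.ul), record.ul):
            if key in estimates:
                return estimates[key]
        raise KeyError(
            f"no RMSEP estimate for record {record.id!r} "
            f"(endpoint={record.endpoint}, ul={record.ul})"
        )
    return float(estimates)


_GROUPERS: dict[str, Callable[[EvaluationRecord], object]] = {
    "ul": lambda r: r.ul,
    "state": lambda r: r.state.value if isinstance(r.state, State) else r.state,
    "membership": lambda r: r.membership,
}


def stratified_stats(
    records: Sequence[EvaluationRecord],
    rmsep_table,
    grouping: str = "ul",
    z: float = CONSTANTS.z95,
) -> pd.DataFrame:
    """Per-group RMSEP, percent within the estimated 95% PI, and count.

    ``rmsep_table`` provides each record's *estimated* RMSEP (an
    :class:`~pplfer.uncertainty.RMSEPTable`, a dict keyed by (endpoint, ul)
    or ul, a callable, or a scalar); the interval is y_pred -/+ z*estimate
    and membership is closed (boundaries count as inside).  Group RMSEP is
    the realised error within the group.
    """
    if len(records) == 0:
        raise ValueError("stratified_stats requires at least one record")
    if grouping not in _GROUPERS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPERS)}")
    for r in records:
        if not 0 <= r.ul <= 6:
            raise ValueError(f"record {r.id!r} has unknown UL {r.ul}")
    key = _GROUPERS[grouping]
    groups: dict[object, list[EvaluationRecord]] = {}
    for r in records:
        groups.setdefault(key(r), []).append(r)
    rows = []
    for gvalue in sorted(groups, key=lambda g: (g is None, str(g))):
        members = groups[gvalue]
        inside = 0
        for r in members:
            est = _resolve_estimate(r, rmsep_table)
            if abs(r.y_exp - r.y_pred) <= z * est:
                inside += 1
        rows.append(
            {
                grouping: gvalue,
                "rmsep": rmsep(members),
                "pct_within_pi": 100.0 * inside / len(members),
                "n": len(members),
            }
        )
    return pd.DataFrame(rows)


def calibrate_adjustments(
    records: Sequence[EvaluationRecord],
    rmsep_estimates,
    target: float = 0.95,
    step: float = 1.25,
    z: float = CONSTANTS.z95,
    max_steps: int = 64,
) -> float:
    """Smallest factor on the ladder {1, step, step^2, ...} reaching coverage.

    Coverage is the closed-interval fraction of records with
    |y_exp - y_pred| <= z * factor * estimated RMSEP.  Deterministic; raises
    if the target is outside (0, 1) or unreachable within ``max_steps``.
    """
    if not 0 < target < 1:
        raise ValueError(f"target must be in (0, 1), got {target}")
    if step <= 1:
        raise ValueError(f"step must be > 1, got {step}")
    if len(records) == 0:
        raise ValueError("calibrate_adjustments requires a nonempty stratum")
    residuals = np.array([abs(r.y_exp - r.y_pred) for r in records])
    estimates = np.array([_resolve_estimate(r, rmsep_estimates) for r in records])
    factor = 1.0
    for _ in range(max_steps):
        coverage = np.mean(residuals <= z * factor * estimates)
        if coverage >= target:
            return factor
        factor *= step
    raise ValueError(
        f"coverage target {target} not reachable within {max_steps} ladder steps"
    )


def filter_ionizable(
    records: Iterable[EvaluationRecord],
) -> tuple[list[EvaluationRecord], list[tuple[EvaluationRecord, str]]]:
    """Remove strong acids (pKa < 4) and strong bases (pKa > 10).

    Inequalities are strict; records without pKa metadata are kept.  Returns
    (kept, removed-with-reason).
    """
    kept: list[EvaluationRecord] = []
    removed: list[tuple[EvaluationRecord, str]] = []
    for r in records:
        if r.pKa_acid is not None and r.pKa_acid < STRONG_ACID_PKA:
            removed.append((r, f"strong acid: pKa {r.pKa_acid} < {STRONG_ACID_PKA}"))
        elif r.pKa_base is not None and r.pKa_base > STRONG_BASE_PKA:
            removed.append((r, f"strong base: pKa {r.pKa_base} > {STRONG_BASE_PKA}"))
        else:
            kept.append(r)
    return kept, removed
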