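"""Thermodynamic property cycles and MLR calibration of system parameters.

The three-solubility approach interprets the partition ratios K_OW, K_OA and
K_AW as ratios of the solubilities in octanol, water and air, so that log
system parameters combine additively along a cycle:

    dry log K_OW  = log K_OA + log K_AW
    log K_OO      = wet log K_OW - dry log K_OW   (wet/dry octanol ratio)
    log S_O[d][l] = log S_W[l] + dry log K_OW
    log S_O[w][l] = log S_W[l] + wet log K_OW

Applying these identities at the level of system parameters builds
thermodynamic consistency into the models: any solute's predictions close the
same cycles exactly.  Standard errors of derived coefficients propagate in
quadrature (independence assumed), which reproduces the published totals.

Calibration of new system parameters from (descriptors, observed value)
tables is ordinary least squares; per-coefficient standard errors come from
the OLS covariance matrix and the total standard error is the residual
standard deviation.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import (
    COEFFICIENT_NAMES,
    DIMENSIONLESS,
    ENDPOINT_UNITS,
    Endpoint,
    PARTITION_ENDPOINTS,
    SOLUBILITY_ENDPOINTS,
    SystemParameters,
)

__all__ = [
    "derive_sum",
    "derive_difference",
    "derived_registry",
    "check_cycle_consistency",
    "calibrate_system_parameters",
]

#: How each derived endpoint is obtained from calibrated rows.
CYCLE_DERIVATIONS = {
    Endpoint.KOW_DRY: ("+", Endpoint.KOA, Endpoint.KAW),
    Endpoint.KOO: ("-", Endpoint.KOW_WET, Endpoint.KOW_DRY),
    Endpoint.SO_DRY_LIQUID: ("+", Endpoint.SW_LIQUID, Endpoint.KOW_DRY),
    Endpoint.SO_WET_LIQUID: ("+", Endpoint.SW_LIQUID, Endpoint.KOW_WET),
}


def _combined_units(u1: str, u2: str, endpoint: Endpoint) -> str:
    """Units of a log-scale sum/difference; adding two dimensioned logs is
    only meaningful when at least one operand is a dimensionless ratio."""
    expected = ENDPOINT_UNITS[endpoint]
    if u1 != DIMENSIONLESS and u2 != DIMENSIONLESS and u1 != u2:
        raise ValueError(f"incompatible units: {u1!r} and {u2!r}")
    candidates = {u for u in (u1, u2) if u != DIMENSIONLESS} or {DIMENSIONLESS}
    if expected not in candidates and not (
        expected == DIMENSIONLESS and candidates == {DIMENSIONLESS}
    ):
        # e.g. K_OO = wet - dry K_OW: both dimensionless, difference too
        if not (u1 == u2 and expected == DIMENSIONLESS):
            raise ValueError(
                f"endpoint {endpoint.value} expects units {expected!r}, "
                f"operands give {sorted(candidates)}"
            )
    return expected


def _combine(
    sp1: SystemParameters, sp2: SystemParameters, endpoint: Endpoint, sign: float
) -> SystemParameters:
    endpoint = Endpoint(endpoint)
    if endpoint is Endpoint.SA:
        raise ValueError("SA has no system parameters; it is a unit conversion of VP")
    units = _combined_units(sp1.units, sp2.units, endpoint)
    coef = {
        name: getattr(sp1, name) + sign * getattr(sp2, name)
        for name in COEFFICIENT_NAMES
    }
    # Errors add in quadrature for sums and differences alike.
    se = {
        f"se_{name}": math.hypot(getattr(sp1, f"se_{name}"), getattr(sp2, f"se_{name}"))
        for name in COEFFICIENT_NAMES
    }
    if endpoint in PARTITION_ENDPOINTS and coef["d"] != 0.0:
        raise ValueError(
            f"derived partition endpoint {endpoint.value} has nonzero d term"
        )
    if endpoint in PARTITION_ENDPOINTS:
        se["se_d"] = 0.0
    return SystemParameters(
        endpoint=endpoint,
        units=units,
        total_se=math.hypot(sp1.total_se, sp2.total_se),
        **coef,
        **se,
    )


def derive_sum(
    sp1: SystemParameters, sp2: SystemParameters, endpoint: Endpoint
) -> SystemParameters:
    """Coefficient-wise sum of two parameter sets, s.e. in quadrature."""
    return _combine(sp1, sp2, endpoint, +1.0)


def derive_difference(
    sp1: SystemParameters, sp2: SystemParameters, endpoint: Endpoint
) -> SystemParameters:
    """Coefficient-wise difference sp1 - sp2, s.e. in quadrature."""
    return _combine(sp1, sp2, endpoint, -1.0)


def derived_registry(
    registry: dict[Endpoint, SystemParameters],
) -> dict[Endpoint, SystemParameters]:
    """Recompute the four cycle-derived rows from the calibrated rows.

    Derivations chain through unrounded intermediates: dry K_OW is derived
    first and then reused (unrounded) for K_OO and S_O[d][l].
    """
    for needed in (Endpoint.KAW, Endpoint.KOA, Endpoint.KOW_WET, Endpoint.SW_LIQUID):
        if needed not in registry:
            raise KeyError(f"registry is missing calibrated endpoint {needed.value}")
    kow_dry = derive_sum(registry[Endpoint.KOA], registry[Endpoint.KAW], Endpoint.KOW_DRY)
    return {
        Endpoint.KOW_DRY: kow_dry,
        Endpoint.KOO: derive_difference(
            registry[Endpoint.KOW_WET], kow_dry, Endpoint.KOO
        ),
        Endpoint.SO_DRY_LIQUID: derive_sum(
            registry[Endpoint.SW_LIQUID], kow_dry, Endpoint.SO_DRY_LIQUID
        ),
        Endpoint.SO_WET_LIQUID: derive_sum(
            registry[Endpoint.SW_LIQUID], registry[Endpoint.KOW_WET],
            Endpoint.SO_WET_LIQUID,
        ),
    }


def check_cycle_consistency(
    registry: dict[Endpoint, SystemParameters], tolerance: float = 0.005
) -> pd.DataFrame:
    """Audit the registry's derived rows against their cycle derivations.

    Returns a table with one row per (derived endpoint, term) where the terms
    are the seven coefficients and the total standard error; ``residual`` is
    |stored - recomputed| with the recomputation done at full float
    precision.  The ``passed`` column marks residuals within ``tolerance``
    (default 0.005, i.e. agreement with 2-decimal rounding).  Per-coefficient
    standard errors are reported as separate ``se_*`` terms but excluded from
    the pass criterion: quadrature totals reproduce published values, while
    individual rounded s.e. cells can differ by up to one unit in the last
    printed digit.
    """
    missing = [ep.value for ep in ENDPOINT_UNITS if ep is not Endpoint.SA
               and ep not in registry]
    if missing:
        raise KeyError(f"registry is missing endpoints: {missing}")
    recomputed = derived_registry(registry)
    rows = []
    for endpoint, derived in recomputed.items():
        stored = registry[endpoint]
        for name in COEFFICIENT_NAMES:
            rows.append((endpoint.value, name, getattr(stored, name),
                         getattr(derived, name), True))
        rows.append((endpoint.value, "total_se", stored.total_se,
                     derived.total_se, True))
        for name in COEFFICIENT_NAMES:
            rows.append((endpoint.value, f"se_{name}",
                         getattr(stored, f"se_{name}"),
                         getattr(derived, f"se_{name}"), False))
    table = pd.DataFrame(rows, columns=["endpoint", "term", "stored",
                                        "recomputed", "in_pass_set"])
    table["residual"] = (table["stored"] - table["recomputed"]).abs()
    table["passed"] = ~table["in_pass_set"] | (table["residual"] <= tolerance)
    return table


_FORM_COLUMNS = {
    "eq1": ("S", "A", "B", "V", "L"),
    "eq3": ("S", "A", "B", "AB_sqrt", "V", "L"),
}
_COEF_FOR_COLUMN = {"S": "s", "A": "a", "B": "b", "AB_sqrt": "d", "V": "v",
                    "L": "l", "const": "c"}


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in a linear dependency (for error messages)."""
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        if np.allclose(others @ beta, X[:, j], atol=1e-8):
            bad.append(names[j])
    return bad or names


def calibrate_system_parameters(
    data: pd.DataFrame,
    form: str = "eq1",
    endpoint: Endpoint | None = None,
    y_column: str = "y",
) -> SystemParameters:
    """Fit PPLFER system parameters by OLS regression of y on descriptors.

    Parameters
    ----------
    data : table with columns S, A, B, V, L and the observed log property
        ``y_column``; for form ``eq3`` the sqrt(A*B) regressor is built from
        A and B.
    form : "eq1" (partition, no d term) or "eq3" (pure phase, with d term).
    endpoint : endpoint tag for the returned parameters; defaults to
        ``KOW_wet`` for eq1 and ``SW_liquid`` for eq3 (tag only, the fit does
        not depend on it).

    Returns parameters with per-coefficient standard errors from the OLS
    covariance matrix and ``total_se`` equal to the residual standard
    deviation sqrt(SSR / (n - p)).
    """
    if form not in _FORM_COLUMNS:
        raise ValueError(f"form must be 'eq1' or 'eq3', got {form!r}")
    required = {"S", "A", "B", "V", "L", y_column}
    missing = sorted(required - set(data.columns))
    if missing:
        raise ValueError(f"calibration table is missing columns: {missing}")
    work = data.copy()
    if form == "eq3":
        if (work["A"] < 0).any() or (work["B"] < 0).any():
            raise ValueError("A and B must be >= 0 to form sqrt(A*B)")
        work["AB_sqrt"] = np.sqrt(work["A"] * work["B"])
    cols = list(_FORM_COLUMNS[form])
    X = work[cols].to_numpy(dtype=float)
    X = sm.add_constant(X, prepend=False, has_constant="add")
    names = cols + ["const"]
    y = work[y_column].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows than coefficients: n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    if endpoint is None:
        endpoint = Endpoint.KOW_WET if form == "eq1" else Endpoint.SW_LIQUID
    endpoint = Endpoint(endpoint)
    if form == "eq1" and endpoint not in PARTITION_ENDPOINTS:
        raise ValueError(f"form eq1 requires a partition endpoint, got {endpoint.value}")
    if form == "eq3" and endpoint not in SOLUBILITY_ENDPOINTS:
        raise ValueError(f"form eq3 requires a pure-phase endpoint, got {endpoint.value}")
    coef = {_COEF_FOR_COLUMN[name]: float(b) for name, b in zip(names, fit.params)}
    se = {f"se_{_COEF_FOR_COLUMN[name]}": float(s) for name, s in zip(names, fit.bse)}
    return SystemParameters(
        endpoint=endpoint,
        units=ENDPOINT_UNITS[endpoint],
        total_se=float(np.sqrt(fit.ssr / fit.df_resid)),
        **coef,
        **se,
    )
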