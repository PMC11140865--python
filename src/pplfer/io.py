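"""Batch prediction pipeline, CSV/YAML interfaces and configuration.

Input tables carry one row per solute with columns
``id, S, A, B, V, L`` (required) and optionally ``smiles`` (opaque
metadata), ``Tm_K, Tb_K, dSm_J_molK, MV_L_mol, pKa_acid, pKa_base, ul``.
Output tables carry one row per (solute, endpoint) with the prediction, its
uncertainty level, adjusted RMSEP, 95% prediction interval, predicted state
and provenance flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import engine, states, uncertainty
from .params import (
    FLAG_DEFAULT_DSM,
    FLAG_INTERCEPT_ONLY,
    FLAG_MV_FALLBACK,
    FLAG_VANT_HOFF,
    Endpoint,
    PropertyPrediction,
    SOLUBILITY_ENDPOINTS,
    SoluteDescriptors,
    State,
    SystemParameters,
    ThermalProperties,
    builtin_registry,
)
from .states import StateConfig
from .synthetic import solute_from_row, thermal_from_row
from .uncertainty import ADContext, AdjustmentFactors, RMSEPTable

__all__ = [
    "PredictionConfig",
    "predict_batch",
    "read_solutes_csv",
    "read_evaluation_csv",
]

REQUIRED_COLUMNS = ("id", "S", "A", "B", "V", "L")
DESCRIPTOR_COLUMNS = ("S", "A", "B", "V", "L")
DEFAULT_ENDPOINTS = tuple(ep for ep in Endpoint if ep is not Endpoint.SA)

_CAPPABLE = SOLUBILITY_ENDPOINTS


@dataclass
class PredictionConfig:
    """Run-time configuration for batch prediction.

    ``solid_output`` selects the reporting convention for pure-phase
    endpoints: "supercooled" (the fate-modelling default — all chemicals
    treated as liquids) or "solid" (Van't Hoff conversion applied to
    predicted maybe/likely solids).
    """

    state: StateConfig = field(default_factory=StateConfig)
    factors: AdjustmentFactors = field(default_factory=AdjustmentFactors)
    solid_output: str = "supercooled"
    ul4_in_ad: bool = True
    endpoints: tuple = DEFAULT_ENDPOINTS

    def __post_init__(self) -> None:
        if self.solid_output not in ("supercooled", "solid"):
            raise ValueError("solid_output must be 'supercooled' or 'solid'")
        self.endpoints = tuple(Endpoint(ep) for ep in self.endpoints)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PredictionConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        state = StateConfig(**doc.get("state", {}))
        fdoc = doc.get("factors", {})
        if "high_uls" in fdoc:
            fdoc["high_uls"] = frozenset(fdoc["high_uls"])
        factors = AdjustmentFactors(**fdoc)
        return cls(
            state=state,
            factors=factors,
            solid_output=doc.get("solid_output", "supercooled"),
            ul4_in_ad=doc.get("ul4_in_ad", True),
            endpoints=tuple(doc.get("endpoints", [e.value for e in DEFAULT_ENDPOINTS])),
        )


def read_solutes_csv(path: str | Path) -> pd.DataFrame:
    """Read a solute table, validating required columns and numeric cells."""
    df = pd.read_csv(path)
    _validate_input(df)
    return df


def _validate_input(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing required columns: {missing}")
    for col in DESCRIPTOR_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[numeric.isna(), "id"]
        if len(bad):
            raise ValueError(
                f"non-numeric or missing value in column {col!r} for "
                f"row id(s): {bad.tolist()[:5]}"
            )


def _thermal_for_row(row, sd: SoluteDescriptors, cfg: PredictionConfig):
    tp = thermal_from_row(row) if "Tm_K" in row or "MV_L_mol" in row else ThermalProperties()
    flags: set[str] = set()
    if tp.MV is None and cfg.state.enable_MV_fallback:
        tp = replace(tp, MV=cfg.state.mv_per_mcgowan * sd.V)
        flags.add(FLAG_MV_FALLBACK)
    return tp, flags


def predict_batch(
    df: pd.DataFrame,
    config: PredictionConfig | None = None,
    registry: dict[Endpoint, SystemParameters] | None = None,
    ad: ADContext | None = None,
    rmsep_table: RMSEPTable | None = None,
) -> pd.DataFrame:
    """Predict every configured endpoint for every solute in ``df``.

    Per solute: evaluate the PPLFER equations, classify the physical state,
    convert pure-phase endpoints to solid values when requested, assign an
    uncertainty level (from the AD context in descriptor space when one is
    supplied, else passthrough of a ``ul`` column, else intercept-only
    detection), cap solubility/VP at their physical bounds, and attach the
    adjusted RMSEP and 95% prediction interval.
    """
    config = config or PredictionConfig()
    registry = registry or builtin_registry()
    rmsep_table = rmsep_table or RMSEPTable.from_registry(registry, config.factors)
    _validate_input(df)
    T = config.state.system_T_K

    out_rows = []
    for _, row in df.iterrows():
        sd = solute_from_row(row)
        tp, solute_flags = _thermal_for_row(row, sd, config)
        state = states.classify_state(tp, T=T, margin=config.state.state_margin_K)
        descriptor_vec = np.array([sd.S, sd.A, sd.B, sd.V, sd.L])
        intercept_only = bool(np.all(descriptor_vec == 0))
        if intercept_only:
            solute_flags.add(FLAG_INTERCEPT_ONLY)
        if "ul" in row and not _isna(row["ul"]):
            ul = int(row["ul"])
        elif ad is not None:
            ul = uncertainty.assign_ul(
                ad.leverage_of(descriptor_vec),
                ad.css_of(descriptor_vec),
                ad,
                fragment_counts=descriptor_vec,
                substructures=frozenset(),
            )
        else:
            ul = 4 if intercept_only else 0

        for endpoint in config.endpoints:
            pred = _predict_one(
                endpoint, sd, tp, state, ul, registry, rmsep_table, config,
                solute_flags,
            )
            out_rows.append(
                {
                    "id": row["id"],
                    "endpoint": endpoint.value,
                    "value": pred.value,
                    "ul": pred.ul,
                    "rmsep": pred.rmsep,
                    "pi_low": pred.pi_low,
                    "pi_high": pred.pi_high,
                    "state": pred.state.value,
                    "flags": ";".join(sorted(pred.flags)),
                }
            )
    return pd.DataFrame(out_rows)


def _isna(value) -> bool:
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def _predict_one(
    endpoint: Endpoint,
    sd: SoluteDescriptors,
    tp: ThermalProperties,
    state: State,
    ul: int,
    registry,
    rmsep_table: RMSEPTable,
    config: PredictionConfig,
    solute_flags: set[str],
) -> PropertyPrediction:
    sp = registry[endpoint]
    value = engine.evaluate(sp, sd)
    flags = set(solute_flags)

    pure_phase = endpoint in SOLUBILITY_ENDPOINTS
    if (
        pure_phase
        and config.solid_output == "solid"
        and state in (State.SOLID, State.MAYBE_SOLID)
        and tp.T_M is not None
    ):
        dSm = tp.dS_M
        if dSm is None:
            dSm = config.state.default_dS_M
            flags.add(FLAG_DEFAULT_DSM)
        value = states.vant_hoff_correct(
            value, dSm, tp.T_M, T=config.state.system_T_K
        )
        flags.add(FLAG_VANT_HOFF)

    base_rmsep = rmsep_table.lookup(endpoint, ul)
    adj = uncertainty.adjusted_rmsep(base_rmsep, endpoint, ul, state, config.factors)
    lo, hi = value - config.factors.z * adj, value + config.factors.z * adj
    pred = PropertyPrediction(
        endpoint=endpoint,
        value=value,
        ul=ul,
        rmsep=adj,
        pi_low=lo,
        pi_high=hi,
        state=state,
        flags=frozenset(flags),
    )
    if endpoint is Endpoint.VP_LIQUID or (pure_phase and tp.MV is not None):
        # Solubility caps need MV; without it the prediction passes through.
        if endpoint is Endpoint.VP_LIQUID or endpoint in _CAPPABLE:
            pred = states.apply_caps(pred, tp)
    return pred


_EVAL_COLUMNS = {"id", "endpoint", "y_exp", "y_pred", "ul"}


def read_evaluation_csv(path: str | Path):
    """Read evaluation records (id, endpoint, y_exp, y_pred, ul, state,
    membership, pKa_acid, pKa_base) into EvaluationRecord objects."""
    from .params import EvaluationRecord

    df = pd.read_csv(path)
    missing = sorted(_EVAL_COLUMNS - set(df.columns))
    if missing:
        raise ValueError(f"evaluation table is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            EvaluationRecord(
                id=str(row["id"]),
                y_exp=float(row["y_exp"]),
                y_pred=float(row["y_pred"]),
                ul=int(row["ul"]),
                state=State(row["state"]) if "state" in row and not _isna(row["state"])
                else State.UNKNOWN,
                endpoint=Endpoint(row["endpoint"]) if not _isna(row["endpoint"]) else None,
                membership=row.get("membership") if "membership" in row
                and not _isna(row.get("membership")) else None,
                pKa_acid=float(row["pKa_acid"]) if "pKa_acid" in row
                and not _isna(row["pKa_acid"]) else None,
                pKa_base=float(row["pKa_base"]) if "pKa_base" in row
                and not _isna(row["pKa_base"]) else None,
            )
        )
    return records
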