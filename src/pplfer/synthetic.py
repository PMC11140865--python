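"""Synthetic solute populations and property datasets for testing.

Generators emulate a population of neutral organic chemicals spanning the
descriptor space of typical environmental and pharmaceutical solutes:
McGowan volumes from small volatiles to large, complex chemicals, mostly
weak hydrogen-bond donors (exponential A, B with donors rarer than
acceptors), and L strongly correlated with molecular size.  Thermal
properties are drawn so that the population contains gases, liquids,
borderline and clear solids at 25 C.  Property datasets are exact PPLFER
values from a chosen parameter set plus i.i.d. Gaussian noise, which is the
generating model assumed by the OLS calibration they exercise.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .params import SoluteDescriptors, SystemParameters, ThermalProperties

__all__ = [
    "generate_solutes",
    "generate_property_dataset",
    "generate_fragment_matrix",
    "FragmentFixture",
    "solute_from_row",
    "thermal_from_row",
]

#: Descriptor-population settings (configuration, not hard-coded truth).
V_RANGE = (0.3, 4.0)
S_RANGE = (0.0, 2.5)
A_MEAN, A_CAP = 0.25, 1.5
B_MEAN, B_CAP = 0.45, 2.5
L_SLOPE, L_SD = 3.5, 0.8
MV_PER_V, MV_NOISE = 1.27, 0.10


def _truncated_exponential(rng, mean: float, cap: float, n: int) -> np.ndarray:
    # Inverse-CDF sampling of an exponential truncated at `cap`.
    u = rng.uniform(size=n)
    return -mean * np.log1p(-u * (1.0 - np.exp(-cap / mean)))


def generate_solutes(n: int, seed: int, missing_thermal: float = 0.05) -> pd.DataFrame:
    """Draw ``n`` solutes with descriptors and thermal properties.

    Columns: id, S, A, B, V, L, Tm_K, Tb_K, dSm_J_molK, MV_L_mol.  A small
    fraction (``missing_thermal``) of rows has missing thermal data to
    exercise the ``unknown`` state branch.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    V = rng.uniform(*V_RANGE, size=n)
    S = rng.uniform(*S_RANGE, size=n)
    A = _truncated_exponential(rng, A_MEAN, A_CAP, n)
    B = _truncated_exponential(rng, B_MEAN, B_CAP, n)
    L = L_SLOPE * V + rng.normal(0.0, L_SD, size=n)
    # Boiling points rise with molecular size; melting points sit well below
    # them.  The offsets put gases, liquids, maybe-solids and solids all in
    # the population at 25 C.
    Tb = 260.0 + 120.0 * V + rng.normal(0.0, 25.0, size=n)
    Tb = np.clip(Tb, 120.0, None)
    Tm = Tb - (60.0 + 100.0 * rng.uniform(size=n))
    Tm = np.clip(Tm, 60.0, None)
    dSm = np.clip(rng.normal(56.5, 10.0, size=n), 20.0, None)
    MV = MV_PER_V * V * (1.0 + rng.normal(0.0, MV_NOISE, size=n))
    MV = np.clip(MV, 0.01, None)
    df = pd.DataFrame(
        {
            "id": [f"syn-{i:05d}" for i in range(n)],
            "S": S,
            "A": A,
            "B": B,
            "V": V,
            "L": L,
            "Tm_K": Tm,
            "Tb_K": Tb,
            "dSm_J_molK": dSm,
            "MV_L_mol": MV,
        }
    )
    if missing_thermal > 0:
        mask = rng.uniform(size=n) < missing_thermal
        df.loc[mask, ["Tm_K", "Tb_K", "dSm_J_molK"]] = np.nan
    return df


def solute_from_row(row) -> SoluteDescriptors:
    return SoluteDescriptors(
        S=float(row["S"]), A=float(row["A"]), B=float(row["B"]),
        V=float(row["V"]), L=float(row["L"]),
    )


def _opt(row, name):
    value = row.get(name) if hasattr(row, "get") else row[name]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def thermal_from_row(row) -> ThermalProperties:
    return ThermalProperties(
        T_M=_opt(row, "Tm_K"), T_B=_opt(row, "Tb_K"),
        dS_M=_opt(row, "dSm_J_molK"), MV=_opt(row, "MV_L_mol"),
    )


def generate_property_dataset(
    params: SystemParameters, n: int, noise_sd: float, seed: int
) -> pd.DataFrame:
    """Descriptor table with exact PPLFER values plus Gaussian noise.

    Emits both the noise-free truth (``y_true``) and the observed ``y``; the
    descriptor draw and the noise use independent substreams of ``seed``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    df = generate_solutes(n, seed=seed, missing_thermal=0.0)
    y_true = np.array(
        [engine.evaluate(params, solute_from_row(row)) for _, row in df.iterrows()]
    )
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    df["y_true"] = y_true
    df["y"] = y_true + noise_rng.normal(0.0, noise_sd, size=n)
    return df


@dataclass
class FragmentFixture:
    """Training design, query rows and substructure bookkeeping for AD tests."""

    training: np.ndarray
    queries: np.ndarray
    known_substructures: frozenset
    query_substructures: list
    expected_special: list  # per query: 5, 4 or None


def generate_fragment_matrix(
    n_train: int,
    n_query: int,
    n_features: int,
    seed: int,
    ul5_fraction: float = 0.1,
    ul4_fraction: float = 0.1,
) -> FragmentFixture:
    """Sparse nonnegative fragment-count matrices with controllable UL cases.

    A block of feature columns is reserved (never used in training); query
    rows in the first ``ul5_fraction`` carry a count on a reserved feature
    (unseen substructure, UL 5), the next ``ul4_fraction`` are all-zero
    (intercept-only, UL 4), the remainder resemble training rows.
    Substructure codes are the feature indices with nonzero counts.
    """
    if min(n_train, n_query, n_features) < 1:
        raise ValueError("dimensions must be >= 1")
    if ul5_fraction + ul4_fraction > 1:
        raise ValueError("ul5_fraction + ul4_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    n_reserved = max(1, n_features // 5)
    n_used = n_features - n_reserved
    if n_used < 1:
        raise ValueError("n_features too small to reserve unseen columns")
    training = np.zeros((n_train, n_features), dtype=int)
    training[:, :n_used] = rng.poisson(0.8, size=(n_train, n_used))
    # Guarantee every calibrated column is actually seen in training.
    for j in range(n_used):
        if training[:, j].sum() == 0:
            training[rng.integers(n_train), j] = 1
    known = frozenset(np.flatnonzero(training.sum(axis=0)).tolist())

    n5 = int(round(ul5_fraction * n_query))
    n4 = int(round(ul4_fraction * n_query))
    n5 = min(n5, n_query)
    n4 = min(n4, n_query - n5)
    queries = np.zeros((n_query, n_features), dtype=int)
    expected: list = []
    subs: list = []
    for i in range(n_query):
        if i < n5:
            row = np.zeros(n_features, dtype=int)
            row[:n_used] = rng.poisson(0.8, size=n_used)
            row[n_used + rng.integers(n_reserved)] = 1 + rng.poisson(0.5)
            expected.append(5)
        elif i < n5 + n4:
            row = np.zeros(n_features, dtype=int)
            expected.append(4)
        else:
            row = np.zeros(n_features, dtype=int)
            row[:n_used] = rng.poisson(0.8, size=n_used)
            if row.sum() == 0:
                row[rng.integers(n_used)] = 1
            expected.append(None)
        queries[i] = row
        subs.append(frozenset(np.flatnonzero(row).tolist()))
    return FragmentFixture(
        training=training,
        queries=queries,
        known_substructures=known,
        query_substructures=subs,
        expected_special=expected,
    )
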