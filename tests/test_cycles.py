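"""Thermodynamic cycle derivation, error propagation and MLR calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pplfer import (
    Endpoint,
    SystemParameters,
    calibrate_system_parameters,
    check_cycle_consistency,
    derive_difference,
    derive_sum,
    generate_property_dataset,
)
from pplfer.params import COEFFICIENT_NAMES, DIMENSIONLESS


def round2(x):
    # half-even, matching how published tables round
    return float(np.round(x, 2))


class TestDeriveSum:
    def test_dry_kow_from_koa_plus_kaw(self, registry):
        derived = derive_sum(registry[Endpoint.KOA], registry[Endpoint.KAW],
                             Endpoint.KOW_DRY)
        assert derived.s == pytest.approx(0.69 + (-2.26))
        assert derived.v == pytest.approx(0.52 + 2.19)
        assert round2(derived.total_se) == 0.23
        assert derived.total_se == pytest.approx(math.hypot(0.16, 0.17))

    def test_so_dry_from_sw_plus_dry_kow(self, registry):
        kow_dry = derive_sum(registry[Endpoint.KOA], registry[Endpoint.KAW],
                             Endpoint.KOW_DRY)
        so_dry = derive_sum(registry[Endpoint.SW_LIQUID], kow_dry,
                            Endpoint.SO_DRY_LIQUID)
        assert so_dry.a == pytest.approx(2.80 + (-0.16))
        # propagated from unrounded dry-K_OW s.e.
        assert so_dry.total_se == pytest.approx(
            math.sqrt(0.60**2 + 0.17**2 + 0.16**2)
        )
        assert round2(so_dry.total_se) == 0.64

    def test_zero_parameter_set_is_identity(self, registry):
        zero = SystemParameters(endpoint=Endpoint.KAW, s=0, a=0, b=0, v=0,
                                l=0, c=0, units=DIMENSIONLESS)
        sp = registry[Endpoint.KAW]
        out = derive_sum(sp, zero, Endpoint.KAW)
        for name in COEFFICIENT_NAMES:
            assert getattr(out, name) == getattr(sp, name)
            assert getattr(out, f"se_{name}") == getattr(sp, f"se_{name}")
        assert out.total_se == sp.total_se

    def test_incompatible_units_rejected(self, registry):
        with pytest.raises(ValueError):
            derive_sum(registry[Endpoint.SW_LIQUID], registry[Endpoint.VP_LIQUID],
                       Endpoint.SO_DRY_LIQUID)

    def test_commutative(self, registry):
        a = derive_sum(registry[Endpoint.KOA], registry[Endpoint.KAW], Endpoint.KOW_DRY)
        b = derive_sum(registry[Endpoint.KAW], registry[Endpoint.KOA], Endpoint.KOW_DRY)
        assert a == b


class TestDeriveDifference:
    def test_koo_from_wet_minus_dry(self, registry):
        kow_dry = derive_sum(registry[Endpoint.KOA], registry[Endpoint.KAW],
                             Endpoint.KOW_DRY)
        koo = derive_difference(registry[Endpoint.KOW_WET], kow_dry, Endpoint.KOO)
        assert koo.b == pytest.approx(-3.49 - (-4.05))
        assert koo.l == pytest.approx(0.0, abs=1e-12)
        assert koo.v == pytest.approx(-0.30)
        # quadrature with the *unrounded* dry-K_OW total s.e.
        assert koo.total_se == pytest.approx(
            math.sqrt(0.15**2 + 0.17**2 + 0.16**2)
        )
        assert round2(koo.total_se) == 0.28

    def test_self_difference_is_zero(self, registry):
        sp = registry[Endpoint.KOW_WET]
        out = derive_difference(sp, sp, Endpoint.KOO)
        for name in COEFFICIENT_NAMES:
            assert getattr(out, name) == 0.0

    def test_difference_inverts_sum_for_coefficients(self, registry):
        x, y = registry[Endpoint.KOA], registry[Endpoint.KAW]
        summed = derive_sum(x, y, Endpoint.KOW_DRY)
        back = derive_difference(summed, y, Endpoint.KOA)
        for name in COEFFICIENT_NAMES:
            assert getattr(back, name) == pytest.approx(getattr(x, name), abs=1e-12)
        # standard errors do not invert: they grow in quadrature both ways
        assert back.total_se > x.total_se


class TestCycleConsistency:
    def test_bundled_registry_closes(self, registry):
        table = check_cycle_consistency(registry)
        audited = table[table["in_pass_set"]]
        assert audited["passed"].all()
        assert audited["residual"].max() <= 0.005

    def test_so_wet_intercept_residual_is_zero(self, registry):
        table = check_cycle_consistency(registry)
        row = table[(table.endpoint == "SO_wet_liquid") & (table.term == "c")]
        assert row["residual"].item() == pytest.approx(abs(0.59 - (0.18 + 0.41)),
                                                       abs=1e-12)

    def test_injected_defect_is_reported(self, registry):
        from dataclasses import replace

        broken = dict(registry)
        sp = broken[Endpoint.KOW_DRY]
        broken[Endpoint.KOW_DRY] = replace(sp, s=sp.s + 0.1)
        table = check_cycle_consistency(broken)
        row = table[(table.endpoint == "KOW_dry") & (table.term == "s")]
        assert row["residual"].item() == pytest.approx(0.1)
        assert not row["passed"].item()

    def test_missing_endpoint_rejected(self, registry):
        partial = {k: v for k, v in registry.items() if k is not Endpoint.KOO}
        with pytest.raises(KeyError, match="KOO"):
            check_cycle_consistency(partial)


class TestCalibration:
    def test_noise_free_data_recovers_exactly(self, registry):
        truth = registry[Endpoint.KAW]
        data = generate_property_dataset(truth, n=50, noise_sd=0.0, seed=7)
        fit = calibrate_system_parameters(data, form="eq1", endpoint=Endpoint.KAW)
        for name in ("s", "a", "b", "v", "l", "c"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name),
                                                       abs=1e-8)

    @pytest.mark.parametrize(
        "endpoint, form",
        [(Endpoint.KAW, "eq1"), (Endpoint.KOW_WET, "eq1"),
         (Endpoint.SW_LIQUID, "eq3"), (Endpoint.VP_LIQUID, "eq3")],
    )
    def test_noisy_recovery_within_three_se(self, registry, endpoint, form):
        truth = registry[endpoint]
        data = generate_property_dataset(truth, n=500, noise_sd=0.2, seed=11)
        fit = calibrate_system_parameters(data, form=form, endpoint=endpoint)
        names = ("s", "a", "b", "v", "l", "c") if form == "eq1" else \
            ("s", "a", "b", "d", "v", "l", "c")
        for name in names:
            z = abs(getattr(fit, name) - getattr(truth, name)) / getattr(fit, f"se_{name}")
            assert z < 3, f"{endpoint.value}.{name}: |z| = {z:.2f}"
        assert 0.17 <= fit.total_se <= 0.23

    def test_duplicated_column_is_rank_deficient(self, registry):
        data = generate_property_dataset(registry[Endpoint.KAW], n=50,
                                         noise_sd=0.0, seed=3)
        data["L"] = data["V"]  # duplicate regressor
        with pytest.raises(ValueError, match="rank deficient"):
            calibrate_system_parameters(data, form="eq1")

    def test_too_few_rows_rejected(self, registry):
        data = generate_property_dataset(registry[Endpoint.KAW], n=5,
                                         noise_sd=0.0, seed=3)
        with pytest.raises(ValueError, match="more rows"):
            calibrate_system_parameters(data.head(5), form="eq1")

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            calibrate_system_parameters(pd.DataFrame({"S": [1.0], "y": [0.0]}))


@settings(max_examples=25, deadline=None)
@given(
    se1=st.floats(0.0, 1.0),
    se2=st.floats(0.0, 1.0),
    se3=st.floats(0.0, 1.0),
)
def test_se_propagation_is_order_independent(registry, se1, se2, se3):
    """Quadrature accumulation over three parameter sets is associative."""
    def mk(total):
        return SystemParameters(endpoint=Endpoint.KAW, s=0, a=0, b=0, v=0,
                                l=0, c=0, total_se=total, units=DIMENSIONLESS)

    left = derive_sum(derive_sum(mk(se1), mk(se2), Endpoint.KAW), mk(se3),
                      Endpoint.KAW)
    right = derive_sum(mk(se1), derive_sum(mk(se2), mk(se3), Endpoint.KAW),
                       Endpoint.KAW)
    assert left.total_se == pytest.approx(right.total_se, rel=1e-12, abs=1e-12)
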