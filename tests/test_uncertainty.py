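"""Applicability-domain metrics, UL assignment, aggregation and intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pplfer import (
    ADContext,
    AdjustmentFactors,
    Endpoint,
    RMSEPTable,
    State,
    adjusted_rmsep,
    aggregate_meta,
    assign_ul,
    css,
    leverage,
    prediction_interval,
)
from pplfer.uncertainty import UNADJUSTED


class TestLeverage:
    def test_textbook_hat_matrix_value(self):
        # intercept + one regressor with values {1, 2, 3}; query at the mean
        X = np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        assert leverage([1.0, 2.0], X) == pytest.approx(1 / 3)

    def test_training_leverages_sum_to_parameter_count(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        total = sum(leverage(row, X) for row in X)
        assert total == pytest.approx(X.shape[1], abs=1e-9)

    def test_mean_point_of_centered_design_has_leverage_1_over_n(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(15, 2))
        Z -= Z.mean(axis=0)
        X = np.column_stack([np.ones(15), Z])
        assert leverage([1.0, 0.0, 0.0], X) == pytest.approx(1 / 15, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            leverage([1.0], np.ones((3, 2)))


class TestCss:
    def test_exact_training_duplicate_scores_one(self):
        X = np.array([[1, 0, 2], [0, 3, 1], [2, 2, 0]], dtype=float)
        assert css(X[1], X, k=1) == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self):
        X = np.array([[1, 1, 0, 0], [2, 1, 0, 0]], dtype=float)
        assert css([0, 0, 3, 1], X, k=2) == pytest.approx(0.0)

    def test_k2_matches_brute_force_enumeration(self):
        X = np.array([[2, 0, 1], [1, 1, 1], [0, 4, 0]], dtype=float)
        x = np.array([1.0, 1.0, 0.0])

        def tanimoto(u, v):
            return np.minimum(u, v).sum() / np.maximum(u, v).sum()

        sims = sorted(tanimoto(x, row) for row in X)
        assert css(x, X, k=2) == pytest.approx(np.mean(sims[-2:]))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            css([1.0], np.empty((0, 1)), k=1)

    def test_cosine_metric_selectable(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert css([2.0, 0.0], X, k=1, metric="cosine") == pytest.approx(1.0)


def make_ctx(**kwargs):
    rng = np.random.default_rng(0)
    X = rng.poisson(1.0, size=(30, 4)).astype(float)
    defaults = dict(training_design=X,
                    known_substructures=frozenset(range(4)))
    defaults.update(kwargs)
    return ADContext(**defaults)


class TestAssignUl:
    def test_no_warnings_gives_ul0(self):
        ctx = make_ctx()
        assert assign_ul(0.01, 0.9, ctx, [1, 0, 0, 0], {0}) == 0

    def test_intercept_only_gives_ul4(self):
        ctx = make_ctx()
        assert assign_ul(0.0, 1.0, ctx, [0, 0, 0, 0], set()) == 4

    def test_unknown_substructure_gives_ul5_regardless_of_leverage(self):
        ctx = make_ctx()
        assert assign_ul(0.0, 1.0, ctx, [1, 0, 0, 0], {99}) == 5

    def test_leverage_grades(self):
        ctx = make_ctx()
        frag, subs = [1, 0, 0, 0], {0}
        assert assign_ul(ctx.leverage_egregious * 1.1, 0.9, ctx, frag, subs) == 3
        assert assign_ul(ctx.leverage_out * 1.1, 0.9, ctx, frag, subs) == 2
        assert assign_ul(ctx.leverage_warn * 1.1, 0.9, ctx, frag, subs) == 1

    def test_css_grades(self):
        ctx = make_ctx()
        frag, subs = [1, 0, 0, 0], {0}
        assert assign_ul(0.01, 0.2, ctx, frag, subs) == 2
        assert assign_ul(0.01, 0.4, ctx, frag, subs) == 1

    @settings(max_examples=100, deadline=None)
    @given(h1=st.floats(0, 2), h2=st.floats(0, 2), cs=st.floats(0, 1))
    def test_worsening_leverage_never_lowers_ul(self, h1, h2, cs):
        ctx = make_ctx()
        lo, hi = sorted([h1, h2])
        frag, subs = [1, 0, 0, 0], {0}
        assert assign_ul(lo, cs, ctx, frag, subs) <= assign_ul(hi, cs, ctx, frag, subs)


class TestAggregateMeta:
    def test_quadrature_reproduces_propagated_totals(self):
        # the dry K_OW and wet octanol solubility propagation sums
        _, r1 = aggregate_meta([0, 0], [0.17, 0.16])
        assert round(r1, 2) == 0.23
        _, r2 = aggregate_meta([0, 0], [0.60, 0.15])
        assert round(r2, 2) == 0.62

    def test_single_input_unchanged(self):
        assert aggregate_meta([2], [0.5]) == (2, 0.5)

    def test_max_ul_policy_with_ul4_in_ad(self):
        ul, _ = aggregate_meta([4, 1], [0.1, 0.1])
        assert ul == 1  # intercept-only component treated as in-AD
        ul, _ = aggregate_meta([4, 4], [0.1, 0.1])
        assert ul == 4  # all components intercept-only
        ul, _ = aggregate_meta([4, 1], [0.1, 0.1], ul4_in_ad=False)
        assert ul == 4

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_meta([], [])

    @settings(max_examples=50, deadline=None)
    @given(rs=st.lists(st.floats(0, 2), min_size=1, max_size=6))
    def test_permutation_invariant_and_at_least_max(self, rs):
        uls = [0] * len(rs)
        _, fwd = aggregate_meta(uls, rs)
        _, rev = aggregate_meta(uls, list(reversed(rs)))
        assert fwd == pytest.approx(rev)
        assert fwd >= max(rs) - 1e-12


class TestPredictionInterval:
    def test_bare_196_interval_with_adjustments_disabled(self):
        lo, hi = prediction_interval(0.0, 1.0, Endpoint.KOW_WET,
                                     factors=UNADJUSTED)
        assert (lo, hi) == pytest.approx((-1.96, 1.96))

    def test_default_global_factor(self):
        lo, hi = prediction_interval(0.0, 1.0, Endpoint.KOW_WET, ul=0,
                                     state=State.LIQUID)
        assert hi == pytest.approx(1.96 * 1.25)

    def test_adjustment_ladder_for_vp_of_solids_at_high_ul(self):
        adj = adjusted_rmsep(1.0, Endpoint.VP_LIQUID, ul=3, state=State.SOLID)
        assert adj == pytest.approx(1.25 * 1.67 * 1.25)
        adj = adjusted_rmsep(1.0, Endpoint.SW_LIQUID, ul=0, state=State.MAYBE_SOLID)
        assert adj == pytest.approx(1.25 * 1.25)
        adj = adjusted_rmsep(1.0, Endpoint.VP_LIQUID, ul=2, state=State.LIQUID)
        assert adj == pytest.approx(1.25 * 1.25)

    def test_zero_rmsep_degenerate_interval(self):
        lo, hi = prediction_interval(1.3, 0.0, Endpoint.KAW)
        assert lo == hi == 1.3

    def test_negative_rmsep_rejected(self):
        with pytest.raises(ValueError):
            prediction_interval(0.0, -0.1, Endpoint.KAW)

    def test_factors_below_one_rejected(self):
        with pytest.raises(ValueError):
            AdjustmentFactors(global_factor=0.9)

    @settings(max_examples=50, deadline=None)
    @given(r=st.floats(0, 3), scale=st.floats(1, 4))
    def test_width_linear_in_rmsep_and_adjustments_only_widen(self, r, scale):
        lo1, hi1 = prediction_interval(0.0, r, Endpoint.VP_LIQUID, ul=3,
                                       state=State.SOLID)
        lo2, hi2 = prediction_interval(0.0, r * scale, Endpoint.VP_LIQUID,
                                       ul=3, state=State.SOLID)
        assert (hi2 - lo2) == pytest.approx(scale * (hi1 - lo1), rel=1e-9, abs=1e-9)
        bare_hi = prediction_interval(0.0, r, Endpoint.VP_LIQUID, ul=3,
                                      state=State.SOLID, factors=UNADJUSTED)[1]
        assert hi1 >= bare_hi - 1e-12


class TestRmsepTable:
    def test_lookup_prefers_specific_over_fallback(self, registry):
        table = RMSEPTable.from_registry(registry)
        assert table.lookup(Endpoint.KAW, 0) == pytest.approx(0.17)
        table.values[(Endpoint.KAW, 3)] = 0.9
        assert table.lookup(Endpoint.KAW, 3) == pytest.approx(0.9)
        assert table.lookup(Endpoint.KAW, 1) == pytest.approx(0.17)

    def test_missing_entry_rejected(self):
        with pytest.raises(KeyError):
            RMSEPTable().lookup(Endpoint.KAW, 0)
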