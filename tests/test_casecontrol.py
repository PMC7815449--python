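import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import nchypergeom_fisher, norm

from netexposure import (
    TwoByTwo,
    build_table,
    cornfield_approx_ci,
    exact_ci,
    odds_ratio,
    woolf_ci,
)
from netexposure.exposure import PREDICATES, exposed_flags, network_exposure

from conftest import make_annotated_network


def scipy_tail_ge(t, psi):
    """Independent conditional tail P(X >= a) via scipy's distribution."""
    return float(
        nchypergeom_fisher.sf(t.a - 1, t.n, t.a + t.b, t.a + t.c, psi)
    )


def scipy_tail_le(t, psi):
    return float(nchypergeom_fisher.cdf(t.a, t.n, t.a + t.b, t.a + t.c, psi))


def grid_invert(tail, t, alpha, lo=1e-8, hi=1e8):
    """Oracle: bisection on scipy tails to find where the tail hits alpha/2."""
    f = lambda logpsi: tail(t, math.exp(logpsi)) - alpha / 2.0
    return math.exp(brentq(f, math.log(lo), math.log(hi), xtol=1e-12))


class TestOddsRatio:
    def test_symmetric_table(self):
        assert odds_ratio(TwoByTwo(5, 5, 5, 5)) == 1.0

    def test_direct_formula(self):
        assert odds_ratio(TwoByTwo(10, 5, 2, 20)) == 20.0

    def test_zero_a_cell(self):
        assert odds_ratio(TwoByTwo(0, 3, 15, 265)) == 0.0

    def test_zero_bc_product_is_infinite(self):
        assert odds_ratio(TwoByTwo(4, 0, 3, 7)) == math.inf

    def test_doubly_degenerate_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(TwoByTwo(0, 5, 0, 7))

    def test_row_and_column_swaps_invert(self):
        t = TwoByTwo(10, 5, 2, 20)
        assert odds_ratio(t.swap_rows()) * odds_ratio(t) == pytest.approx(1.0)
        assert odds_ratio(t.swap_cols()) * odds_ratio(t) == pytest.approx(1.0)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)


class TestBuildTable:
    def test_hand_enumerated_counts(self):
        # 7-node network: two antivaccine hubs, known exposure pattern
        net = make_annotated_network(
            [("a1", "x1"), ("a1", "x2"), ("a2", "x2"), ("x3", "x4"),
             ("a1", "a2")],
            anti_ids={"a1", "a2"},
            extra_ids=["x5"],
        )
        flags = exposed_flags(network_exposure(net, PREDICATES["antivaccine"]))
        t = build_table(net, PREDICATES["antivaccine"], flags)
        # a1,a2 are exposed to each other; x1,x2 exposed; x3,x4,x5 not
        assert (t.a, t.b, t.c, t.d) == (2, 0, 2, 3)
        assert t.n == net.n_nodes

    def test_predicate_matching_nothing(self):
        net = make_annotated_network([("u", "v")])
        flags = {"u": True, "v": False}
        t = build_table(net, lambda n: False, flags)
        assert (t.a, t.b) == (0, 0)
        assert t.c + t.d == 2

    def test_predicate_matching_everything(self):
        net = make_annotated_network([("u", "v")])
        t = build_table(net, lambda n: True, {"u": True, "v": False})
        assert (t.c, t.d) == (0, 0)

    def test_uncovered_node_rejected(self):
        net = make_annotated_network([("u", "v")])
        with pytest.raises(KeyError):
            build_table(net, lambda n: True, {"u": True})


class TestWoolf:
    def test_closed_form(self):
        t = TwoByTwo(10, 5, 2, 20)
        res = woolf_ci(t, alpha=0.05)
        z = norm.ppf(0.975)
        se = math.sqrt(1 / 10 + 1 / 5 + 1 / 2 + 1 / 20)
        assert res.or_point == 20.0
        assert res.ci_low == pytest.approx(math.exp(math.log(20) - z * se))
        assert res.ci_high == pytest.approx(math.exp(math.log(20) + z * se))

    def test_symmetric_about_one_on_log_scale(self):
        res = woolf_ci(TwoByTwo(100, 100, 100, 100))
        assert math.log(res.ci_low) == pytest.approx(-math.log(res.ci_high))

    def test_interval_shrinks_with_counts(self):
        wide = woolf_ci(TwoByTwo(5, 5, 5, 5))
        narrow = woolf_ci(TwoByTwo(50, 50, 50, 50))
        assert wide.ci_low < narrow.ci_low < narrow.ci_high < wide.ci_high

    def test_zero_cell_refused(self):
        with pytest.raises(ValueError, match="exact_ci"):
            woolf_ci(TwoByTwo(0, 5, 5, 5))


class TestExactCI:
    def test_matches_scipy_inversion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            t = TwoByTwo(*(int(v) for v in rng.integers(1, 12, size=4)))
            res = exact_ci(t)
            lo = grid_invert(scipy_tail_ge, t, 0.05)
            hi = grid_invert(scipy_tail_le, t, 0.05)
            assert res.ci_low == pytest.approx(lo, rel=1e-6)
            assert res.ci_high == pytest.approx(hi, rel=1e-6)

    def test_zero_a_cell_gives_zero_lower_finite_upper(self):
        t = TwoByTwo(0, 3, 5, 7)
        res = exact_ci(t)
        assert res.ci_low == 0.0
        assert 0 < res.ci_high < math.inf
        assert res.ci_high == pytest.approx(grid_invert(scipy_tail_le, t, 0.05), rel=1e-6)

    def test_zero_bc_product_gives_infinite_upper(self):
        res = exact_ci(TwoByTwo(4, 0, 3, 7))
        assert res.ci_high == math.inf
        assert res.ci_low > 0

    def test_unit_table_contains_one(self):
        res = exact_ci(TwoByTwo(1, 1, 1, 1))
        assert res.ci_low < 1.0 < res.ci_high

    def test_interval_contains_conditional_mle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = TwoByTwo(*(int(v) for v in rng.integers(1, 15, size=4)))
            # oracle: solve the conditional score equation E_psi(X) = a
            f = lambda logpsi: (
                nchypergeom_fisher.mean(
                    t.n, t.a + t.b, t.a + t.c, math.exp(logpsi)
                )
                - t.a
            )
            mle = math.exp(brentq(f, -30, 30, xtol=1e-10))
            res = exact_ci(t)
            assert res.ci_low <= mle <= res.ci_high

    def test_converges_to_woolf_on_large_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = TwoByTwo(*(int(v) for v in rng.integers(50, 200, size=4)))
            e = exact_ci(t)
            w = woolf_ci(t)
            for exact_lim, woolf_lim in ((e.ci_low, w.ci_low), (e.ci_high, w.ci_high)):
                # exact equal-tail limits are conservative; allow a small
                # absolute slack where the log-limit itself is near zero
                assert abs(math.log(exact_lim) - math.log(woolf_lim)) < max(
                    0.05 * abs(math.log(woolf_lim)), 0.03
                )

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            exact_ci(TwoByTwo(0, 5, 0, 7))

    def test_mid_p_interval_is_narrower(self):
        t = TwoByTwo(8, 4, 3, 9)
        plain = exact_ci(t)
        mid = exact_ci(t, mid_p=True)
        assert plain.ci_low < mid.ci_low < mid.ci_high < plain.ci_high


class TestCornfieldApprox:
    def test_close_to_exact_for_moderate_table(self):
        t = TwoByTwo(20, 10, 8, 25)
        approx = cornfield_approx_ci(t)
        exact = exact_ci(t)
        assert math.log(approx.ci_low) == pytest.approx(
            math.log(exact.ci_low), abs=0.15
        )
        assert math.log(approx.ci_high) == pytest.approx(
            math.log(exact.ci_high), abs=0.15
        )

    def test_boundary_cell_refused(self):
        with pytest.raises(ValueError, match="exact_ci"):
            cornfield_approx_ci(TwoByTwo(0, 3, 5, 7))
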