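"""Rank-based valuation: relative ranks, choice rule, proportion predictions."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import mixedgambles as mg
from mixedgambles.dbs import ComparisonContext
from mixedgambles.errors import InvalidContextError, InvalidInputError


class TestRelativeRank:
    def test_ten_in_wide_and_narrow_contexts(self):
        # a 10-unit amount beats a quarter of a 0-40 experience pool and
        # half of a 0-20 pool
        assert mg.relative_rank(10, mg.uniform_pool(40, 41)) == 0.25
        assert mg.relative_rank(10, mg.uniform_pool(20, 21)) == 0.5

    def test_extremes(self):
        pool = (5.0, 10.0, 15.0)
        assert mg.relative_rank(1, pool) == 0.0
        assert mg.relative_rank(15, pool) == 1.0  # max, self excluded

    def test_midrank_with_ties_and_self_exclusion(self):
        # x=5 against [5, 5, 10]: one 5 is x itself; the other ties at 0.5
        assert mg.relative_rank(5, (5.0, 5.0, 10.0)) == 0.25

    def test_empty_pool_raises(self):
        with pytest.raises(InvalidContextError):
            mg.relative_rank(5, ())

    @given(
        pool=st.lists(st.integers(0, 50), min_size=1, max_size=20),
        xs=st.tuples(st.integers(0, 50), st.integers(0, 50)),
    )
    def test_monotone_in_x(self, pool, xs):
        lo, hi = sorted(xs)
        assert mg.relative_rank(lo, pool) <= mg.relative_rank(hi, pool)


class TestAcceptProbability:
    def _ctx_sym(self):
        levels = tuple(float(v) for v in range(1, 21))
        return ComparisonContext(levels, levels)

    def test_symmetric_context_equal_outcomes_indifferent(self):
        g = mg.MixedGamble(10, 10)
        for s in (0.5, 3.0, 10.0):
            p = mg.dbs_accept_probability(g, self._ctx_sym(), mg.DbSParams(s, 0.0))
            assert p == pytest.approx(0.5)

    def test_wide_gain_narrow_loss_context_rejects(self):
        ctx = ComparisonContext(mg.uniform_pool(40, 41), mg.uniform_pool(20, 21))
        p = mg.dbs_accept_probability(
            mg.MixedGamble(10, 10), ctx, mg.DbSParams(3.0, 0.0)
        )
        assert p < 0.5

    def test_zero_sensitivity_is_coin_flip(self):
        p = mg.dbs_accept_probability(
            mg.MixedGamble(3, 17), self._ctx_sym(), mg.DbSParams(0.0, 0.0)
        )
        assert p == 0.5

    def test_tremble_compresses_toward_half(self):
        ctx = ComparisonContext((1.0, 2.0, 20.0), (1.0, 2.0, 20.0))
        g = mg.MixedGamble(20, 1)  # top-rank gain, bottom-rank loss
        p0 = mg.dbs_accept_probability(g, ctx, mg.DbSParams(50.0, 0.0))
        pt = mg.dbs_accept_probability(g, ctx, mg.DbSParams(50.0, 0.1))
        assert p0 == pytest.approx(1.0, abs=1e-9)
        assert pt == pytest.approx(0.9, abs=1e-6)

    @given(
        gain=st.integers(1, 20),
        loss=st.integers(1, 20),
        sens=st.floats(0, 10),
    )
    def test_gain_loss_swap_antisymmetry(self, gain, loss, sens):
        gains = mg.uniform_pool(20, 21)
        losses = mg.uniform_pool(40, 41)
        ctx = ComparisonContext(gains, losses)
        swapped = ComparisonContext(losses, gains)
        params = mg.DbSParams(sens, 0.0)
        p = mg.dbs_accept_probability(mg.MixedGamble(gain, loss), ctx, params)
        q = mg.dbs_accept_probability(mg.MixedGamble(loss, gain), swapped, params)
        assert p + q == pytest.approx(1.0)

    def test_monotone_in_gamble(self):
        ctx = self._ctx_sym()
        params = mg.DbSParams(3.0, 0.05)
        probs = [
            mg.dbs_accept_probability(mg.MixedGamble(g, 10), ctx, params)
            for g in range(1, 21)
        ]
        assert probs == sorted(probs)


class TestPredictedProportions:
    def test_symmetric_condition_exactly_half(self):
        cond = mg.build_condition(20, 20, 5, "LL")
        # common set closed under gain/loss swap
        common = [mg.MixedGamble(4, 8), mg.MixedGamble(8, 4), mg.MixedGamble(12, 12)]
        tab = mg.predicted_proportion_table([cond], common, mg.DbSParams(3.0, 0.0))
        assert tab["mean_accept"].iloc[0] == pytest.approx(0.5)

    def test_two_gamble_enumeration_oracle(self):
        # hand enumeration of the two logistic terms at sensitivity 3
        cond = mg.build_condition(20, 20, 5, "LL")
        common = [mg.MixedGamble(4, 8), mg.MixedGamble(8, 4)]
        # pools are the levels {4,8,12,16,20}; rank(4)=0, rank(8)=0.25
        expected = (
            1 / (1 + math.exp(-3 * (0.0 - 0.25)))
            + 1 / (1 + math.exp(-3 * (0.25 - 0.0)))
        ) / 2
        tab = mg.predicted_proportion_table([cond], common, mg.DbSParams(3.0, 0.0))
        assert tab["mean_accept"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_four_condition_pattern(self, standard_conditions, common_standard):
        tab = mg.predicted_proportion_table(
            standard_conditions, common_standard, mg.DbSParams(3.0, 0.05)
        ).set_index("condition")["mean_accept"]
        assert tab["LH"] > 0.5 > tab["HL"]
        assert tab["LL"] == pytest.approx(0.5)
        assert tab["HH"] == pytest.approx(0.5)

    def test_empty_common_set_raises(self, standard_conditions):
        with pytest.raises(InvalidInputError):
            mg.predicted_proportion_table(standard_conditions, [], mg.DbSParams())
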