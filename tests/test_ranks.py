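import numpy as np
import pytest

from microstab.abundance import AbundanceTable
from microstab.ranks import (
    RankMatrix,
    RankReport,
    difference_variability,
    rank_over_time,
    rank_report,
    rank_variability,
    rsi,
    stability_islands,
)


def rel_table(rows, ids=None):
    rows = np.asarray(rows, float)
    rows = rows / rows.sum(axis=0)
    ids = ids or [f"T{i}" for i in range(rows.shape[0])]
    return AbundanceTable("s", ids, np.arange(rows.shape[1], dtype=float), rows,
                          is_relative=True)


class TestRankOverTime:
    def test_constant_order(self):
        tb = rel_table([[0.5] * 4, [0.3] * 4, [0.2] * 4])
        m = rank_over_time(tb, top_n=3)
        np.testing.assert_array_equal(m.ranks, [[1] * 4, [2] * 4, [3] * 4])

    def test_tie_broken_by_overall_rank(self):
        # T0 dominates overall; at t1 both tie -> T0 keeps the better rank
        tb = rel_table([[0.6, 0.5, 0.6], [0.4, 0.5, 0.4]])
        m = rank_over_time(tb, top_n=2)
        assert m.ranks[0, 1] == 1 and m.ranks[1, 1] == 2

    def test_swap_mid_series(self):
        tb = rel_table([[0.6, 0.6, 0.3, 0.6], [0.4, 0.4, 0.7, 0.4]])
        m = rank_over_time(tb, top_n=2)
        np.testing.assert_array_equal(m.ranks[0], [1, 1, 2, 1])
        np.testing.assert_array_equal(m.ranks[1], [2, 2, 1, 2])

    def test_columns_are_permutations(self):
        rng = np.random.default_rng(0)
        tb = rel_table(rng.dirichlet(np.ones(12), size=9).T)
        m = rank_over_time(tb, top_n=8)  # RankMatrix validates permutations
        assert m.N == 8 and m.t == 9

    def test_top_n_bounds(self):
        tb = rel_table([[0.6, 0.6], [0.4, 0.4]] )
        with pytest.raises(ValueError):
            rank_over_time(tb, top_n=1)
        with pytest.raises(ValueError):
            rank_over_time(tb, top_n=5)


class TestRSI:
    def test_constant_series_is_one(self):
        assert rsi([5] * 30, N=20) == 1.0

    def test_extreme_oscillation_is_zero(self):
        series = [1, 20] * 15
        assert rsi(series, N=20) == 0.0

    def test_hand_case(self):
        assert rsi([1, 2, 2], N=3, p=4) == pytest.approx(0.31640625, abs=1e-12)

    def test_rsi_monotone_in_cumulative_displacement(self):
        # more total rank hopping can never raise the index (fixed N, t, p)
        rng = np.random.default_rng(5)
        series = [rng.integers(1, 11, size=12) for _ in range(25)]
        D = [np.abs(np.diff(s)).sum() for s in series]
        vals = [rsi(s, N=10) for s in series]
        order = np.argsort(D)
        assert all(
            vals[order[i]] >= vals[order[i + 1]] - 1e-12
            for i in range(len(order) - 1)
        )

    def test_out_of_range_ranks_rejected(self):
        with pytest.raises(ValueError):
            rsi([0, 1, 2], N=3)
        with pytest.raises(ValueError):
            rsi([2], N=3)


class TestRVDV:
    def test_rv_zero_when_matching_overall_order(self):
        tb = rel_table([[0.5] * 4, [0.3] * 4, [0.2] * 4])
        m = rank_over_time(tb, top_n=3)
        np.testing.assert_allclose(rank_variability(m), 0.0)

    def test_rv_single_swap(self):
        # 10 taxa, overall order 1..10; one timepoint with top two swapped
        ranks = np.tile(np.arange(1, 11)[:, None], (1, 3))
        ranks[0, 1], ranks[1, 1] = 2, 1
        m = RankMatrix([f"T{i}" for i in range(10)], np.arange(3.0), ranks)
        np.testing.assert_allclose(rank_variability(m), [0.0, 0.2, 0.0])

    def test_rv_full_reversal_matches_brute_force(self):
        N = 10
        ranks = np.tile(np.arange(1, N + 1)[:, None], (1, 2))
        ranks[:, 1] = ranks[::-1, 1]
        m = RankMatrix([f"T{i}" for i in range(N)], np.arange(2.0), ranks)
        brute = sum(abs(i - (N + 1 - i)) for i in range(1, N + 1)) / N
        assert rank_variability(m)[1] == pytest.approx(brute)

    def test_dv_constant_and_swap(self):
        ranks = np.tile(np.arange(1, 11)[:, None], (1, 4))
        m = RankMatrix([f"T{i}" for i in range(10)], np.arange(4.0), ranks)
        dv = difference_variability(m)
        assert np.isnan(dv[0])
        np.testing.assert_allclose(dv[1:], 0.0)
        ranks2 = ranks.copy()
        ranks2[0, 2], ranks2[1, 2] = 2, 1
        m2 = RankMatrix([f"T{i}" for i in range(10)], np.arange(4.0), ranks2)
        dv2 = difference_variability(m2)
        assert dv2[2] == pytest.approx(0.2)

    def test_dv_equals_rv_after_overall_ordered_column(self):
        # when column k-1 equals the overall order, DV(k) == RV(k)
        rng = np.random.default_rng(1)
        N = 8
        col = rng.permutation(np.arange(1, N + 1))
        ranks = np.column_stack([np.arange(1, N + 1), col])
        m = RankMatrix([f"T{i}" for i in range(N)], np.arange(2.0), ranks)
        assert difference_variability(m)[1] == pytest.approx(rank_variability(m)[1])


class TestStabilityIslands:
    def _report(self, rsi_vals):
        n = len(rsi_vals)
        ranks = np.tile(np.arange(1, n + 1)[:, None], (1, 3))
        m = RankMatrix([f"T{i}" for i in range(n)], np.arange(3.0), ranks)
        rep = RankReport([f"T{i}" for i in range(n)], np.asarray(rsi_vals),
                         rank_variability(m), difference_variability(m))
        return rep, m

    def test_all_below_threshold_empty(self):
        rep, m = self._report([0.5] * 50)
        assert stability_islands(rep, m) == []

    def test_mid_rank_stable_taxon_flagged(self):
        vals = [0.3] * 50
        vals[0] = 0.95  # dominant, outside band
        vals[19] = 0.9  # overall rank 20: inside band, beats neighbours
        rep, m = self._report(vals)
        assert stability_islands(rep, m) == ["T19"]

    def test_dominant_taxon_not_flagged(self):
        vals = [0.2] * 50
        vals[0] = 0.99
        rep, m = self._report(vals)
        assert "T0" not in stability_islands(rep, m)


class TestRankReport:
    def test_invariant_to_taxon_relabeling(self):
        rng = np.random.default_rng(7)
        rows = rng.dirichlet(np.ones(10), size=6).T
        a = rel_table(rows, ids=[f"T{i}" for i in range(10)])
        b = rel_table(rows, ids=[f"Z{i}" for i in range(10)])
        _, ra = rank_report(a, top_n=10)
        _, rb = rank_report(b, top_n=10)
        np.testing.assert_allclose(np.sort(ra.rsi), np.sort(rb.rsi))
        np.testing.assert_allclose(ra.rv, rb.rv)
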