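import numpy as np
import pandas as pd
import pytest

import condfdr as cf

from conftest import make_sumstats


class TestEmpiricalCdf:
    def test_counting_with_ties_inclusive(self):
        e = cf.ecdf([0.1, 0.2, 0.3])
        assert e.evaluate(0.2) == pytest.approx(2 / 3)
        assert e.evaluate(0.05) == 0.0
        assert e.evaluate(1.0) == 1.0

    def test_matches_brute_force_rank_over_n(self):
        rng = np.random.default_rng(5)
        p = rng.random(500)
        e = cf.ecdf(p)
        for threshold in np.sort(p):  # oracle: exhaustive count at each value
            assert e.evaluate(threshold) == np.sum(p <= threshold) / p.size

    def test_non_decreasing(self):
        e = cf.ecdf(np.random.default_rng(6).random(200))
        grid = np.linspace(0, 1, 101)
        vals = e.evaluate(grid)
        assert np.all(np.diff(vals) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cf.ecdf([])


class TestPointEstimates:
    def test_fdr_arithmetic(self):
        assert cf.fdr_estimate(0.01, 0.2) == pytest.approx(0.05)
        assert cf.fdr_estimate(0.3, 0.3) == 1.0

    def test_neglog_relation(self):
        # -log10(FDR) = log10(q) - log10(p): horizontal Q-Q shift
        fdr = cf.fdr_estimate(0.01, 0.2)
        assert -np.log10(fdr) == pytest.approx(np.log10(0.2) - np.log10(0.01))
        assert -np.log10(fdr) == pytest.approx(1.301, abs=1e-3)

    def test_tdr_complements_fdr(self):
        for p, q in [(0.01, 0.2), (0.5, 0.9), (1e-6, 0.01)]:
            assert cf.tdr_estimate(p, q) + cf.fdr_estimate(p, q) == pytest.approx(1.0)
        assert cf.tdr_estimate(0.01, 0.2) == pytest.approx(0.95)
        assert cf.tdr_estimate(0.3, 0.3) == 0.0

    def test_q_zero_returns_one(self):
        assert cf.fdr_estimate(1e-8, 0.0) == 1.0


class TestConjunctionRule:
    @pytest.mark.parametrize("a, b, expected", [
        (0.044, 0.01872, 0.044),    # published conditional pair, max rule
        (0.038, 0.04536, 0.04536),  # rounds to the printed 0.045
        (0.2, 0.2, 0.2),
    ])
    def test_max_rule(self, a, b, expected):
        assert cf.conjunction_fdr(a, b) == expected

    def test_exceeds_neither_bound(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(100) + 1e-9, rng.random(100) + 1e-9
        out = cf.conjunction_fdr(x, y)
        assert np.all(out >= np.minimum(x, y))
        assert np.all((out == x) | (out == y))

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            cf.conjunction_fdr(bad, 0.5)


class TestConditionalSubset:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.primary = make_sumstats(rng.random(2_000))
        self.secondary = make_sumstats(rng.random(2_000))

    def test_threshold_zero_keeps_all_joined(self):
        subset = cf.conditional_subset(self.primary, self.secondary, 0.0)
        assert len(subset) == 2_000

    def test_threshold_semantics(self):
        subset = cf.conditional_subset(self.primary, self.secondary, 3.0)
        assert (subset["P_2"] <= 1e-3 + 1e-12).all()

    def test_nesting(self):
        sets = [set(cf.conditional_subset(self.primary, self.secondary, t)["SNP"])
                for t in (0.0, 1.0, 2.0, 3.0)]
        assert sets[3] <= sets[2] <= sets[1] <= sets[0]

    def test_empty_join_rejected(self):
        other = make_sumstats([0.5], start=10_000)
        with pytest.raises(ValueError):
            cf.conditional_subset(self.primary, other, 0.0)


class TestLookupTable:
    grid = np.round(np.arange(0.0, 5.01, 0.25), 10)

    def test_column_zero_equals_unconditional(self, default_sim):
        _, t1, t2, _ = default_sim
        table = cf.build_lookup(t1, t2, self.grid, self.grid)
        p1 = t1["P"].to_numpy()
        e = cf.ecdf(p1)
        expected = [cf.fdr_estimate(10.0 ** -g, e.evaluate(10.0 ** -g))
                    for g in self.grid]
        np.testing.assert_allclose(table.values[:, 0], expected)

    def test_independent_null_constant_across_conditioning(self, null_sim):
        _, t1, t2, _ = null_sim
        table = cf.build_lookup(t1, t2, self.grid, self.grid)
        # at moderate p1 the estimate should barely move with the threshold
        i = np.searchsorted(self.grid, 1.0)
        populated = ~table.inherited
        col = table.values[i, populated]
        assert col.max() - col.min() < 0.15 * col.mean()

    def test_enrichment_decreases_fdr_along_conditioning(self, default_sim):
        _, t1, t2, _ = default_sim
        table = cf.build_lookup(t1, t2, self.grid, self.grid)
        populated = ~table.inherited
        i = np.searchsorted(self.grid, 2.0)
        vals = table.values[i, populated]
        # trend on cell averages: strictest third below loosest third
        k = max(populated.sum() // 3, 1)
        assert vals[-k:].mean() < vals[:k].mean()

    def test_node_values_reproduce_direct_computation(self, default_sim):
        _, t1, t2, _ = default_sim
        table = cf.build_lookup(t1, t2, self.grid, self.grid,
                                min_subset_size=50)
        joined = cf.join_pair(t1, t2)
        rng = np.random.default_rng(10)
        for _ in range(25):
            i = rng.integers(0, self.grid.size)
            j = rng.integers(0, self.grid.size)
            if table.inherited[j]:
                continue
            p1 = np.power(10.0, -self.grid)[i]
            sub = joined.loc[-np.log10(joined["P_2"]) >= self.grid[j] - 1e-9, "P"]
            if len(sub) < 50:
                continue
            direct = cf.fdr_estimate(p1, np.sum(sub.to_numpy() <= p1) / len(sub))
            assert table.values[i, j] == direct  # bit-exact

    def test_underpopulated_cells_inherit_looser_column(self, default_sim):
        _, t1, t2, _ = default_sim
        wide = np.round(np.arange(0.0, 10.01, 0.5), 10)
        table = cf.build_lookup(t1, t2, self.grid, wide, min_subset_size=500)
        assert table.inherited.any()
        j_bad = int(np.flatnonzero(table.inherited)[0])
        j_src = int(np.flatnonzero(~table.inherited[:j_bad])[-1])
        np.testing.assert_array_equal(table.values[:, j_bad],
                                      table.values[:, j_src])

    def test_all_cells_underpopulated_is_error(self, default_sim):
        _, t1, t2, _ = default_sim
        with pytest.raises(ValueError):
            cf.build_lookup(t1, t2, self.grid, self.grid,
                            min_subset_size=10**9)


@pytest.fixture(scope="module")
def table(default_sim):
    _, t1, t2, _ = default_sim
    grid = np.round(np.arange(0.0, 5.01, 0.25), 10)
    return cf.build_lookup(t1, t2, grid, grid)


class TestLookupInterpolation:

    def test_exact_at_nodes_bit_identical(self, table):
        for i in (0, 3, 10, table.grid1.size - 1):
            for j in (0, 5, table.grid2.size - 1):
                got = cf.lookup_fdr(table, 10.0 ** -table.grid1[i],
                                    10.0 ** -table.grid2[j])
                assert got == table.values[i, j]

    def test_constant_between_equal_nodes(self):
        table = cf.CondFdrTable(
            grid1=np.array([0.0, 1.0]), grid2=np.array([0.0, 1.0]),
            values=np.full((2, 2), 0.3), subset_sizes=np.array([10, 10]),
            inherited=np.zeros(2, bool), q_zero=np.zeros((2, 2), bool))
        assert cf.lookup_fdr(table, 10 ** -0.5, 10 ** -0.5) == pytest.approx(0.3)

    def test_interpolant_within_surrounding_node_bounds(self, table):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 5, 1000)
        y = rng.uniform(0, 5, 1000)
        got = cf.lookup_fdr(table, 10.0 ** -x, 10.0 ** -y)
        i = np.clip(np.searchsorted(table.grid1, x) - 1, 0, table.grid1.size - 2)
        j = np.clip(np.searchsorted(table.grid2, y) - 1, 0, table.grid2.size - 2)
        corners = np.stack([table.values[i, j], table.values[i + 1, j],
                            table.values[i, j + 1], table.values[i + 1, j + 1]])
        assert np.all(got <= corners.max(axis=0) + 1e-12)
        assert np.all(got >= corners.min(axis=0) - 1e-12)

    def test_clamped_outside_grid(self, table):
        inside = cf.lookup_fdr(table, 10.0 ** -5.0, 1.0)
        outside = cf.lookup_fdr(table, 10.0 ** -8.0, 1.0)
        assert outside == inside  # boundary clamp


class TestAssignments:
    def test_conjunction_columns_consistent(self, default_sim):
        _, t1, t2, _ = default_sim
        grid = np.round(np.arange(0.0, 5.01, 0.5), 10)
        a = cf.assign_conjunction(t1, t2, grid, grid)
        np.testing.assert_allclose(
            a["CONJFDR"], np.maximum(a["CONDFDR_12"], a["CONDFDR_21"]))
        assert ((a["CONJFDR"] > 0) & (a["CONJFDR"] <= 1)).all()
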