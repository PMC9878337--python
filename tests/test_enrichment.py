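import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import bh_stepup_oracle

from rade.effects import EffectSets
from rade.enrichment import (
    PathwayCollection,
    bh_fdr,
    compare_combination,
    enrich,
    hypergeom_pvalue,
)
from rade.errors import InputError
from rade.perturbation import ConditionKey


def enumerate_tail(N, M, n, m):
    """Brute-force upper tail: enumerate all C(N, n) draws and count overlaps >= m."""
    universe = list(range(N))
    special = set(range(M))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(special & set(draw)) >= m:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_zero_overlap_is_one(self):
        assert hypergeom_pvalue(100, 10, 5, 0) == 1.0

    def test_five_sixths_case(self):
        assert hypergeom_pvalue(4, 2, 2, 1) == pytest.approx(5 / 6, abs=1e-12)

    def test_single_term_case(self):
        assert hypergeom_pvalue(10, 5, 5, 5) == pytest.approx(1 / 252, abs=1e-12)

    def test_matches_enumeration_on_small_worlds(self):
        for N in (5, 8):
            for M in range(N + 1):
                for n in range(N + 1):
                    for m in range(min(M, n) + 1):
                        assert hypergeom_pvalue(N, M, n, m) == pytest.approx(
                            enumerate_tail(N, M, n, m), abs=1e-12), (N, M, n, m)

    def test_monotone_decreasing_in_m(self):
        ps = [hypergeom_pvalue(50, 20, 15, m) for m in range(16)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_invalid_bounds_rejected(self):
        for bad in [(5, 6, 2, 1), (5, 2, 6, 1), (5, 2, 2, 3), (5, -1, 2, 0)]:
            with pytest.raises(InputError):
                hypergeom_pvalue(*bad)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_worked_case(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_empty_in_empty_out(self):
        assert len(bh_fdr([])) == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_textbook_stepup(self, ps):
        assert bh_fdr(ps) == pytest.approx(bh_stepup_oracle(ps), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.randoms())
    def test_permutation_equivariance(self, ps, rand):
        idx = list(range(len(ps)))
        rand.shuffle(idx)
        q = bh_fdr(ps)
        q_perm = bh_fdr([ps[i] for i in idx])
        assert q_perm == pytest.approx([q[i] for i in idx], abs=1e-12)


class TestEnrich:
    universe = {f"g{i}" for i in range(10)}

    def test_query_equals_universe_gives_p_one(self):
        coll = PathwayCollection({"pw": frozenset(["g0", "g1", "g2"])})
        res = enrich(set(self.universe), coll, self.universe)
        row = res.iloc[0]
        assert (row["m"], row["M"]) == (3, 3)
        assert row["p_value"] == pytest.approx(1.0)

    def test_half_overlap_single_term(self):
        coll = PathwayCollection({"pw": frozenset(f"g{i}" for i in range(5))})
        res = enrich({f"g{i}" for i in range(5)}, coll, self.universe)
        assert res.iloc[0]["p_value"] == pytest.approx(1 / 252, abs=1e-12)
        assert bool(res.iloc[0]["significant"])

    def test_empty_query_nothing_significant(self):
        coll = PathwayCollection({"pw": frozenset(["g0", "g1"])})
        res = enrich(set(), coll, self.universe)
        assert res.iloc[0]["m"] == 0
        assert res.iloc[0]["p_value"] == 1.0
        assert not res["significant"].any()

    def test_query_outside_universe_dropped(self):
        coll = PathwayCollection({"pw": frozenset(["g0"])})
        res = enrich({"g0", "not_measured"}, coll, self.universe)
        assert res.iloc[0]["n"] == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            enrich({"g0"}, PathwayCollection({"pw": frozenset(["g0"])}), set())

    def test_empty_collection_gives_empty_table(self):
        res = enrich({"g0"}, PathwayCollection({}), self.universe)
        assert len(res) == 0


def _effects(compound, reversed_genes, adverse_genes=(), cell_line="CL1", sig="toy"):
    rev, adv = frozenset(reversed_genes), frozenset(adverse_genes)
    return EffectSets(
        key=ConditionKey(compound, cell_line, "10 uM", "24 h"),
        reversed_genes=rev, adverse_genes=adv, universe=rev | adv | {"pad"},
        signature_name=sig,
    )


class TestComboComparison:
    def test_identical_sets_all_shared(self):
        a = _effects("A", {"g1", "g2"}, {"g3"})
        b = _effects("B", {"g1", "g2"}, {"g3"})
        c = compare_combination(a, b)
        assert c.reversed_shared == {"g1", "g2"} and not c.reversed_only_a
        assert c.adverse_shared == {"g3"} and not c.adverse_only_b

    def test_disjoint_sets(self):
        c = compare_combination(_effects("A", {"r1", "r2", "r3"}),
                                _effects("B", {"s1", "s2", "s3", "s4"}))
        assert not c.reversed_shared
        assert len(c.reversed_only_a) == 3 and len(c.reversed_only_b) == 4

    def test_hand_partition(self):
        c = compare_combination(_effects("A", {"g1", "g2", "g3"}),
                                _effects("B", {"g2", "g3", "g4", "g5"}))
        assert c.reversed_shared == {"g2", "g3"}
        assert c.reversed_only_a == {"g1"}
        assert c.reversed_only_b == {"g4", "g5"}

    def test_inclusion_exclusion_exact(self, rng):
        pool = [f"g{i}" for i in range(20)]
        for _ in range(20):
            ra = set(rng.choice(pool, size=8, replace=False))
            rb = set(rng.choice(pool, size=6, replace=False))
            c = compare_combination(_effects("A", ra), _effects("B", rb))
            assert len(c.reversed_only_a) + len(c.reversed_shared) == len(ra)
            assert len(c.reversed_only_b) + len(c.reversed_shared) == len(rb)

    def test_mismatched_cell_line_or_signature_rejected(self):
        with pytest.raises(InputError):
            compare_combination(_effects("A", {"g"}),
                                _effects("B", {"g"}, cell_line="CL2"))
        with pytest.raises(InputError):
            compare_combination(_effects("A", {"g"}),
                                _effects("B", {"g"}, sig="other"))
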