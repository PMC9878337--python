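import numpy as np
import pytest

from conftest import eq2_oracle, make_fc_vector, make_signature

from rade.effects import (
    RadeStatus,
    classify_effects,
    rade_from_counts,
    rade_score,
    rank_compounds,
    effect_table,
)
from rade.errors import ConfigError, InputError
from rade.perturbation import ConditionKey


class TestClassify:
    @pytest.mark.parametrize(
        "label,fc2,expected",
        [
            (1, -3.0, "reversed"),
            (-1, 3.0, "reversed"),
            (0, 16.0, "adverse"),
            (1, 16.0, "adverse"),
            (-1, -16.0, "adverse"),
            (1, 10.0, "none"),     # same direction but below the adverse threshold
            (1, 1.0, "none"),
            (0, -3.0, "none"),
            (1, -2.0, "none"),     # strict reversal boundary
            (0, 15.0, "none"),     # strict adverse boundary
        ],
    )
    def test_branch_table(self, label, fc2, expected):
        sig = make_signature({"g": label, "pad": 0})
        eff = classify_effects(sig, make_fc_vector({"g": fc2, "pad": 0.0}))
        got = ("reversed" if "g" in eff.reversed_genes
               else "adverse" if "g" in eff.adverse_genes else "none")
        assert got == expected

    def test_neutral_gene_strongly_downregulated_depends_on_mode(self):
        sig = make_signature({"g": 0})
        vec = make_fc_vector({"g": -16.0})
        assert "g" in classify_effects(sig, vec, adverse_mode="symmetric").adverse_genes
        assert "g" not in classify_effects(sig, vec, adverse_mode="strict_paper").adverse_genes

    def test_universe_is_shared_genes_only(self):
        sig = make_signature({"g1": 1, "g2": -1})
        eff = classify_effects(sig, make_fc_vector({"g2": 3.0, "g3": 3.0}))
        assert eff.universe == {"g2"}
        assert eff.reversed_genes == {"g2"}

    def test_degenerate_thresholds_rejected(self):
        sig = make_signature({"g": 1})
        with pytest.raises(ConfigError):
            classify_effects(sig, make_fc_vector({"g": 3.0}), adverse_threshold=2.0)

    def test_matches_branch_oracle_on_random_vectors(self, rng):
        """Vectorised classification equals per-gene branch evaluation."""
        genes = [f"g{i}" for i in range(20)]
        fc_pool = np.array([-16.0, -3.0, -1.0, 0.0, 1.0, 3.0, 16.0])
        for mode in ("symmetric", "strict_paper"):
            for _ in range(50):
                labels = dict(zip(genes, rng.choice([-1, 0, 1], size=20)))
                fcs = dict(zip(genes, rng.choice(fc_pool, size=20)))
                sig = make_signature({g: int(v) for g, v in labels.items()})
                eff = classify_effects(sig, make_fc_vector(fcs), adverse_mode=mode)
                for g in genes:
                    want = eq2_oracle(labels[g], fcs[g], mode)
                    got = ("reversed" if g in eff.reversed_genes
                           else "adverse" if g in eff.adverse_genes else "none")
                    assert got == want, (g, labels[g], fcs[g], mode)

    def test_reversed_and_adverse_always_disjoint(self, rng):
        genes = [f"g{i}" for i in range(30)]
        for _ in range(30):
            sig = make_signature(
                {g: int(v) for g, v in zip(genes, rng.choice([-1, 0, 1], size=30))})
            fcs = dict(zip(genes, rng.uniform(-30, 30, size=30)))
            eff = classify_effects(sig, make_fc_vector(fcs))
            assert eff.reversed_genes.isdisjoint(eff.adverse_genes)

    def test_raising_thresholds_never_grows_sets(self, rng):
        genes = [f"g{i}" for i in range(40)]
        sig = make_signature(
            {g: int(v) for g, v in zip(genes, rng.choice([-1, 0, 1], size=40))})
        fcs = dict(zip(genes, rng.uniform(-40, 40, size=40)))
        vec = make_fc_vector(fcs)
        base = classify_effects(sig, vec)
        tight_rev = classify_effects(sig, vec, reversal_threshold=5.0)
        tight_adv = classify_effects(sig, vec, adverse_threshold=25.0)
        assert tight_rev.reversed_genes <= base.reversed_genes
        assert tight_adv.adverse_genes <= base.adverse_genes


class TestRadeScore:
    def test_zero_adverse_convention(self):
        res = rade_from_counts(n_adverse=0, n_reversed=100, n_signature=500)
        assert res.score == 0.0
        assert res.status is RadeStatus.ZERO_ADVERSE

    def test_zero_adverse_applies_even_without_reversals(self):
        res = rade_from_counts(n_adverse=0, n_reversed=0, n_signature=500)
        assert res.score == 0.0
        assert res.status is RadeStatus.ZERO_ADVERSE

    def test_hand_computed_score(self):
        res = rade_from_counts(n_adverse=2, n_reversed=4, n_signature=8)
        assert res.score == pytest.approx(1.0)  # (2/4)*(8/4)
        assert res.status is RadeStatus.DEFINED

    def test_no_reversal_is_undefined(self):
        res = rade_from_counts(n_adverse=3, n_reversed=0, n_signature=8)
        assert res.score is None
        assert res.status is RadeStatus.UNDEFINED_NO_REVERSAL

    def test_scores_effect_sets_against_signature(self):
        sig = make_signature({"g1": 1, "g2": -1, "g3": 0})
        eff = classify_effects(sig, make_fc_vector({"g1": -3.0, "g2": 3.0, "g3": 16.0}))
        res = rade_score(eff, sig)
        assert (res.n_reversed, res.n_adverse, res.n_signature) == (2, 1, 2)
        assert res.score == pytest.approx((1 / 2) * (2 / 2))

    def test_monotone_in_counts(self):
        base = rade_from_counts(5, 10, 100).score
        assert rade_from_counts(6, 10, 100).score >= base
        assert rade_from_counts(5, 10, 120).score >= base
        assert rade_from_counts(5, 12, 100).score <= base


class TestRanking:
    def _result(self, n_adverse, n_reversed, n_signature=500, compound="c"):
        return rade_from_counts(
            n_adverse, n_reversed, n_signature,
            key=ConditionKey(compound, "CL1", "10 uM", "24 h"),
        )

    def test_stated_total_order(self):
        # two zero-adverse compounds (tie on score, broken by more reversals),
        # then finite scores ascending
        results = [
            self._result(217, 1165, 11644, "thiocolchicoside"),  # ~2.26
            self._result(0, 588, 500, "pemetrexed"),
            self._result(217, 1165, 2062, "topotecan"),          # ~0.4
            self._result(0, 676, 500, "cisplatin"),
        ]
        ranked = rank_compounds(results)
        assert [r.key.compound_id for r in ranked] == [
            "cisplatin", "pemetrexed", "topotecan", "thiocolchicoside"]
        assert [r.rank for r in ranked] == [1, 2, 3, 4]

    def test_single_result_rank_1(self):
        assert rank_compounds([self._result(1, 2)])[0].rank == 1

    def test_undefined_sort_last_lexicographic(self):
        ranked = rank_compounds([
            self._result(3, 0, compound="zeta"),
            self._result(3, 0, compound="alpha"),
            self._result(1, 10, compound="mid"),
        ])
        assert [r.key.compound_id for r in ranked] == ["mid", "alpha", "zeta"]
        assert ranked[1].rank == 2 and ranked[2].rank == 3

    def test_mixed_signatures_rejected(self):
        a = rade_from_counts(1, 2, 10, signature_name="sigA")
        b = rade_from_counts(1, 2, 10, signature_name="sigB")
        with pytest.raises(InputError):
            rank_compounds([a, b])


class TestEffectTable:
    def test_table_matches_sets(self):
        sig = make_signature({"g1": 1, "g2": -1, "g3": 0})
        vec = make_fc_vector({"g1": -3.0, "g2": -16.0, "g3": 1.0})
        eff = classify_effects(sig, vec)
        table = effect_table(eff, sig, vec)
        assert dict(zip(table["gene_id"], table["effect"])) == {
            "g1": "reversed", "g2": "adverse", "g3": "none"}
        assert dict(zip(table["gene_id"], table["e1_label"])) == {
            "g1": 1, "g2": -1, "g3": 0}
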