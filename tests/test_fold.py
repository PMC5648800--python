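"""Folding-engine unit and property tests, all anchored on the
exhaustive-enumeration oracle."""

import numpy as np
import pytest

from oracles import count_structures, enumeration_oracle, random_rna_string
from starkit import (
    EnergyModel,
    InputError,
    ModelError,
    SecondaryStructure,
    SizeError,
    cofold,
    enumerate_structures,
    fold_mfe,
    pair_probabilities,
)


class TestEnergyModel:
    def test_pair_scores(self, model):
        assert model.pair_score("G", "C") == 3
        assert model.pair_score("A", "U") == 2
        assert model.pair_score("U", "G") == 1
        assert model.pair_score("A", "G") == 0  # forbidden

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ModelError):
            EnergyModel(kT=0.0)
        with pytest.raises(ModelError):
            EnergyModel(min_loop=-1)


class TestSecondaryStructure:
    def test_dot_bracket_round_trip(self):
        s = SecondaryStructure(length=9, pairs=((0, 8), (1, 7), (2, 6)))
        assert s.to_dot_bracket() == "(((...)))"
        assert SecondaryStructure.from_dot_bracket("(((...)))") == s

    def test_dot_bracket_round_trip_with_strand_break(self):
        s = SecondaryStructure(length=8, pairs=((0, 7), (1, 6)), strand_break=4)
        db = s.to_dot_bracket()
        assert db == "((..&..))"
        assert SecondaryStructure.from_dot_bracket(db) == s

    def test_pseudoknot_rejected(self):
        with pytest.raises(InputError):
            SecondaryStructure(length=12, pairs=((0, 6), (3, 9)))

    def test_shared_position_rejected(self):
        with pytest.raises(InputError):
            SecondaryStructure(length=12, pairs=((0, 6), (0, 9)))

    def test_inter_pairs_counts_break_spanning_only(self):
        s = SecondaryStructure(
            length=10, pairs=((0, 9), (1, 8), (3, 7)), strand_break=5
        )
        assert s.inter_pairs() == 3
        assert SecondaryStructure(length=4, pairs=(), strand_break=2).inter_pairs() == 0


class TestFoldMfe:
    def test_hairpin_example(self, model):
        r = fold_mfe("GGGAAACCC", model)
        assert r.mfe_score == 9
        assert r.structure.pairs == ((0, 8), (1, 7), (2, 6))  # 1-based (1,9)(2,8)(3,7)

    @pytest.mark.parametrize("seq", ["AAAAAA", "GC"])
    def test_unfoldable_sequences(self, seq, model):
        r = fold_mfe(seq, model)
        assert r.mfe_score == 0 and r.structure.pairs == ()

    def test_empty_sequence_rejected(self, model):
        with pytest.raises(InputError):
            fold_mfe("", model)

    def test_deterministic_traceback(self, model):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = random_rna_string(rng, 15)
            assert fold_mfe(seq, model) == fold_mfe(seq, model)

    def test_score_equals_sum_of_pair_scores(self, model):
        rng = np.random.default_rng(6)
        for _ in range(20):
            seq = random_rna_string(rng, 20)
            r = fold_mfe(seq, model)
            total = sum(model.pair_score(seq[i], seq[j]) for i, j in r.structure.pairs)
            assert total == r.mfe_score

    def test_forbidden_pair_mask_never_improves_score(self, model):
        rng = np.random.default_rng(7)
        for _ in range(15):
            seq = random_rna_string(rng, 14)
            base = fold_mfe(seq, model).mfe_score
            i, j = sorted(rng.choice(len(seq), size=2, replace=False).tolist())
            masked = fold_mfe(seq, model, forbidden_pairs=[(i, j)]).mfe_score
            assert masked <= base


class TestCofold:
    def test_full_duplex(self, model):
        c = cofold("AAAA", "UUUU", model)
        assert c.inter_pairs == 4
        assert c.structure.to_dot_bracket() == "((((&))))"

    def test_no_pairing_possible(self, model):
        assert cofold("AAAA", "AAAA", model).inter_pairs == 0

    def test_gc_duplex_score(self, model):
        c = cofold("GGG", "CCC", model)
        assert c.inter_pairs == 3 and c.mfe_score == 9

    def test_min_loop_waived_across_break_only(self, model):
        # G and C alone cannot pair intramolecularly (loop 0 < 3) but can
        # across the strand break.
        assert fold_mfe("GC", model).mfe_score == 0
        assert cofold("G", "C", model).inter_pairs == 1

    def test_inter_pairs_bounded_by_shorter_strand(self, model):
        rng = np.random.default_rng(8)
        for _ in range(15):
            a = random_rna_string(rng, int(rng.integers(2, 12)))
            b = random_rna_string(rng, int(rng.integers(2, 12)))
            c = cofold(a, b, model)
            assert 0 <= c.inter_pairs <= min(len(a), len(b))

    def test_complementary_strands_pair_fully(self, model):
        # neither strand can self-pair: poly-A vs poly-U
        for k in (3, 5, 8):
            assert cofold("A" * k, "U" * k, model).inter_pairs == k


class TestEnumeration:
    def test_counts_for_trivial_cases(self, model):
        assert len(enumerate_structures("AAA", model)) == 1
        structs = enumerate_structures("GAAAC", model)
        assert len(structs) == 2
        assert {s.pairs for s in structs} == {(), ((0, 4),)}

    def test_count_matches_independent_recursion(self, model):
        rng = np.random.default_rng(9)
        for _ in range(20):
            seq = random_rna_string(rng, int(rng.integers(4, 13)))
            assert len(enumerate_structures(seq, model)) == count_structures(seq, model)
        assert len(enumerate_structures("GGGAAACCC", model)) == count_structures(
            "GGGAAACCC", model
        )

    def test_structures_unique(self, model):
        structs = enumerate_structures("GGGAAACCC", model)
        assert len({s.pairs for s in structs}) == len(structs)

    def test_complex_enumeration_counts(self, model):
        assert len(enumerate_structures(("G", "C"), model)) == 2  # empty + duplex
        rng = np.random.default_rng(10)
        for _ in range(10):
            a = random_rna_string(rng, int(rng.integers(2, 6)))
            b = random_rna_string(rng, int(rng.integers(2, 6)))
            assert len(enumerate_structures((a, b), model)) == count_structures(
                a + b, model, brk=len(a)
            )

    def test_length_guard(self, model):
        with pytest.raises(SizeError):
            enumerate_structures("A" * 15, model)


class TestOracleEquivalence:
    def test_mfe_and_probabilities_match_enumeration(self, model):
        rng = np.random.default_rng(11)
        for _ in range(60):
            seq = random_rna_string(rng, int(rng.integers(2, 13)))
            best, P, Z = enumeration_oracle(seq, model)
            r = pair_probabilities(seq, model)
            assert r.mfe_score == best
            assert abs(r.partition - Z) <= 1e-9 * Z
            assert np.abs(r.pair_prob - P).max() <= 1e-9

    def test_cofold_matches_enumeration(self, model):
        rng = np.random.default_rng(12)
        for _ in range(25):
            a = random_rna_string(rng, int(rng.integers(2, 7)))
            b = random_rna_string(rng, int(rng.integers(2, 7)))
            best, P, _ = enumeration_oracle((a, b), model)
            c = cofold(a, b, model, probabilities=True)
            assert c.mfe_score == best
            assert np.abs(c.pair_prob - P).max() <= 1e-9


class TestPairProbabilities:
    def test_unfoldable_sequence_has_unit_partition(self, model):
        r = pair_probabilities("AAAAAA", model)
        assert r.partition == 1.0
        assert np.all(r.pair_prob == 0.0)

    def test_row_sums_at_most_one(self, model):
        rng = np.random.default_rng(13)
        for _ in range(20):
            seq = random_rna_string(rng, int(rng.integers(2, 14)))
            r = pair_probabilities(seq, model)
            assert r.pair_prob.sum(axis=1).max() <= 1.0 + 1e-12

    def test_low_temperature_concentrates_on_unique_mfe(self):
        cold = EnergyModel(kT=0.05)
        r = pair_probabilities("GGGAAACCC", cold)
        for i, j in ((0, 8), (1, 7), (2, 6)):
            assert r.pair_prob[i, j] == pytest.approx(1.0, abs=1e-6)
        assert r.pair_prob.sum() == pytest.approx(6.0, abs=1e-5)
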