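import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protint.features import (
    FeatureSpace,
    aa_composition,
    build_space,
    dipeptide_composition,
    encode,
    f_score_rank,
    f_scores,
    top_feature_indices,
)
from protint.seqdata import AMINO_ACIDS, ProteinRecord
from conftest import make_dataset
from oracles import two_pass_f_scores

protein_seqs = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=80)


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", {"A": 1.0}),
            ("ACDE", {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}),
            ("AAC", {"A": 2 / 3, "C": 1 / 3}),
        ],
    )
    def test_examples(self, seq, expected):
        vec = aa_composition(seq)
        for i, aa in enumerate(AMINO_ACIDS):
            assert vec[i] == pytest.approx(expected.get(aa, 0.0))

    def test_empty_sequence_is_hard_error(self):
        with pytest.raises(ValueError):
            aa_composition("")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seq=protein_seqs)
    def test_sums_to_one(self, seq):
        assert aa_composition(seq).sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAA", {"AA": 1.0}),
            ("ACAC", {"AC": 2 / 3, "CA": 1 / 3}),
            ("AC", {"AC": 1.0}),
        ],
    )
    def test_dipeptide_examples(self, seq, expected):
        from protint.features import DIPEPTIDES
        vec = dipeptide_composition(seq)
        for i, dp in enumerate(DIPEPTIDES):
            assert vec[i] == pytest.approx(expected.get(dp, 0.0))
        assert vec.sum() == pytest.approx(1.0)

    def test_dipeptide_needs_two_residues(self):
        with pytest.raises(ValueError):
            dipeptide_composition("A")


class TestFeatureSpace:
    def test_registry_is_sorted_union(self):
        records = [
            ProteinRecord("P1", "AA", {"D2"}),
            ProteinRecord("P2", "CC", {"D1", "D2"}),
        ]
        space = build_space(records)
        assert space.domain_registry == ("D1", "D2")
        assert space.dimension == 22

    def test_no_domains_gives_composition_only(self):
        assert build_space([ProteinRecord("P1", "AA")]).dimension == 20

    def test_413_domains_give_433_dimensions(self):
        domains = {f"IPR{i:06d}" for i in range(413)}
        assert build_space([ProteinRecord("P1", "AA", domains)]).dimension == 433

    def test_empty_collection_is_hard_error(self):
        with pytest.raises(ValueError):
            build_space([])

    def test_duplicate_registry_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpace(domain_registry=("D1", "D1"))


class TestEncode:
    def test_domain_indicators_in_registry_order(self):
        space = FeatureSpace(domain_registry=("D1", "D2"))
        vec = encode(ProteinRecord("P", "AAAA", {"D2"}), space).values
        assert vec[0] == pytest.approx(1.0)  # composition A
        assert vec[20] == 0.0 and vec[21] == 1.0

    def test_unseen_domain_contributes_nothing(self):
        space = FeatureSpace(domain_registry=("D1", "D2"))
        with_unseen = encode(ProteinRecord("P", "AAAA", {"D9"}), space).values
        without = encode(ProteinRecord("P", "AAAA"), space).values
        assert np.array_equal(with_unseen, without)

    def test_all_registry_domains_present_gives_ones_block(self):
        space = FeatureSpace(domain_registry=("D1", "D2", "D3"))
        vec = encode(ProteinRecord("P", "AC", {"D1", "D2", "D3"}), space).values
        assert np.array_equal(vec[20:], np.ones(3))

    def test_dipeptide_block_appended_when_enabled(self):
        space = FeatureSpace(domain_registry=("D1",), include_dipeptides=True)
        assert space.dimension == 421
        vec = encode(ProteinRecord("P", "ACAC", {"D1"}), space).values
        assert vec.shape == (421,)
        assert vec[21:].sum() == pytest.approx(1.0)  # dipeptide block


class TestFScore:
    def test_worked_example(self):
        dataset = make_dataset([[2.0], [4.0], [0.0], [2.0]], [1, 1, 0, 0])
        assert f_scores(dataset.X, dataset.y)[0] == pytest.approx(0.5)

    def test_constant_feature_scores_zero(self):
        dataset = make_dataset([[1.0], [1.0], [1.0], [1.0]], [1, 1, 0, 0])
        assert f_scores(dataset.X, dataset.y)[0] == 0.0

    def test_perfect_separator_is_infinite_and_ranked_first(self):
        dataset = make_dataset(
            [[1.0, 0.3], [1.0, 0.9], [0.0, 0.2], [0.0, 0.8]], [1, 1, 0, 0]
        )
        ranking = f_score_rank(dataset)
        assert ranking[0].feature_index == 0
        assert ranking[0].f_score == np.inf
        assert [s.rank for s in ranking] == [1, 2]

    def test_label_swap_invariance(self, rng):
        X = rng.normal(size=(12, 5))
        y = np.array([1] * 6 + [0] * 6)
        assert np.allclose(f_scores(X, y), f_scores(X, 1 - y))

    def test_matches_two_pass_oracle(self, rng):
        X = rng.normal(size=(15, 8))
        y = (rng.random(15) < 0.5).astype(int)
        y[:2] = 1
        y[-2:] = 0
        assert np.allclose(f_scores(X, y), two_pass_f_scores(X, y), atol=1e-12)

    def test_needs_two_samples_per_class(self):
        with pytest.raises(ValueError):
            f_scores(np.zeros((3, 2)), np.array([1, 0, 0]))

    def test_ranks_are_a_permutation(self, rng):
        dataset = make_dataset(rng.normal(size=(10, 7)), [1] * 5 + [0] * 5)
        ranking = f_score_rank(dataset)
        assert sorted(s.rank for s in ranking) == list(range(1, 8))


def test_top_feature_indices_zero_selects_all(rng):
    X = rng.normal(size=(10, 6))
    y = np.array([1] * 5 + [0] * 5)
    assert np.array_equal(top_feature_indices(X, y, 0), np.arange(6))
    top2 = top_feature_indices(X, y, 2)
    assert len(top2) == 2
    assert np.array_equal(top2, np.sort(top2))
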