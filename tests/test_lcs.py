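"""Classic and semantic LCS dynamic programs against the brute-force oracle."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from lcscoder.lcs import brute_force_lcs, classic_lcs, semantic_lcs
from lcscoder.ontology import SynonymGroup, TermOntology, token_similarity


class TestClassicLCS:
    def test_identical_sequences(self):
        xs = ["w1", "w2", "w3", "w4"]
        assert classic_lcs(xs, xs).length == 4

    def test_empty_side_gives_zero(self):
        assert classic_lcs(["w1", "w2", "w3"], []).length == 0
        assert classic_lcs([], []).length == 0

    def test_worked_triple(self):
        xs = ["jia xing", "gan", "gan hun mi"]
        ys = ["jia xing", "bing du xing gan yan", "gan hun mi"]
        res = classic_lcs(xs, ys)
        assert res.length == 2
        assert res.length == brute_force_lcs(xs, ys)

    def test_matrix_invariants(self):
        xs, ys = ["a", "b", "a", "c"], ["b", "a", "c", "a"]
        res = classic_lcs(xs, ys)
        c = res.matrix
        assert all(c[0][j] == 0 for j in range(len(ys) + 1))
        assert all(c[i][0] == 0 for i in range(len(xs) + 1))
        for i in range(1, len(xs) + 1):
            for j in range(1, len(ys) + 1):
                assert c[i][j] >= c[i - 1][j] and c[i][j] >= c[i][j - 1]
                assert c[i][j] - c[i - 1][j - 1] in (0, 1)
        assert res.length == c[-1][-1]

    def test_matched_pairs_strictly_increasing(self):
        res = classic_lcs(["a", "b", "c", "d"], ["b", "x", "c", "d"])
        assert res.length == 3
        pairs = res.matched_pairs
        assert len(pairs) == res.length
        assert all(p1 < p2 and q1 < q2 for (p1, q1), (p2, q2) in zip(pairs, pairs[1:]))


ONTO = TermOntology(
    groups=(SynonymGroup("abbr", frozenset({"jia gan", "jia xing bing du xing gan yan"}), 0.9),)
)


class TestSemanticLCS:
    def test_abbreviation_matches_through_ontology(self):
        xs = ["jia gan", "gan hun mi"]
        ys = ["jia xing bing du xing gan yan", "gan hun mi"]
        assert semantic_lcs(xs, ys, ONTO, epsilon=0.8).length == 2
        assert classic_lcs(xs, ys).length == 1

    def test_empty_ontology_reduces_to_classic(self):
        xs, ys = ["a", "b", "c"], ["b", "c", "d"]
        assert semantic_lcs(xs, ys, TermOntology(), epsilon=0.5).length == classic_lcs(xs, ys).length

    def test_epsilon_one_strict_matches_nothing(self):
        xs = ["a", "b"]
        assert semantic_lcs(xs, xs, TermOntology(), epsilon=1.0).length == 0
        assert semantic_lcs(xs, xs, TermOntology(), epsilon=1.0, inclusive=True).length == 2

    def test_inclusive_threshold_at_group_weight(self):
        xs, ys = ["jia gan"], ["jia xing bing du xing gan yan"]
        assert semantic_lcs(xs, ys, ONTO, epsilon=0.9).length == 0
        assert semantic_lcs(xs, ys, ONTO, epsilon=0.9, inclusive=True).length == 1

    def test_epsilon_monotonicity(self):
        rng = random.Random(7)
        alphabet = ["a", "b", "c", "jia gan", "jia xing bing du xing gan yan"]
        for _ in range(50):
            xs = [rng.choice(alphabet) for _ in range(rng.randint(0, 6))]
            ys = [rng.choice(alphabet) for _ in range(rng.randint(0, 6))]
            lengths = [
                semantic_lcs(xs, ys, ONTO, epsilon=e).length
                for e in (0.0, 0.5, 0.85, 0.95, 1.0)
            ]
            assert lengths == sorted(lengths, reverse=True)

    def test_epsilon_validated(self):
        with pytest.raises(ValueError):
            semantic_lcs(["a"], ["a"], TermOntology(), epsilon=1.5)


class TestBruteForceOracle:
    def test_self_lcs_is_length(self):
        xs = ["a", "b", "c"]
        assert brute_force_lcs(xs, xs) == 3

    def test_disjoint_alphabets(self):
        assert brute_force_lcs(["a", "b"], ["c", "d"]) == 0

    def test_cap_enforced(self):
        with pytest.raises(ValueError):
            brute_force_lcs(["a"] * 13, ["a"])


@st.composite
def seq_pairs(draw):
    alphabet = ["a", "b", "c", "d", "e"]
    xs = draw(st.lists(st.sampled_from(alphabet), max_size=8))
    ys = draw(st.lists(st.sampled_from(alphabet), max_size=8))
    return xs, ys


class TestOracleEquivalence:
    @given(seq_pairs())
    @settings(max_examples=300, deadline=None)
    def test_classic_matches_brute_force(self, pair):
        xs, ys = pair
        res = classic_lcs(xs, ys)
        assert res.length == brute_force_lcs(xs, ys)
        assert res.length <= min(len(xs), len(ys))

    @given(seq_pairs(), st.floats(0.0, 1.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_semantic_matches_brute_force_with_random_ontology(self, pair, eps, seed):
        xs, ys = pair
        rng = random.Random(seed)
        letters = ["a", "b", "c", "d", "e"]
        groups = []
        for gi in range(rng.randint(0, 3)):
            members = frozenset(rng.sample(letters, rng.randint(2, 3)))
            groups.append(SynonymGroup(f"g{gi}", members, rng.uniform(0.1, 1.0)))
        onto = TermOntology(groups=tuple(groups))
        match = lambda a, b: token_similarity(a, b, onto) > eps
        assert semantic_lcs(xs, ys, onto, epsilon=eps).length == brute_force_lcs(xs, ys, match)
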