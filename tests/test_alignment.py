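import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spikeseq.alignment import (
    SimilarityStore,
    batch_edit_similarity,
    dense_distance_matrix,
    distance_from_similarity,
    edit_similarity,
    nw_score_strings,
)

from oracles import chain_oracle, lcs_by_enumeration


class TestClassicNW:
    def test_worked_example(self):
        score, sub = nw_score_strings("ATCGTAC", "ATGTTAT")
        assert score == 5
        assert sub == "ATGTA"

    @pytest.mark.parametrize("s", ["A", "GATTACA", "TTTT"])
    def test_self_alignment(self, s):
        score, sub = nw_score_strings(s, s)
        assert score == len(s)
        assert sub == s

    def test_disjoint_alphabets(self):
        score, sub = nw_score_strings("A", "T")
        assert score == 0
        assert sub == ""

    def test_empty_string(self):
        assert nw_score_strings("", "ACGT")[0] == 0

    def test_matches_lcs_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            s1 = "".join(rng.choice(list("ACGT"), rng.integers(1, 8)))
            s2 = "".join(rng.choice(list("ACGT"), rng.integers(1, 8)))
            score, sub = nw_score_strings(s1, s2)
            assert score == lcs_by_enumeration(s1, s2)
            assert len(sub) == score


def rand_window(rng, n, l, maxcount=2):
    return rng.integers(0, maxcount + 1, size=(n, l)).astype(float)


class TestEditSimilarity:
    def test_self_similarity_is_sum_of_squared_bins(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = rand_window(rng, 4, 6)
            expected = float((w * w).sum())
            for alpha in (0.05, 0.5, 2.0):
                assert edit_similarity(w, w, alpha).similarity == pytest.approx(expected)

    def test_shift_inside_window_is_free(self):
        # the same two-bin pattern at bins (1,2) vs (2,3): local restart makes
        # the offset free, so the score equals the self-similarity
        w1 = np.zeros((3, 6))
        w1[0, 1] = 1
        w1[1, 2] = 1
        w2 = np.zeros((3, 6))
        w2[0, 2] = 1
        w2[1, 3] = 1
        for alpha in (0.1, 1.0):
            shifted = edit_similarity(w1, w2, alpha).similarity
            assert shifted == pytest.approx(edit_similarity(w1, w1, alpha).similarity)

    def test_orthogonal_windows_score_zero(self):
        w1 = np.zeros((4, 5))
        w1[0] = 1
        w2 = np.zeros((4, 5))
        w2[1] = 1
        assert edit_similarity(w1, w2, 0.1).similarity == 0.0

    def test_score_non_increasing_in_alpha(self):
        # fixed internal lag: matches at bins (1, 4) vs (1, 2) force a gap
        w1 = np.zeros((2, 6))
        w1[0, 1] = 2
        w1[1, 4] = 2
        w2 = np.zeros((2, 6))
        w2[0, 1] = 2
        w2[1, 2] = 2
        alphas = [0.05, 0.1, 0.2, 0.5, 1.0]
        scores = [edit_similarity(w1, w2, a).similarity for a in alphas]
        oracle = [chain_oracle(w1, w2, a) for a in alphas]
        assert scores == pytest.approx(oracle)
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            w1 = rand_window(rng, 3, 5)
            w2 = rand_window(rng, 3, 5)
            a = edit_similarity(w1, w2, 0.3).similarity
            b = edit_similarity(w2, w1, 0.3).similarity
            assert a == pytest.approx(b)

    def test_non_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w1 = rng.normal(size=(3, 5))  # real-valued (z-scored) windows
            w2 = rng.normal(size=(3, 5))
            assert edit_similarity(w1, w2, 0.2).similarity >= 0.0

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="neuron dimension"):
            edit_similarity(np.zeros((3, 5)), np.zeros((4, 5)), 0.1)

    @pytest.mark.parametrize("alpha", [0.1, 0.2])
    def test_equals_brute_force_oracle(self, alpha):
        """DP equals exhaustive search over monotone partial alignments.

        Small-window domain (L <= 6, N <= 4, counts <= 2) where a single
        exponential gap charge is never beaten by splitting a run.
        """
        rng = np.random.default_rng(17)
        for _ in range(150):
            L = int(rng.integers(2, 7))
            N = int(rng.integers(1, 5))
            w1 = rand_window(rng, N, L)
            w2 = rand_window(rng, N, L)
            dp = edit_similarity(w1, w2, alpha).similarity
            assert dp == pytest.approx(chain_oracle(w1, w2, alpha), abs=1e-9)

    def test_traceback_pairs_strictly_monotone_and_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w1 = rand_window(rng, 4, 6)
            w2 = rand_window(rng, 4, 6)
            res = edit_similarity(w1, w2, 0.2, with_traceback=True)
            pairs = res.pairs
            assert all(
                a2 > a1 and b2 > b1
                for (a1, b1), (a2, b2) in zip(pairs, pairs[1:])
            )
            # score decomposes into matched products minus gap charges
            total = sum(float(w1[:, a] @ w2[:, b]) for a, b in pairs)
            for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
                gv, gh = a2 - a1 - 1, b2 - b1 - 1
                if gv > 0:
                    total -= np.exp(0.2 * gv)
                if gh > 0:
                    total -= np.exp(0.2 * gh)
            assert res.similarity == pytest.approx(total)

    def test_batch_kernel_agrees_with_traceback_version(self):
        rng = np.random.default_rng(5)
        windows = rng.integers(0, 3, size=(12, 5, 8)).astype(float)
        pairs = np.array([(i, j) for i in range(12) for j in range(i + 1, 12)])
        batch = batch_edit_similarity(windows, pairs, 0.4)
        single = [
            edit_similarity(windows[i], windows[j], 0.4).similarity for i, j in pairs
        ]
        np.testing.assert_allclose(batch, single)


class TestEditSimilarityHypothesis:
    window = arrays(np.int64, (3, 5), elements=st.integers(0, 2)).map(
        lambda a: a.astype(float)
    )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(w1=window, w2=window, alpha=st.floats(0.05, 1.0))
    def test_symmetric_nonnegative_and_self_maximal_form(self, w1, w2, alpha):
        s12 = edit_similarity(w1, w2, alpha).similarity
        s21 = edit_similarity(w2, w1, alpha).similarity
        assert s12 == pytest.approx(s21)
        assert s12 >= 0.0
        assert edit_similarity(w1, w1, alpha).similarity == pytest.approx(
            float((w1 * w1).sum())
        )


class TestDistanceTransform:
    def test_direct_formula(self):
        store = SimilarityStore(3)
        store.set(0, 1, 5.0)
        store.set(0, 2, 2.0)
        dist = distance_from_similarity(store)
        assert dist.get(0, 1) == 0.0
        assert dist.get(0, 2) == 3.0
        dense = dense_distance_matrix(store)
        assert dense[1, 2] == 5.0  # uncomputed pair at maximal distance
        assert dense[0, 0] == 0.0

    def test_all_equal_similarities_give_zero_distances(self):
        store = SimilarityStore(3)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            store.set(i, j, 4.0)
        assert all(v == 0.0 for v in distance_from_similarity(store).values.values())

    def test_order_reversal(self):
        rng = np.random.default_rng(6)
        store = SimilarityStore(6)
        for i in range(6):
            for j in range(i + 1, 6):
                store.set(i, j, float(rng.uniform(0, 10)))
        sims = store.values
        dists = distance_from_similarity(store).values
        emax_pair = max(sims, key=sims.get)
        assert dists[emax_pair] == min(dists.values())

    def test_empty_store_errors(self):
        with pytest.raises(ValueError, match="empty"):
            distance_from_similarity(SimilarityStore(3))
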