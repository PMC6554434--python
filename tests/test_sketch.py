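import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeseq.io import SpikeData, WindowConfig
from spikeseq.sketch import (
    BandParams,
    activity_masks,
    build_signatures,
    candidate_pairs,
    candidate_probability,
    estimate_jaccard_thresholds,
    jaccard,
    select_band_params,
)


class TestActivityMasks:
    def test_counts_anywhere_in_window_activate(self):
        w = np.zeros((1, 4, 10))
        w[0, 0, 2] = 3
        mask = activity_masks(w)
        assert mask.tolist() == [[True, False, False, False]]

    def test_all_zero_window(self):
        assert not activity_masks(np.zeros((1, 3, 5))).any()

    def test_invariant_under_moving_spikes_between_bins(self):
        rng = np.random.default_rng(0)
        w = rng.integers(0, 2, size=(5, 8)).astype(int)
        shuffled = np.zeros_like(w)
        for i in range(5):
            shuffled[i] = rng.permutation(w[i])
        np.testing.assert_array_equal(
            activity_masks(w[None]), activity_masks(shuffled[None])
        )


class TestJaccard:
    def test_identical_masks(self):
        m = np.array([1, 0, 1, 1], bool)
        assert jaccard(m, m) == 1.0

    def test_disjoint_supports(self):
        assert jaccard(np.array([1, 0, 0], bool), np.array([0, 1, 1], bool)) == 0.0

    def test_one_third(self):
        assert jaccard(np.array([1, 1, 0], bool), np.array([1, 0, 1], bool)) == pytest.approx(1 / 3)

    def test_both_empty_is_zero(self):
        z = np.zeros(4, bool)
        assert jaccard(z, z) == 0.0


class TestCandidateProbability:
    def test_printed_series_for_three_bands_of_five_rows(self):
        series = {0.3: 0.007, 0.5: 0.091, 0.7: 0.424, 0.8: 0.696, 0.9: 0.931}
        for s, expected in series.items():
            assert round(candidate_probability(s, 3, 5), 3) == expected

    def test_boundary_values(self):
        for b, l in [(1, 1), (3, 5), (30, 1)]:
            assert candidate_probability(0.0, b, l) == 0.0
            assert candidate_probability(1.0, b, l) == 1.0

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            candidate_probability(1.2, 3, 5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        s1=st.floats(0.0, 1.0),
        s2=st.floats(0.0, 1.0),
        b=st.integers(1, 30),
        l=st.integers(1, 30),
    )
    def test_monotone_in_similarity_and_bands(self, s1, s2, b, l):
        lo, hi = sorted((s1, s2))
        assert candidate_probability(lo, b, l) <= candidate_probability(hi, b, l) + 1e-12
        assert candidate_probability(s1, b, l) <= candidate_probability(s1, b + 1, l) + 1e-12
        assert candidate_probability(s1, b, l + 1) <= candidate_probability(s1, b, l) + 1e-12

    def test_monotonicity(self):
        s_grid = np.linspace(0, 1, 21)
        p = [candidate_probability(s, 3, 5) for s in s_grid]
        assert all(b >= a for a, b in zip(p, p[1:]))
        assert candidate_probability(0.5, 4, 5) >= candidate_probability(0.5, 3, 5)
        assert candidate_probability(0.5, 3, 6) <= candidate_probability(0.5, 3, 5)


def poisson_like_data(n_neurons, rate, duration, seed=0):
    rng = np.random.default_rng(seed)
    counts = np.full(n_neurons, int(rate * duration))
    ids = np.repeat(np.arange(n_neurons), counts)
    times = rng.uniform(0, duration, counts.sum())
    return SpikeData(ids, times, n_neurons, duration)


class TestJaccardThresholds:
    def test_uniform_rate_closed_form(self):
        # all neurons with p_i = p: jaccard1 = p / (2 - p); rates chosen so
        # that p = 1 - (1 - rate*b)^L = 0.5
        cfg = WindowConfig(0.2, 0.01)
        rate_per_bin = 1.0 - 0.5 ** (1 / cfg.n_bins)
        rate_hz = rate_per_bin / cfg.bin_size
        data = poisson_like_data(10, rate_hz, 100.0)
        j1, _ = estimate_jaccard_thresholds(data, cfg, 0)
        assert j1 == pytest.approx(0.5 / 1.5, rel=0.05)

    def test_zero_extra_collapses_thresholds(self):
        data = poisson_like_data(10, 2.0, 50.0)
        j1, j2 = estimate_jaccard_thresholds(data, WindowConfig(0.2, 0.01), 0)
        assert j1 == pytest.approx(j2)

    def test_silent_population(self):
        data = SpikeData(np.array([], dtype=int), np.array([]), 10, 10.0)
        j1, _ = estimate_jaccard_thresholds(data, WindowConfig(0.2, 0.01), 0)
        assert j1 == 0.0

    def test_too_large_extra_errors(self):
        data = poisson_like_data(5, 1.0, 50.0)
        with pytest.raises(ValueError, match="too large"):
            estimate_jaccard_thresholds(data, WindowConfig(0.2, 0.01), 50)


class TestBandSelection:
    def test_feasible_pair_found_and_valid(self):
        params = select_band_params(0.3, 0.9)
        assert candidate_probability(0.3, params.n_bands, params.rows_per_band) <= 0.1
        assert candidate_probability(0.9, params.n_bands, params.rows_per_band) >= 0.8

    def test_three_by_five_feasible_for_example_thresholds(self):
        assert candidate_probability(0.3, 3, 5) <= 0.1
        assert candidate_probability(0.9, 3, 5) >= 0.8

    def test_near_equal_thresholds_infeasible(self):
        with pytest.raises(ValueError, match="no \\(bands, rows\\)"):
            select_band_params(0.5, 0.51)

    def test_minimal_hash_budget(self):
        params = select_band_params(0.3, 0.9)
        for l in range(1, 51):
            for b in range(1, 51):
                if b * l < params.n_hashes:
                    assert not (
                        candidate_probability(0.3, b, l) <= 0.1
                        and candidate_probability(0.9, b, l) >= 0.8
                    )


class TestSignaturesAndPairs:
    def test_identical_masks_identical_columns(self):
        masks = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]], bool)
        sig = build_signatures(masks, BandParams(3, 4), seed=7)
        np.testing.assert_array_equal(sig[:, 0], sig[:, 1])

    def test_collision_frequency_matches_jaccard(self):
        """Single-row min-hash collision rate estimates Jaccard similarity.

        Monte-Carlo over >= 1e4 independent hash functions; the empirical
        rate must sit within 3 standard errors of the true Jaccard.
        """
        m1 = np.zeros(40, bool)
        m2 = np.zeros(40, bool)
        m1[:15] = True
        m2[8:20] = True  # intersection 7, union 20
        true_j = jaccard(m1, m2)
        n = 12000
        sig = build_signatures(np.stack([m1, m2]), BandParams(n, 1), seed=11)
        freq = np.mean(sig[:, 0] == sig[:, 1])
        se = np.sqrt(true_j * (1 - true_j) / n)
        assert abs(freq - true_j) < 3 * se

    def test_identical_columns_always_candidates(self):
        masks = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], bool)
        sig = build_signatures(masks, BandParams(4, 2), seed=0)
        pairs = candidate_pairs(sig, BandParams(4, 2))
        assert [0, 1] in pairs.tolist()

    def test_disjoint_masks_never_candidates(self):
        masks = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], bool)
        for seed in range(10):
            sig = build_signatures(masks, BandParams(5, 2), seed=seed)
            assert candidate_pairs(sig, BandParams(5, 2)).size == 0

    def test_empty_mask_excluded(self):
        masks = np.array([[1, 1, 0], [0, 0, 0], [1, 1, 0]], bool)
        sig = build_signatures(masks, BandParams(3, 2), seed=1)
        pairs = candidate_pairs(sig, BandParams(3, 2)).tolist()
        assert [0, 2] in pairs
        assert all(1 not in p for p in pairs)

    def test_relabeling_invariance_in_distribution(self):
        # permuting neuron ids and re-seeding leaves the *rate* of candidate
        # decisions for a fixed mask pair statistically unchanged
        rng = np.random.default_rng(3)
        m1 = rng.random(30) < 0.4
        m2 = rng.random(30) < 0.4
        params = BandParams(6, 2)

        def rate(mask1, mask2, seeds):
            hits = 0
            for s in seeds:
                sig = build_signatures(np.stack([mask1, mask2]), params, seed=s)
                hits += candidate_pairs(sig, params).size > 0
            return hits / len(seeds)

        perm = rng.permutation(30)
        r1 = rate(m1, m2, range(150))
        r2 = rate(m1[perm], m2[perm], range(1000, 1150))
        assert abs(r1 - r2) < 0.12
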