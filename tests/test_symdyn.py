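"""Symbolic dynamics: labeling, transitions, surrogates, LZ76, triplets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statescape.fixtures import markov_chain_fixture, second_order_chain
from statescape.meanshift import ClusterResult
from statescape.symbolic_dynamics import (
    LabelSequence,
    label_series,
    lz76_complexity,
    lz76_phrases,
    markov_surrogate,
    merge_fuzzy_centroids,
    relative_complexity,
    remove_self_transitions,
    stationary_distribution,
    transition_matrix,
    triplet_stats,
)


def brute_force_lz76_phrases(seq):
    """Independent exhaustive-history parser: each phrase is the longest
    reproducible extension (a substring of everything before its last
    character) plus one symbol."""
    s = list(seq)
    n = len(s)
    p = 0
    phrases = 0
    while p < n:
        length = 0
        while p + length < n:
            candidate = s[p : p + length + 1]
            history = s[: p + length]
            found = any(
                history[i : i + length + 1] == candidate for i in range(len(history) - length)
            )
            if found:
                length += 1
            else:
                break
        phrases += 1
        p += length + 1 if p + length < n else length
    return phrases


class TestLabeling:
    def _clusters(self):
        cents = np.array([[1, 1, 1, 1], [-1, -1, -1, -1]], dtype=np.int8)
        return ClusterResult(cents, np.array([10, 5]), np.array([], dtype=np.int64))

    def test_constant_series(self):
        clus = self._clusters()
        states = np.tile(clus.centroids[0], (6, 1))
        seq = label_series(states, clus)
        assert np.all(seq.labels == 0) and seq.alphabet_size == 2

    def test_nearest_centroid_with_mass_tiebreak(self):
        clus = self._clusters()
        states = np.array(
            [
                [1, 1, 1, -1],  # distance 1 vs 3 -> label 0
                [-1, -1, -1, 1],  # distance 3 vs 1 -> label 1
                [1, 1, -1, -1],  # tie -> larger mass -> label 0
            ],
            dtype=np.int8,
        )
        seq = label_series(states, clus)
        assert seq.labels.tolist() == [0, 1, 0]

    def test_empty_centroids_rejected(self):
        clus = ClusterResult(np.zeros((0, 4), np.int8), np.array([], np.int64), np.array([], np.int64))
        with pytest.raises(ValueError):
            label_series(np.ones((3, 4), dtype=np.int8), clus)


class TestSelfTransitions:
    def test_collapse_example(self):
        seq = LabelSequence(np.array([0, 0, 0, 1, 1, 0]), 2)  # AAABBA -> ABA
        out = remove_self_transitions(seq)
        assert out.labels.tolist() == [0, 1, 0]
        assert out.self_transitions_removed

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=60))
    def test_idempotent(self, labels):
        seq = LabelSequence(np.array(labels), 4)
        once = remove_self_transitions(seq)
        twice = remove_self_transitions(once)
        assert np.array_equal(once.labels, twice.labels)


class TestTransitionMatrix:
    def test_alternating_sequence(self):
        seq = LabelSequence(np.array([0, 1, 0, 1, 0, 1]), 2)
        tm = transition_matrix(seq)
        assert tm.P[0, 1] == 1.0 and tm.P[1, 0] == 1.0

    def test_hand_counted(self):
        labels = [0, 1, 1, 2, 0, 1, 2, 2, 0, 1]
        tm = transition_matrix(LabelSequence(np.array(labels), 3))
        # transitions from 0: ->1 x3 ; from 1: ->1 x1, ->2 x2 ; from 2: ->0 x2, ->2 x1
        assert tm.counts[0].tolist() == [0, 3, 0]
        assert tm.counts[1].tolist() == [0, 1, 2]
        assert tm.counts[2].tolist() == [2, 0, 1]
        assert np.allclose(tm.P.sum(axis=1), 1.0)


class TestSurrogates:
    def test_deterministic_cycle(self):
        P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        seq = markov_surrogate(P, 12, seed=0)
        diffs = (np.diff(seq.labels) - 1) % 3
        assert np.all(diffs == 0)

    def test_two_state_frequencies_binomial(self):
        P = np.array([[0.3, 0.7], [0.4, 0.6]])
        seq = markov_surrogate(P, 100000, seed=1)
        lab = seq.labels
        for a in (0, 1):
            sel = lab[:-1] == a
            n = sel.sum()
            p_emp = (lab[1:][sel] == 1).mean()
            assert abs(p_emp - P[a, 1]) < 3 * np.sqrt(P[a, 1] * (1 - P[a, 1]) / n)

    def test_stationary_distribution_power_iteration(self):
        P = np.array([[0.9, 0.1], [0.5, 0.5]])
        pi = stationary_distribution(P)
        assert np.allclose(pi @ P, pi, atol=1e-10)
        assert pi[0] == pytest.approx(5 / 6, abs=1e-9)


class TestLZ76:
    def test_classic_binary_string(self):
        # 0001101001000101 parses into 6 exhaustive-history phrases
        s = np.array([0, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 1])
        assert lz76_phrases(s) == 6
        assert brute_force_lz76_phrases(s) == 6

    @settings(max_examples=200, deadline=None)
    @given(
        st.integers(2, 5).flatmap(
            lambda A: st.lists(st.integers(0, A - 1), min_size=2, max_size=200)
        )
    )
    def test_equals_brute_force_reference(self, labels):
        got = lz76_phrases(np.array(labels, dtype=np.int64))
        assert got == brute_force_lz76_phrases(labels)

    def test_degenerate_alphabet_convention(self):
        S, C = lz76_complexity(np.zeros(50, dtype=np.int64), alphabet_size=1)
        assert C == 0.0 and S >= 1

    def test_iid_uniform_normalization_near_one(self):
        # C_LZ -> 1 for long iid uniform sequences (finite-length bias is
        # alphabet-dependent; small alphabets sit inside [0.95, 1.1])
        for A, n in ((2, 20000), (5, 20000)):
            cs = [
                lz76_complexity(np.random.default_rng(s).integers(0, A, n), alphabet_size=A)[1]
                for s in range(3)
            ]
            assert 0.95 < np.mean(cs) < 1.1


class TestRelativeComplexity:
    def test_markov_sample_centered_on_zero(self):
        rs = []
        for seed in range(10):
            seq, _ = markov_chain_fixture(K=13, length=10000, seed=seed, concentration=2.0)
            rs.append(relative_complexity(seq, n_surrogates=8, seed=seed).R)
        assert np.mean(np.abs(rs)) < 0.02

    def test_second_order_chain_positive(self):
        seq = second_order_chain(length=10000, seed=3, memory=0.85)
        res = relative_complexity(seq, n_surrogates=8, seed=4)
        assert res.R > 0.05

    def test_memory_monotonicity(self):
        # interpolating first -> second order dependence raises both R and
        # the triplet KL distance
        rs, kls = [], []
        for memory in (0.5, 0.7, 0.9):
            seq = second_order_chain(length=12000, seed=11, memory=memory)
            rs.append(relative_complexity(seq, n_surrogates=6, seed=12).R)
            kls.append(triplet_stats(seq, min_count=10, seed=13).kl_sample_vs_surrogate)
        assert rs[0] <= rs[1] <= rs[2]
        assert kls[0] <= kls[1] <= kls[2]


class TestTriplets:
    def test_deterministic_cycle_matches_prediction(self):
        labels = np.tile([0, 1], 50)  # 98 windows: 49 of each triplet, pi = 1/2
        rep = triplet_stats(LabelSequence(labels, 2), min_count=10, seed=0)
        assert np.allclose(rep.observed, rep.predicted, atol=1e-12)
        labels3 = np.tile([0, 1, 2], 50)
        rep3 = triplet_stats(LabelSequence(labels3, 3), min_count=10, seed=0)
        # up to boundary effects of the overlapping windows
        assert np.allclose(rep3.observed, rep3.predicted, atol=0.01)

    def test_hand_built_counts(self):
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        rep = triplet_stats(LabelSequence(labels, 2), min_count=3, seed=0)
        tri = {tuple(t): o for t, o in zip(rep.triplets, rep.observed)}
        # overlapping triplets: (0,1,0) x7, (1,0,1) x6, of 13 windows
        assert tri[(0, 1, 0)] == pytest.approx(7 / 13)
        assert tri[(1, 0, 1)] == pytest.approx(6 / 13)

    def test_markov_kl_smaller_than_second_order(self):
        for seed in (0, 1, 2):
            m_seq, _ = markov_chain_fixture(K=2, length=8000, seed=seed, concentration=2.0)
            s_seq = second_order_chain(length=8000, seed=seed, memory=0.85)
            kl_m = triplet_stats(m_seq, seed=seed).kl_sample_vs_surrogate
            kl_s = triplet_stats(s_seq, seed=seed).kl_sample_vs_surrogate
            assert kl_m < kl_s


class TestFuzzyCentroids:
    def test_identical_sets_full_detection(self):
        cents = np.array([[1] * 8, [-1] * 8, [1, 1, 1, 1, -1, -1, -1, -1]], dtype=np.int8)
        runs = [ClusterResult(cents, np.array([5, 4, 3]), np.array([], np.int64))] * 3
        cat = merge_fuzzy_centroids(runs, cut_distance=1.0)
        assert cat.representatives.shape[0] == 3
        assert cat.detection.all()
        assert cat.mass_share.sum() == pytest.approx(1.0)

    def test_matches_brute_force_complete_linkage(self):
        cents = np.array(
            [
                [1, 1, 1, 1, 1, 1],
                [1, 1, 1, 1, 1, -1],  # d=1 from first
                [-1, -1, -1, 1, 1, 1],  # far
                [-1, -1, -1, 1, 1, -1],  # d=1 from previous
                [1, -1, 1, -1, 1, -1],  # isolated
            ],
            dtype=np.int8,
        )
        cat = merge_fuzzy_centroids([cents], cut_distance=2.0)
        groups = [set(np.flatnonzero(cat.group_of == g)) for g in range(cat.representatives.shape[0])]
        assert sorted(map(sorted, groups)) == [[0, 1], [2, 3], [4]]

    def test_recovery_threshold_from_quantile(self):
        rng = np.random.default_rng(2)
        ref = rng.choice([-1, 1], size=(3, 30)).astype(np.int8)
        runs = [np.vstack([ref, rng.choice([-1, 1], size=(5, 30))]).astype(np.int8)]
        cat = merge_fuzzy_centroids(runs, cut_distance=2.0, reference_centroids=ref)
        assert cat.recovered is not None and cat.recovered.all()
        assert 0 < cat.recovery_threshold < 1
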