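import itertools

import numpy as np
import pytest

import popmix as pm
from popmix import (
    ClusterPartition,
    SAConfig,
    SAState,
    allele_counts,
    cluster_freqs,
    cluster_loglik,
    overall_freqs,
    partition_loglik,
    sa_search,
    scaled_cluster_loglik,
)

from conftest import make_gm


def naive_counts(gm, assignment, K):
    """Per-individual loop tally, the oracle for the vectorised version."""
    jmax = int(gm.alleles_per_locus.max())
    c = np.zeros((K, gm.n_loci, jmax))
    for i in range(gm.n_individuals):
        for l in range(gm.n_loci):
            for a in range(2):
                j = gm.genotypes[i, l, a]
                if j >= 0:
                    c[assignment[i], l, j] += 1
    return c


def naive_partition_loglik(gm, assignment, K, s):
    """Independent recomposition of counts, frequencies and scaling."""
    c = naive_counts(gm, assignment, K)
    c_l = c.sum(axis=0)
    p = c_l / c_l.sum(axis=1, keepdims=True)
    n = gm.n_individuals
    sizes = np.bincount(assignment, minlength=K)
    total = 0.0
    for k in range(K):
        lk = 0.0
        for l in range(gm.n_loci):
            denom = 1.0 + c[k, l].sum()
            for j in range(int(gm.alleles_per_locus[l])):
                if c[k, l, j] > 0:
                    lk += c[k, l, j] * np.log((p[l, j] + c[k, l, j]) / denom)
        if s == 0:
            total += lk
        else:
            total += lk / (1.0 + np.exp(s * sizes[k] / (8.0 * n)))
    return total


class TestCountsAndFreqs:
    def test_direct_tally(self):
        gm = make_gm([[[0, 0]], [[0, 1]]])
        part = ClusterPartition(np.array([0, 0]), 1)
        c = allele_counts(gm, part)
        np.testing.assert_array_equal(c.counts[0, 0], [3, 1])

    def test_missing_contributes_nothing(self):
        gm = make_gm(
            [[[0, 1], [0, 1]], [[0, 1], [0, 0]]],
            missing=[[[False] * 2, [False] * 2], [[True] * 2, [False] * 2]],
        )
        c = allele_counts(gm, ClusterPartition(np.array([0, 0]), 1))
        np.testing.assert_array_equal(c.counts[0, 0], [1, 1])
        np.testing.assert_array_equal(c.counts[0, 1], [3, 1])

    def test_matches_naive_loops(self, rng):
        raw = rng.integers(0, 3, size=(4, 5, 2))
        gm = make_gm(raw)
        assign = np.array([0, 1, 0, 1])
        c = allele_counts(gm, ClusterPartition(assign, 2))
        np.testing.assert_array_equal(c.counts, naive_counts(gm, assign, 2))
        np.testing.assert_array_equal(c.overall_counts, c.counts.sum(axis=0))

    @pytest.mark.parametrize(
        "counts,expected",
        [([4.0, 4.0], [0.5, 0.5]), ([9.0, 1.0], [0.9, 0.1]), ([2.0, 5.0, 3.0], [0.2, 0.5, 0.3])],
    )
    def test_overall_freqs(self, counts, expected):
        gm_counts = pm.mixture.ClusterCounts(
            np.array(counts)[None, None, :], np.array([len(counts)])
        )
        np.testing.assert_allclose(overall_freqs(gm_counts)[0], expected)

    def test_cluster_freqs_prior_blend(self):
        c = pm.mixture.ClusterCounts(
            np.array([[[3.0, 1.0]], [[1.0, 3.0]]]), np.array([2])
        )
        p = overall_freqs(c)
        np.testing.assert_allclose(p[0], [0.5, 0.5])
        pk = cluster_freqs(c, p)
        np.testing.assert_allclose(pk[0, 0], [0.7, 0.3])
        np.testing.assert_allclose(pk[1, 0], [0.3, 0.7])

    def test_cluster_freqs_prior_only_when_empty(self):
        c = pm.mixture.ClusterCounts(
            np.array([[[6.0, 2.0]], [[0.0, 0.0]]]), np.array([2])
        )
        p = overall_freqs(c)
        pk = cluster_freqs(c, p)
        np.testing.assert_allclose(pk[1, 0], p[0])

    def test_cluster_freqs_large_count_limit(self):
        c = pm.mixture.ClusterCounts(
            np.array([[[3e6, 1e6]]]), np.array([2])
        )
        pk = cluster_freqs(c, overall_freqs(c))
        np.testing.assert_allclose(pk[0, 0], [0.75, 0.25], atol=1e-6)

    def test_simplex_invariant(self, rng):
        raw = rng.integers(0, 4, size=(10, 6, 2))
        gm = make_gm(raw)
        assign = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        c = allele_counts(gm, ClusterPartition(assign, 3))
        pk = cluster_freqs(c, overall_freqs(c))
        mask = np.arange(pk.shape[2])[None, :] < gm.alleles_per_locus[:, None]
        sums = (pk * mask[None]).sum(axis=2)
        np.testing.assert_allclose(sums, 1.0)


class TestLoglik:
    def test_scalar_example(self):
        counts = np.array([[[3.0, 1.0]]])
        freqs = np.array([[[0.7, 0.3]]])
        assert cluster_loglik(counts[0], freqs[0]) == pytest.approx(
            3 * np.log(0.7) + np.log(0.3), abs=1e-9
        )
        assert cluster_loglik(counts[0], freqs[0]) == pytest.approx(-2.27400, abs=1e-4)

    def test_monomorphic_and_empty_contribute_zero(self):
        counts = np.array([[4.0, 0.0], [0.0, 0.0]])
        freqs = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert cluster_loglik(counts, freqs) == 0.0

    def test_scaling_example(self):
        val = scaled_cluster_loglik(-100.0, 40, 80, 2)
        assert val == pytest.approx(-100.0 / (1 + np.exp(0.125)), abs=1e-6)
        assert val == pytest.approx(-46.8787, abs=1e-3)

    def test_scaling_disabled_at_zero(self):
        assert scaled_cluster_loglik(-57.3, 10, 100, 0) == -57.3

    def test_scaling_increases_with_cluster_size(self):
        vals = [scaled_cluster_loglik(-100.0, nk, 100, 2) for nk in (10, 50, 90)]
        assert vals[0] < vals[1] < vals[2]

    @pytest.mark.parametrize("s", [0, 2])
    def test_partition_loglik_matches_independent_recomputation(self, rng, s):
        raw = rng.integers(0, 3, size=(6, 3, 2))
        gm = make_gm(raw)
        assign = np.array([0, 1, 0, 1, 1, 0])
        part = ClusterPartition(assign, 2)
        assert partition_loglik(gm, part, s) == pytest.approx(
            naive_partition_loglik(gm, assign, 2, s), abs=1e-9
        )

    def test_k1_partition_equals_whole_sample_loglik(self, tiny_gm):
        part = ClusterPartition(np.zeros(6, dtype=int), 1)
        c = allele_counts(tiny_gm, part)
        pk = cluster_freqs(c, overall_freqs(c))
        assert partition_loglik(tiny_gm, part, 0) == pytest.approx(
            cluster_loglik(c.counts[0], pk[0])
        )


class TestMoveDelta:
    def _random_state(self, rng, n=8, L=6, s=0):
        raw = rng.integers(0, 3, size=(n, L, 2))
        gm = make_gm(raw)
        assign = np.array([0, 1] * (n // 2))
        return gm, SAState(gm, ClusterPartition(assign, 2), s)

    @pytest.mark.parametrize("s", [0, 2])
    def test_delta_matches_scratch_recomputation(self, rng, s):
        gm, state = self._random_state(rng, s=s)
        for i in range(8):
            to = 1 - int(state.assignment[i])
            if state.sizes[state.assignment[i]] <= 1:
                continue
            before = partition_loglik(gm, state.partition(), s)
            delta = state.move_delta(i, to)
            assign2 = state.assignment.copy()
            assign2[i] = to
            after = partition_loglik(gm, ClusterPartition(assign2, 2), s)
            assert delta == pytest.approx(after - before, abs=1e-9)

    def test_move_and_return_cancels(self, rng):
        gm, state = self._random_state(rng)
        d1 = state.apply_move(2, 1 - int(state.assignment[2]))
        d2 = state.apply_move(2, 1 - int(state.assignment[2]))
        assert d1 + d2 == pytest.approx(0.0, abs=1e-9)

    def test_all_missing_individual_zero_delta(self):
        raw = np.zeros((4, 3, 2), dtype=int)
        raw[:3] = [[[0, 1]] * 3, [[1, 1]] * 3, [[0, 0]] * 3]
        missing = np.zeros((4, 3, 2), dtype=bool)
        missing[3] = True
        gm = make_gm(raw, missing)
        state = SAState(gm, ClusterPartition(np.array([0, 0, 1, 1]), 2), 0)
        assert state.move_delta(3, 0) == pytest.approx(0.0, abs=1e-12)

    def test_emptying_move_rejected(self, rng):
        gm, state = self._random_state(rng)
        state.apply_move(0, 1)
        state.apply_move(2, 1)
        state.apply_move(4, 1)
        with pytest.raises(ValueError):
            state.move_delta(6, 1)

    def test_incremental_agrees_with_scratch_after_many_moves(self, rng):
        """Cached objective tracks a from-scratch recomputation."""
        raw = rng.integers(0, 3, size=(12, 8, 2))
        gm = make_gm(raw)
        assign = np.arange(12) % 3
        state = SAState(gm, ClusterPartition(assign, 3), 2)
        accepted = 0
        while accepted < 1000:
            i = int(rng.integers(12))
            frm = int(state.assignment[i])
            if state.sizes[frm] <= 1:
                continue
            to = int(rng.integers(2))
            if to >= frm:
                to += 1
            state.apply_move(i, to)
            accepted += 1
        scratch = partition_loglik(gm, state.partition(), 2)
        assert state.objective == pytest.approx(scratch, abs=1e-6)


def exhaustive_best_bipartition(gm, s=0):
    """Oracle: enumerate all non-empty 2-cluster partitions."""
    n = gm.n_individuals
    best = -np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        assign = np.array((0,) + bits)
        if assign.sum() == 0:
            continue
        val = partition_loglik(gm, ClusterPartition(assign, 2), s)
        best = max(best, val)
    return best


class TestSaSearch:
    def test_k1_no_search(self, tiny_gm):
        res = sa_search(tiny_gm, 1, SAConfig(seed=0))
        assert res.partition.K == 1
        assert res.objective == pytest.approx(
            partition_loglik(tiny_gm, res.partition, 0)
        )

    def test_k_exceeding_n_rejected(self, tiny_gm):
        with pytest.raises(ValueError):
            sa_search(tiny_gm, 7)

    def test_seeded_determinism(self, tiny_gm):
        cfg = SAConfig(seed=42, n_restarts=2)
        a = sa_search(tiny_gm, 2, cfg)
        b = sa_search(tiny_gm, 2, cfg)
        np.testing.assert_array_equal(a.partition.assignment, b.partition.assignment)
        assert a.objective == b.objective

    def test_final_objective_not_below_initial(self, rng):
        raw = rng.integers(0, 2, size=(10, 12, 2))
        gm = make_gm(raw)
        init = ClusterPartition(np.arange(10) % 2, 2)
        res = sa_search(gm, 2, SAConfig(seed=1, n_restarts=1))
        assert res.objective >= partition_loglik(gm, init, 0) - 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """SA finds the global optimum on instances small enough to enumerate."""
        rng = np.random.default_rng(seed)
        raw = rng.integers(0, 2, size=(8, 20, 2))
        gm = make_gm(raw)
        res = sa_search(gm, 2, SAConfig(seed=seed, n_restarts=3))
        assert res.objective == pytest.approx(exhaustive_best_bipartition(gm), abs=1e-9)

    def test_island_structure_recovered(self):
        """Clustering recovers the true partition of well-separated islands."""
        spec = pm.SimulationSpec(K=3, fst=0.1, n_loci=300, sample_sizes=(20, 20, 20), seed=9)
        gm, q_true, _ = pm.simulate_sample(spec)
        res = sa_search(gm, 3, SAConfig(seed=5, n_restarts=2))
        assert pm.aae(q_true, res.partition.indicator_q()) == pytest.approx(0.0, abs=1e-12)
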