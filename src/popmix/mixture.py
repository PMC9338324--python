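"""Mixture-model clustering by simulated annealing.

Under the mixture (no-admixture) model each individual's genome originates
wholly from one of K source populations.  A clustering configuration
``Omega`` partitions the N individuals into K non-empty clusters; its
log-likelihood is the sum over clusters of

    L_k = sum_l sum_j c_klj * log(p_klj)

with allele counts ``c_klj`` tallied within the cluster and frequencies
estimated with the whole-sample frequency as a unit-weight prior,

    p_klj = (p_lj + c_klj) / (1 + sum_m c_klm),    p_lj = c_lj / sum_m c_lm.

To counter the split-large/merge-small pathology under unbalanced sampling,
each cluster's log-likelihood may be scaled by its size,

    L_Sk = L_k / (1 + exp(s * N_k / (8 N))),    s in {1, 2, 3},

before summation; s = 0 leaves the likelihood unscaled.  The scaled sum is
maximised over partitions by a Metropolis simulated-annealing search with
single-individual reassignment proposals and geometric cooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .genodata import DegenerateLocusError, GenotypeMatrix

__all__ = [
    "SAConfig",
    "ClusterPartition",
    "ClusterCounts",
    "ClusteringResults",
    "allele_counts",
    "overall_freqs",
    "cluster_freqs",
    "cluster_loglik",
    "scaled_cluster_loglik",
    "partition_loglik",
    "SAState",
    "sa_search",
]


@dataclass(frozen=True)
class SAConfig:
    """Annealing schedule and search options.

    ``initial_temperature=None`` calibrates T0 from the data so that roughly
    80% of single-individual moves from the initial random partition would be
    accepted.  ``scaling_level`` is the cluster-size scaling exponent s
    (0 disables scaling).
    """

    initial_temperature: float | None = None
    cooling_factor: float = 0.9
    sweeps_per_temperature: int = 10
    stop_stall_temperatures: int = 5
    n_restarts: int = 10
    scaling_level: int = 0
    seed: int = 0
    max_temperature_levels: int = 500

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.scaling_level not in (0, 1, 2, 3):
            raise ValueError("scaling_level must be one of 0, 1, 2, 3")
        if min(self.sweeps_per_temperature, self.stop_stall_temperatures, self.n_restarts) < 1:
            raise ValueError("schedule counters must be positive")


@dataclass
class ClusterPartition:
    """Hard assignment of N individuals to K non-empty clusters."""

    assignment: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        sizes = np.bincount(self.assignment, minlength=self.K)
        if len(sizes) > self.K or np.any(sizes == 0):
            raise ValueError("every cluster must be non-empty and labels < K")

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.K)

    @property
    def n_individuals(self) -> int:
        return self.assignment.size

    def indicator_q(self) -> np.ndarray:
        """0/1 ancestry matrix equivalent of the hard partition."""
        q = np.zeros((self.assignment.size, self.K))
        q[np.arange(self.assignment.size), self.assignment] = 1.0
        return q


@dataclass
class ClusterCounts:
    """Allele-copy counts c_klj per cluster (padded to the max J_l)."""

    counts: np.ndarray  # (K, L, Jmax)
    alleles_per_locus: np.ndarray

    @property
    def overall_counts(self) -> np.ndarray:
        """c_lj: allele copies at locus l in the entire sample."""
        return self.counts.sum(axis=0)


def allele_counts(gm: GenotypeMatrix, part: ClusterPartition) -> ClusterCounts:
    """Tally non-missing allele copies per (cluster, locus, allele)."""
    jmax = int(gm.alleles_per_locus.max())
    counts = np.zeros((part.K, gm.n_loci, jmax))
    geno = gm.genotypes
    lidx = np.broadcast_to(np.arange(gm.n_loci)[None, :, None], geno.shape)
    kidx = np.broadcast_to(part.assignment[:, None, None], geno.shape)
    obs = geno >= 0
    np.add.at(counts, (kidx[obs], lidx[obs], geno[obs]), 1.0)
    return ClusterCounts(counts, gm.alleles_per_locus)


def overall_freqs(counts: ClusterCounts) -> np.ndarray:
    """Whole-sample allele frequencies p_lj = c_lj / sum_m c_lm."""
    c = counts.overall_counts
    tot = c.sum(axis=1, keepdims=True)
    if np.any(tot == 0):
        raise DegenerateLocusError("locus with zero observed allele copies")
    return c / tot


def cluster_freqs(counts: ClusterCounts, overall: np.ndarray) -> np.ndarray:
    """p_klj = (p_lj + c_klj) / (1 + sum_m c_klm), a unit-weight prior blend."""
    denom = 1.0 + counts.counts.sum(axis=2, keepdims=True)
    return (overall[None] + counts.counts) / denom


def cluster_loglik(counts_k: np.ndarray, freqs_k: np.ndarray) -> float:
    """L_k = sum c_klj log p_klj over entries with a positive count."""
    pos = counts_k > 0
    return float(np.sum(counts_k[pos] * np.log(freqs_k[pos])))


def scaled_cluster_loglik(lk: float, n_k: int, n: int, s: int) -> float:
    """Cluster-size scaling; s = 0 returns the unscaled value."""
    if s == 0:
        return lk
    return lk / (1.0 + np.exp(s * n_k / (8.0 * n)))


def partition_loglik(gm: GenotypeMatrix, part: ClusterPartition, s: int = 0) -> float:
    """SA objective: sum over clusters of (optionally scaled) L_k."""
    counts = allele_counts(gm, part)
    p = overall_freqs(counts)
    pk = cluster_freqs(counts, p)
    n = part.n_individuals
    sizes = part.cluster_sizes
    return sum(
        scaled_cluster_loglik(cluster_loglik(counts.counts[k], pk[k]), int(sizes[k]), n, s)
        for k in range(part.K)
    )


# -- numba kernels -------------------------------------------------------------


@njit(cache=True)
def _cluster_ll(counts, ckl, p, jl, k):
    tot = 0.0
    for l in range(counts.shape[1]):
        denom = 1.0 + ckl[k, l]
        for j in range(jl[l]):
            c = counts[k, l, j]
            if c > 0.0:
                tot += c * np.log((p[l, j] + c) / denom)
    return tot


@njit(cache=True)
def _shift(counts, ckl, geno, i, frm, to):
    for l in range(geno.shape[1]):
        a0 = geno[i, l, 0]
        if a0 >= 0:
            a1 = geno[i, l, 1]
            counts[frm, l, a0] -= 1.0
            counts[frm, l, a1] -= 1.0
            counts[to, l, a0] += 1.0
            counts[to, l, a1] += 1.0
            ckl[frm, l] -= 2.0
            ckl[to, l] += 2.0


@njit(cache=True)
def _scaled(lk, nk, n, s):
    if s == 0:
        return lk
    return lk / (1.0 + np.exp(s * nk / (8.0 * n)))


@njit(cache=True)
def _move_delta(counts, ckl, geno, p, jl, sizes, llk, n, s, i, a, b):
    """Objective change for moving individual i from cluster a to b.

    Leaves the state unchanged.  Returns (delta, new_ll_a, new_ll_b).
    """
    _shift(counts, ckl, geno, i, a, b)
    nla = _cluster_ll(counts, ckl, p, jl, a)
    nlb = _cluster_ll(counts, ckl, p, jl, b)
    _shift(counts, ckl, geno, i, b, a)
    delta = (
        _scaled(nla, sizes[a] - 1, n, s)
        + _scaled(nlb, sizes[b] + 1, n, s)
        - _scaled(llk[a], sizes[a], n, s)
        - _scaled(llk[b], sizes[b], n, s)
    )
    return delta, nla, nlb


@njit(cache=True)
def _sa_kernel(
    geno, jl, p, assign, counts, ckl, sizes, llk,
    s, t0, cool, sweeps, stall_stop, max_levels, seed,
):
    np.random.seed(seed)
    n = geno.shape[0]
    K = counts.shape[0]
    obj = 0.0
    for k in range(K):
        obj += _scaled(llk[k], sizes[k], n, s)
    best_obj = obj
    best_assign = assign.copy()
    T = t0
    stall = 0
    level = 0
    nprop = sweeps * n
    while stall < stall_stop and level < max_levels:
        any_acc = False
        for _ in range(nprop):
            i = np.random.randint(0, n)
            a = assign[i]
            if sizes[a] <= 1:
                continue  # move would empty the source cluster
            b = np.random.randint(0, K - 1)
            if b >= a:
                b += 1
            delta, nla, nlb = _move_delta(
                counts, ckl, geno, p, jl, sizes, llk, n, s, i, a, b
            )
            if delta > 0.0 or np.random.random() < np.exp(delta / T):
                _shift(counts, ckl, geno, i, a, b)
                assign[i] = b
                sizes[a] -= 1
                sizes[b] += 1
                llk[a] = nla
                llk[b] = nlb
                obj += delta
                any_acc = True
                if obj > best_obj:
                    best_obj = obj
                    best_assign[:] = assign
        if any_acc:
            stall = 0
        else:
            stall += 1
        T *= cool
        level += 1
    return best_assign, best_obj


# -- incremental state (python surface over the kernels) ------------------------


class SAState:
    """Cached counts/likelihood state supporting O(L) move evaluation.

    Moving one individual changes the counts of two clusters only; the
    whole-sample frequencies p_lj are move-invariant, so the objective delta
    needs just the two affected clusters' log-likelihoods.
    """

    def __init__(self, gm: GenotypeMatrix, part: ClusterPartition, scaling_level: int = 0):
        self.gm = gm
        self.K = part.K
        self.s = int(scaling_level)
        self.n = part.n_individuals
        self.assignment = part.assignment.copy()
        cc = allele_counts(gm, part)
        self.counts = cc.counts
        self.ckl = self.counts.sum(axis=2)
        self.p = overall_freqs(cc)
        self.jl = np.asarray(gm.alleles_per_locus, dtype=np.int64)
        self.sizes = part.cluster_sizes.astype(np.int64)
        self.llk = np.array(
            [_cluster_ll(self.counts, self.ckl, self.p, self.jl, k) for k in range(self.K)]
        )

    @property
    def objective(self) -> float:
        return sum(
            _scaled(self.llk[k], int(self.sizes[k]), self.n, self.s) for k in range(self.K)
        )

    def move_delta(self, i: int, to: int) -> float:
        frm = int(self.assignment[i])
        if frm == to:
            raise ValueError("destination equals source cluster")
        if self.sizes[frm] <= 1:
            raise ValueError("move would empty the source cluster")
        delta, _, _ = _move_delta(
            self.counts, self.ckl, self.gm.genotypes, self.p, self.jl,
            self.sizes, self.llk, self.n, self.s, i, frm, to,
        )
        return float(delta)

    def apply_move(self, i: int, to: int) -> float:
        frm = int(self.assignment[i])
        delta, nla, nlb = _move_delta(
            self.counts, self.ckl, self.gm.genotypes, self.p, self.jl,
            self.sizes, self.llk, self.n, self.s, i, frm, to,
        )
        _shift(self.counts, self.ckl, self.gm.genotypes, i, frm, to)
        self.assignment[i] = to
        self.sizes[frm] -= 1
        self.sizes[to] += 1
        self.llk[frm] = nla
        self.llk[to] = nlb
        return float(delta)

    def partition(self) -> ClusterPartition:
        return ClusterPartition(self.assignment.copy(), self.K)


# -- search ---------------------------------------------------------------------


@dataclass
class ClusteringResults:
    """Best partition found, with frequency estimates and objective values."""

    partition: ClusterPartition
    freqs: np.ndarray  # p_klj, (K, L, Jmax)
    overall: np.ndarray  # p_lj
    objective: float  # scaled objective actually maximised
    loglik: float  # unscaled partition log-likelihood of the same partition
    scaling_level: int
    n_restarts: int

    def summary(self) -> str:
        sizes = ", ".join(str(v) for v in self.partition.cluster_sizes)
        lines = [
            "Mixture-model clustering (simulated annealing)",
            f"  individuals: {self.partition.n_individuals}   clusters: {self.partition.K}",
            f"  cluster sizes: {sizes}",
            f"  scaling level s = {self.scaling_level}   restarts: {self.n_restarts}",
            f"  objective (scaled): {self.objective:.6f}",
            f"  log-likelihood (unscaled): {self.loglik:.6f}",
        ]
        return "\n".join(lines)


def _stratified_init(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Round-robin assignment of a random permutation: non-empty by design."""
    assign = np.empty(n, dtype=np.int64)
    assign[rng.permutation(n)] = np.arange(n) % K
    return assign


def _estimate_t0(state: SAState, rng: np.random.Generator, n_probe: int = 200) -> float:
    """T0 such that ~80% of uniform single moves would be accepted."""
    if state.K < 2:
        return 1.0
    downs = []
    for _ in range(n_probe):
        i = int(rng.integers(state.n))
        frm = int(state.assignment[i])
        if state.sizes[frm] <= 1:
            continue
        to = int(rng.integers(state.K - 1))
        if to >= frm:
            to += 1
        d = state.move_delta(i, to)
        if d < 0:
            downs.append(-d)
    if not downs:
        return 1.0
    return float(np.mean(downs) / (-np.log(0.8)))


def sa_search(gm: GenotypeMatrix, K: int, cfg: SAConfig | None = None) -> ClusteringResults:
    """Maximise the (scaled) partition log-likelihood over K-cluster partitions."""
    cfg = cfg or SAConfig()
    n = gm.n_individuals
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > n:
        raise ValueError(f"infeasible: K={K} clusters for N={n} individuals")

    if K == 1:
        part = ClusterPartition(np.zeros(n, dtype=np.int64), 1)
        return _results_for(gm, part, cfg, n_restarts=0)

    rng = np.random.default_rng(cfg.seed)
    kernel_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_restarts)
    best_assign = None
    best_obj = -np.inf
    geno = np.ascontiguousarray(gm.genotypes, dtype=np.int32)
    for r in range(cfg.n_restarts):
        init = _stratified_init(n, K, rng)
        state = SAState(gm, ClusterPartition(init, K), cfg.scaling_level)
        t0 = cfg.initial_temperature
        if t0 is None:
            t0 = _estimate_t0(state, rng)
        assign, obj = _sa_kernel(
            geno,
            state.jl,
            state.p,
            state.assignment,
            state.counts,
            state.ckl,
            state.sizes,
            state.llk,
            cfg.scaling_level,
            float(t0),
            cfg.cooling_factor,
            cfg.sweeps_per_temperature,
            cfg.stop_stall_temperatures,
            cfg.max_temperature_levels,
            int(kernel_seeds[r]) & 0x7FFFFFFF,
        )
        if obj > best_obj:  # ties between restarts broken first-found
            best_obj = obj
            best_assign = assign.copy()
    part = ClusterPartition(best_assign, K)
    return _results_for(gm, part, cfg, n_restarts=cfg.n_restarts)


def _results_for(
    gm: GenotypeMatrix, part: ClusterPartition, cfg: SAConfig, n_restarts: int
) -> ClusteringResults:
    counts = allele_counts(gm, part)
    p = overall_freqs(counts)
    pk = cluster_freqs(counts, p)
    unscaled = partition_loglik(gm, part, 0)
    scaled = partition_loglik(gm, part, cfg.scaling_level)
    return ClusteringResults(
        partition=part,
        freqs=pk,
        overall=p,
        objective=scaled,
        loglik=unscaled,
        scaling_level=cfg.scaling_level,
        n_restarts=n_restarts,
    )
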