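"""EM refinement of ancestry proportions under the admixture model.

Each individual i carries an ancestry vector q_i on the K-simplex; the
log-likelihood of ancestry matrix Q and cluster allele frequencies P is

    L(Q, P | X) = sum_i sum_l sum_{a=1,2} log( sum_k q_ik * p_{k,l,x_ila} )

over non-missing allele copies.  Three departures from a plain alternating
EM are used:

* Q is initialised from the hard mixture-model partition (softened off the
  boundary, which is absorbing under the multiplicative update) and P from
  the prior-blended cluster frequencies of that partition.
* Q is iterated to convergence under fixed P before P is updated; the outer
  alternation repeats until the log-likelihood stabilises.
* when updating q_i, the frequencies can exclude individual i's own
  genotypes (leave-one-out), removing self-influence; the exclusion is done
  by subtracting i's posterior allele-copy contributions from the cached
  M-step accumulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .genodata import GenotypeMatrix
from .mixture import (
    ClusterPartition,
    allele_counts,
    cluster_freqs,
    overall_freqs,
)

__all__ = [
    "EMConfig",
    "admixture_loglik",
    "admixture_measure",
    "em_q_step",
    "em_converge_q",
    "em_p_step",
    "fit_admixture",
]

_FLOOR = 1e-9


@dataclass(frozen=True)
class EMConfig:
    tol_loglik: float = 1e-4
    tol_q: float = 1e-5
    max_outer_iters: int = 500
    max_q_iters: int = 1000
    use_loo: bool = True
    freq_pseudocount: bool = True

    def __post_init__(self) -> None:
        if self.tol_loglik <= 0 or self.tol_q <= 0:
            raise ValueError("tolerances must be positive")


def _gather_p(p: np.ndarray, geno: np.ndarray) -> np.ndarray:
    """p_{k,l,x_ila} for every allele copy: shape (N, K, L, 2); 0 at missing."""
    gsafe = np.clip(geno, 0, None)
    lidx = np.arange(geno.shape[1])[None, :, None]
    if p.ndim == 3:  # shared P, (K, L, J)
        out = p[:, lidx, gsafe]  # (K, N, L, 2) via broadcasting
        out = np.moveaxis(out, 0, 1)
    else:  # per-individual P, (N, K, L, J)
        out = p[np.arange(geno.shape[0])[:, None, None, None],
                np.arange(p.shape[1])[None, :, None, None],
                lidx[None],
                gsafe[:, None]]
    return np.where((geno >= 0)[:, None], out, 0.0)


def admixture_loglik(q: np.ndarray, p: np.ndarray, gm: GenotypeMatrix) -> float:
    """Evaluate the admixture log-likelihood over non-missing copies."""
    pa = _gather_p(p, gm.genotypes)  # (N, K, L, 2)
    mix = np.einsum("nk,nkla->nla", q, pa)
    obs = gm.genotypes >= 0
    vals = mix[obs]
    if np.any(vals <= 0):
        raise FloatingPointError("zero mixture probability for an observed allele")
    return float(np.log(vals).sum())


def admixture_measure(q_i: np.ndarray) -> float | np.ndarray:
    """M_i = 1 - sum_k q_ik^2: chance two random alleles differ in origin."""
    q_i = np.asarray(q_i)
    return 1.0 - np.sum(q_i * q_i, axis=-1)


def _posteriors(q: np.ndarray, pa: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """g_ikla: posterior origin of each observed allele copy; 0 at missing."""
    num = q[:, :, None, None] * pa  # (N, K, L, 2)
    denom = num.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(denom > 0, num / denom, 0.0)
    return np.where(obs[:, None], g, 0.0)


def em_q_step(q: np.ndarray, p: np.ndarray, gm: GenotypeMatrix) -> np.ndarray:
    """One multiplicative ancestry update for all individuals.

    q'_ik = (1 / 2L_i) sum_{l,a} q_ik p_{k,l,x_ila} / sum_m q_im p_{m,l,x_ila}
    where L_i counts individual i's non-missing loci.
    """
    geno = gm.genotypes
    obs = geno >= 0
    n_copies = obs.sum(axis=(1, 2))  # 2 * L_i
    if np.any(n_copies == 0):
        raise ValueError("individual with all loci missing")
    pa = _gather_p(p, geno)
    g = _posteriors(q, pa, obs)
    return g.sum(axis=(2, 3)) / n_copies[:, None]


@njit(cache=True)
def _q_converge_kernel(pa, n_copies, q, tol, maxit):
    """Per-individual multiplicative updates to convergence.

    ``pa`` holds p_{k,l,x_ila} with zeros at missing copies; individuals are
    independent given P, so each row iterates with its own early exit.
    """
    n, K, L, _ = pa.shape
    newq = np.empty(K)
    for i in range(n):
        for _ in range(maxit):
            newq[:] = 0.0
            for l in range(L):
                for a in range(2):
                    s = 0.0
                    for k in range(K):
                        s += q[i, k] * pa[i, k, l, a]
                    if s > 0.0:
                        for k in range(K):
                            newq[k] += q[i, k] * pa[i, k, l, a] / s
            diff = 0.0
            for k in range(K):
                newq[k] /= n_copies[i]
                d = abs(newq[k] - q[i, k])
                if d > diff:
                    diff = d
                q[i, k] = newq[k]
            if diff < tol:
                break
    return q


def em_converge_q(
    q: np.ndarray,
    p: np.ndarray,
    gm: GenotypeMatrix,
    cfg: EMConfig | None = None,
) -> np.ndarray:
    """Iterate ancestry updates under fixed frequencies until stable.

    ``p`` may be a shared (K, L, J) array or a per-individual (N, K, L, J)
    array of leave-one-out frequencies.  All rows are updated from the same
    frequencies within a sweep, so the result is order-independent.
    """
    cfg = cfg or EMConfig()
    geno = gm.genotypes
    obs = geno >= 0
    n_copies = obs.sum(axis=(1, 2)).astype(np.float64)
    if np.any(n_copies == 0):
        raise ValueError("individual with all loci missing")
    pa = np.ascontiguousarray(_gather_p(p, geno))  # fixed while P is fixed
    q = np.asarray(q, dtype=np.float64).copy()
    return _q_converge_kernel(pa, n_copies, q, cfg.tol_q, cfg.max_q_iters)


def _accumulate(q: np.ndarray, p: np.ndarray, gm: GenotypeMatrix):
    """M-step accumulators and per-individual contributions.

    Returns (A, D, a_i, d_i): A_klj = sum_{i,a} 1[x_ila = j] g_ikla,
    D_kl = sum_j A_klj, and a_i/d_i the addend of each individual so that
    leave-one-out frequencies can be formed by subtraction.
    """
    geno = gm.genotypes
    obs = geno >= 0
    pa = _gather_p(p, geno)
    g = _posteriors(q, pa, obs)  # (N, K, L, 2)
    n, K, L, _ = g.shape
    jmax = p.shape[-1]
    a_i = np.empty((n, K, L, jmax))
    for j in range(jmax):  # few alleles: masked sums beat scatter-adds
        a_i[:, :, :, j] = (g * (geno == j)[:, None]).sum(axis=3)
    d_i = a_i.sum(axis=3)  # (N, K, L)
    return a_i.sum(axis=0), d_i.sum(axis=0), a_i, d_i


def em_p_step(
    q: np.ndarray,
    p: np.ndarray,
    gm: GenotypeMatrix,
    use_pseudocount: bool = True,
    exclude: int | None = None,
) -> np.ndarray:
    """Frequency update from posterior allele-origin fractions.

    p'_klj = (pi_lj + sum_{i != exclude, a} 1[x_ila = j] g_ikla)
             / (1 + sum_{i != exclude, a} g_ikla)
    with pi_lj the whole-sample frequency (unit total weight) when the
    pseudocount is on; with it off the prior weight is dropped and zero
    entries are floored at 1e-9 before renormalising.
    """
    A, D, a_i, d_i = _accumulate(q, p, gm)
    if exclude is not None:
        A = A - a_i[exclude]
        D = D - d_i[exclude]
    return _freqs_from_accumulators(A, D, gm, use_pseudocount)


def _overall_pi(gm: GenotypeMatrix, jmax: int) -> np.ndarray:
    part = ClusterPartition(np.zeros(gm.n_individuals, dtype=np.int64), 1)
    pi = overall_freqs(allele_counts(gm, part))
    if pi.shape[1] < jmax:
        pi = np.pad(pi, ((0, 0), (0, jmax - pi.shape[1])))
    return pi


def _freqs_from_accumulators(
    A: np.ndarray, D: np.ndarray, gm: GenotypeMatrix, use_pseudocount: bool
) -> np.ndarray:
    jmax = A.shape[-1]
    jl = np.asarray(gm.alleles_per_locus)
    valid = np.arange(jmax)[None, :] < jl[:, None]  # (L, J)
    if use_pseudocount:
        pi = _overall_pi(gm, jmax)
        p_new = (pi[None] + A) / (1.0 + D[..., None])
    else:
        if np.any(D.sum(axis=1) == 0):
            raise ZeroDivisionError(
                "cluster with zero posterior mass and pseudocount disabled"
            )
        p_new = np.where(valid[None], np.maximum(A, _FLOOR), 0.0)
        p_new = p_new / p_new.sum(axis=-1, keepdims=True)
    return np.where(valid[None], p_new, 0.0)


def _soften_indicator(part: ClusterPartition, eps: float = 1e-3) -> np.ndarray:
    q = np.full((part.n_individuals, part.K), eps)
    q[np.arange(part.n_individuals), part.assignment] = 1.0 - (part.K - 1) * eps
    return q


def _loo_freqs(q: np.ndarray, p: np.ndarray, gm: GenotypeMatrix, use_pseudocount: bool):
    """Per-individual leave-one-out frequencies, (N, K, L, J)."""
    A, D, a_i, d_i = _accumulate(q, p, gm)
    A_loo = A[None] - a_i
    D_loo = D[None] - d_i
    jmax = A.shape[-1]
    jl = np.asarray(gm.alleles_per_locus)
    valid = np.arange(jmax)[None, :] < jl[:, None]
    if use_pseudocount:
        pi = _overall_pi(gm, jmax)
        p_loo = (pi[None, None] + A_loo) / (1.0 + D_loo[..., None])
    else:
        p_loo = np.where(valid[None, None], np.maximum(A_loo, _FLOOR), 0.0)
        p_loo = p_loo / p_loo.sum(axis=-1, keepdims=True)
    return np.where(valid[None, None], p_loo, 0.0)


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    init: ClusterPartition,
    cfg: EMConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Alternating EM from a hard-partition start.

    Returns (Q, P, loglik, trace) where trace holds the outer-iteration
    log-likelihood values.
    """
    cfg = cfg or EMConfig()
    if init.K != K or init.n_individuals != gm.n_individuals:
        raise ValueError("initial partition inconsistent with data or K")
    counts = allele_counts(gm, init)
    p = cluster_freqs(counts, overall_freqs(counts))
    q = _soften_indicator(init)
    trace: list[float] = []
    ll_prev = -np.inf
    for _ in range(cfg.max_outer_iters):
        q_prev = q
        if cfg.use_loo:
            p_loo = _loo_freqs(q, p, gm, cfg.freq_pseudocount)
            q = em_converge_q(q, p_loo, gm, cfg)
        else:
            q = em_converge_q(q, p, gm, cfg)
        p = em_p_step(q, p, gm, use_pseudocount=cfg.freq_pseudocount)
        ll = admixture_loglik(q, p, gm)
        trace.append(ll)
        # stop on likelihood stability or on joint (Q, P) stationarity: with
        # |LL| large the absolute tol can sit below the EM tail's step size
        # long after Q has stopped moving
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < cfg.tol_loglik:
            break
        if np.max(np.abs(q - q_prev)) < cfg.tol_q:
            break
        ll_prev = ll
    return q, p, trace[-1], trace
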