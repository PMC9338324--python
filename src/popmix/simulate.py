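"""Genotype simulation with known truth.

Island model: ancestral allele frequencies p_0l are drawn from a flat
Dirichlet; subpopulation frequencies p_kl are drawn from
Dirichlet(lambda_j = (1/F_ST - 1) p_0lj), so that E[p_klj] = p_0lj and
Var[p_klj] = F_ST p_0lj (1 - p_0lj).  Genotypes are formed by drawing, for
each of the two allele copies at each locus, a source population from the
individual's ancestry vector q_i and then an allele from that population's
frequencies (linkage equilibrium across loci).

Spatial model: K source populations and N sampled individuals are equally
spaced on a line; ancestry decays with squared distance,

    q_ik  propto  [1 - ((i-1)/(N-1) - (k-1)/(K-1))^2]^S,

with the scaler S solved from a target corner ancestry q_11.

Optional realism layers: full-sib families (Poisson family sizes, offspring
by Mendelian sampling from two unsampled simulated parents), partial
selfing (equilibrium inbreeding F = S_self / (2 - S_self): both copies of a
locus identical by descent with probability F), and F1/F2 hybrid classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .genodata import GenotypeMatrix

__all__ = [
    "SimulationSpec",
    "draw_ancestral_freqs",
    "draw_subpop_freqs",
    "spatial_admixture_q",
    "solve_spatial_scaler",
    "draw_genotypes",
    "simulate_sample",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for one synthetic dataset.

    ``admixture_mode``:
      * ``purebred`` — one-hot ancestry by subpopulation (needs sample_sizes)
      * ``dirichlet_q`` — q_i ~ symmetric Dirichlet(dirichlet_alpha)
      * ``spatial`` — line model driven by spatial_q11 (needs n_individuals)
      * ``hybrid_class`` — K=2 with sample_sizes = (P1, P2, F1, F2) counts
    """

    K: int
    fst: float
    n_loci: int
    alleles_per_locus: int = 2
    sample_sizes: tuple[int, ...] | None = None
    admixture_mode: str = "purebred"
    dirichlet_alpha: float = 1.0
    spatial_q11: float | None = None
    n_individuals: int | None = None
    fullsib_mean: float = 0.0
    selfing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("F_ST must be in (0, 1)")
        if self.K < 1 or self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ValueError("K >= 1, L >= 1 and J >= 2 required")
        if not (0.0 <= self.selfing_rate <= 1.0):
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.fullsib_mean < 0:
            raise ValueError("fullsib_mean must be non-negative")
        if self.admixture_mode == "spatial":
            if self.sample_sizes is not None:
                raise ValueError("spatial mode takes n_individuals, not sample_sizes")
            if self.n_individuals is None or self.spatial_q11 is None:
                raise ValueError("spatial mode needs n_individuals and spatial_q11")
        elif self.admixture_mode == "hybrid_class":
            if self.K != 2 or self.sample_sizes is None or len(self.sample_sizes) != 4:
                raise ValueError(
                    "hybrid_class mode needs K=2 and sample_sizes=(P1, P2, F1, F2)"
                )
        elif self.admixture_mode in ("purebred", "dirichlet_q"):
            if self.admixture_mode == "purebred":
                if self.sample_sizes is None or len(self.sample_sizes) != self.K:
                    raise ValueError("purebred mode needs one sample size per population")
            elif self.n_individuals is None and self.sample_sizes is None:
                raise ValueError("dirichlet_q mode needs n_individuals or sample_sizes")
        else:
            raise ValueError(f"unknown admixture_mode {self.admixture_mode!r}")
        if self.sample_sizes is not None:
            ss = np.asarray(self.sample_sizes)
            if np.any(ss < 0) or ss.sum() <= 0:
                raise ValueError("sample sizes must be non-negative with a positive total")


def _dirichlet(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise Dirichlet draws via gamma variates (vectorised over leading axes)."""
    g = rng.gamma(np.maximum(alpha, 1e-300))
    tot = g.sum(axis=-1, keepdims=True)
    # guard against underflow for very small concentration parameters
    bad = tot[..., 0] <= 0
    if np.any(bad):
        g[bad] = alpha[bad] if alpha.ndim == g.ndim else alpha
        tot = g.sum(axis=-1, keepdims=True)
    return g / tot


def draw_ancestral_freqs(
    n_loci: int, n_alleles: int, rng: np.random.Generator
) -> np.ndarray:
    """Flat-Dirichlet ancestral frequencies, shape (L, J)."""
    if n_alleles < 2:
        raise ValueError("need at least two alleles per locus")
    return _dirichlet(np.ones((n_loci, n_alleles)), rng)


def draw_subpop_freqs(
    p0: np.ndarray, fst: float, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Correlated subpopulation frequencies, shape (K, L, J)."""
    if not (0.0 < fst < 1.0):
        raise ValueError("F_ST must be in (0, 1)")
    lam = (1.0 / fst - 1.0) * p0  # (L, J)
    return _dirichlet(np.broadcast_to(lam, (K,) + p0.shape).copy(), rng)


# -- spatial admixture ----------------------------------------------------------


def _spatial_bases(K: int, N: int) -> np.ndarray:
    pos_i = np.arange(N) / (N - 1)
    pos_k = np.arange(K) / (K - 1)
    return np.clip(1.0 - (pos_i[:, None] - pos_k[None, :]) ** 2, 0.0, None)


def spatial_admixture_q(K: int, N: int, scaler: float) -> np.ndarray:
    """Ancestry of N equally spaced individuals between K equally spaced sources."""
    if N < 2 or K < 2:
        raise ValueError("spatial model needs N >= 2 and K >= 2")
    if scaler < 0:
        raise ValueError("scaler must be non-negative")
    base = _spatial_bases(K, N)
    if math.isinf(scaler):
        q = (base == base.max(axis=1, keepdims=True)).astype(float)
    else:
        q = base**scaler  # 0**0 == 1: scaler 0 gives uniform rows
    return q / q.sum(axis=1, keepdims=True)


def solve_spatial_scaler(q11_target: float, K: int, N: int) -> float:
    """Solve for S such that the corner ancestry q_11 hits the target.

    q_11 is monotone increasing in S from 1/K (S=0) towards 1, so the root is
    bracketed by doubling and found by Brent's method.
    """
    if K < 2 or N < 2:
        raise ValueError("spatial model needs N >= 2 and K >= 2")
    if q11_target <= 1.0 / K or q11_target > 1.0:
        raise ValueError("target q_11 must lie in (1/K, 1]")
    if q11_target == 1.0:
        return math.inf
    base = _spatial_bases(K, N)[0]

    def f(s: float) -> float:
        return float(base[0] ** s / np.sum(base**s)) - q11_target

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for valid targets
            raise RuntimeError("failed to bracket the spatial scaler")
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


# -- genotype drawing -----------------------------------------------------------


def draw_genotypes(
    q: np.ndarray,
    p: np.ndarray,
    rng: np.random.Generator,
    inbreeding: float = 0.0,
) -> np.ndarray:
    """Draw (N, L, 2) genotypes: origin ~ q_i, then allele ~ p_kl, per copy.

    With ``inbreeding`` F > 0, the two copies of a locus are identical by
    descent (a single origin/allele draw duplicated) with probability F.
    """
    q = np.atleast_2d(q)
    n, K = q.shape
    _, L, J = p.shape
    cum_q = np.cumsum(q, axis=1)
    u = rng.random((n, L, 2))
    origins = (u[..., None] > cum_q[:, None, None, :]).sum(axis=-1)
    origins = np.minimum(origins, K - 1)
    cum_p = np.cumsum(p, axis=2)  # (K, L, J)
    v = rng.random((n, L, 2))
    lidx = np.arange(L)[None, :, None]
    alleles = (v[..., None] > cum_p[origins, lidx]).sum(axis=-1)
    alleles = np.minimum(alleles, J - 1).astype(np.int32)
    if inbreeding > 0:
        ibd = rng.random((n, L)) < inbreeding
        alleles[:, :, 1] = np.where(ibd, alleles[:, :, 0], alleles[:, :, 1])
    return alleles


def _mendelian_offspring(
    par1: np.ndarray, par2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Each parent transmits one random allele per locus; (L, 2) output."""
    L = par1.shape[0]
    pick1 = rng.integers(0, 2, size=L)
    pick2 = rng.integers(0, 2, size=L)
    out = np.empty((L, 2), dtype=par1.dtype)
    out[:, 0] = par1[np.arange(L), pick1]
    out[:, 1] = par2[np.arange(L), pick2]
    return out


def _family_sizes(n_total: int, lam: float, rng: np.random.Generator) -> list[int]:
    """Poisson(lam) family sizes truncated >= 1; last family trimmed to fit."""
    sizes: list[int] = []
    left = n_total
    while left > 0:
        size = 0
        while size < 1:
            size = int(rng.poisson(lam))
        size = min(size, left)
        sizes.append(size)
        left -= size
    return sizes


def simulate_sample(
    spec: SimulationSpec,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Generate one dataset: (genotypes, true Q, true subpopulation P)."""
    rng = np.random.default_rng(spec.seed)
    L, J, K = spec.n_loci, spec.alleles_per_locus, spec.K
    p0 = draw_ancestral_freqs(L, J, rng)
    p = draw_subpop_freqs(p0, spec.fst, K, rng)
    F = spec.selfing_rate / (2.0 - spec.selfing_rate) if spec.selfing_rate > 0 else 0.0

    mode = spec.admixture_mode
    if mode == "purebred":
        sizes = np.asarray(spec.sample_sizes)
        labels = np.repeat(np.arange(K), sizes)
        q_true = np.zeros((labels.size, K))
        q_true[np.arange(labels.size), labels] = 1.0
        if spec.fullsib_mean > 0:
            geno = _simulate_families(labels, p, spec.fullsib_mean, F, rng)
        else:
            geno = draw_genotypes(q_true, p, rng, inbreeding=F)
    elif mode == "dirichlet_q":
        n = spec.n_individuals or int(np.sum(spec.sample_sizes))
        q_true = _dirichlet(np.full((n, K), spec.dirichlet_alpha), rng)
        geno = draw_genotypes(q_true, p, rng, inbreeding=F)
    elif mode == "spatial":
        s = solve_spatial_scaler(spec.spatial_q11, K, spec.n_individuals)
        q_true = spatial_admixture_q(K, spec.n_individuals, s)
        geno = draw_genotypes(q_true, p, rng, inbreeding=F)
    else:  # hybrid_class
        geno, q_true = _simulate_hybrids(spec.sample_sizes, p, F, rng)

    n = geno.shape[0]
    ids = [f"ind{i + 1}" for i in range(n)]
    locus_ids = [f"locus{l + 1}" for l in range(L)]
    gm = _to_genotype_matrix(geno, J, ids, locus_ids)
    return gm, q_true, p


def _to_genotype_matrix(
    geno: np.ndarray, n_alleles: int, ids: list[str], locus_ids: list[str]
) -> GenotypeMatrix:
    """Recode simulated alleles, dropping simulated-but-unobserved alleles."""
    missing = np.zeros_like(geno, dtype=bool)
    return GenotypeMatrix.from_raw(geno, missing, ids, locus_ids)


def _simulate_families(
    labels: np.ndarray,
    p: np.ndarray,
    lam: float,
    inbreeding: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Full-sib structure within each subpopulation; parents are not sampled."""
    K, L, _ = p.shape
    one_hot = np.eye(K)
    rows = []
    for k in range(K):
        n_k = int(np.sum(labels == k))
        if n_k == 0:
            continue
        for fam in _family_sizes(n_k, lam, rng):
            parents = draw_genotypes(
                np.tile(one_hot[k], (2, 1)), p, rng, inbreeding=inbreeding
            )
            for _ in range(fam):
                rows.append(_mendelian_offspring(parents[0], parents[1], rng))
    return np.stack(rows)


def _simulate_hybrids(
    sizes: tuple[int, ...],
    p: np.ndarray,
    inbreeding: float,
    rng: np.random.Generator,
):
    """P1, P2 purebreds plus F1 (one copy per parental pool) and F2 hybrids."""
    n_p1, n_p2, n_f1, n_f2 = sizes
    L = p.shape[1]
    rows = []
    q_rows = []

    def f1_genotype() -> np.ndarray:
        copies = draw_genotypes(np.eye(2), p, rng)  # one draw per parental pool
        out = np.empty((L, 2), dtype=np.int32)
        out[:, 0] = copies[0, :, 0]
        out[:, 1] = copies[1, :, 0]
        return out

    for k, n_k in ((0, n_p1), (1, n_p2)):
        if n_k:
            onehot = np.zeros(2)
            onehot[k] = 1.0
            g = draw_genotypes(np.tile(onehot, (n_k, 1)), p, rng, inbreeding=inbreeding)
            rows.extend(g)
            q_rows.extend([onehot] * n_k)
    for _ in range(n_f1):
        rows.append(f1_genotype())
        q_rows.append(np.array([0.5, 0.5]))
    for _ in range(n_f2):
        rows.append(_mendelian_offspring(f1_genotype(), f1_genotype(), rng))
        q_rows.append(np.array([0.5, 0.5]))
    return np.stack(rows), np.stack(q_rows)
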