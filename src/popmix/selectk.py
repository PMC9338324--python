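"""Choosing the number of populations K.

Two complementary estimators computed from a scan of clustering analyses
over a K range:

* ``D_LK2`` — the absolute second difference of the best clustering
  log-likelihood across consecutive K values,
  ``|L(K-1) - 2 L(K) + L(K+1)|``; the true K tends to sit at the elbow of
  the likelihood curve, where the curvature peaks.  (The concrete formula
  is this package's choice; only the curvature idea is prescribed.)
* ``F_STIS`` — Wright's F-statistics on the hard partition at each K.  The
  best K should maximise among-cluster differentiation (F_ST) while keeping
  within-cluster Hardy-Weinberg deviation (F_IS) low: merging distinct
  populations inflates F_IS (Wahlund effect), over-splitting stops adding
  F_ST.  The combined score used here is ``F_ST - |F_IS|`` (again this
  package's concrete rule; both raw curves are always reported).

F-statistics are multilocus Weir-Cockerham (1984) estimates, with per-locus
variance components combined as a ratio of averages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix
from .mixture import ClusterPartition, SAConfig, sa_search

__all__ = ["KScanResult", "f_statistics", "dlk2", "fstis", "k_scan"]


def _wc_components(gm: GenotypeMatrix, part: ClusterPartition):
    """Per-locus-allele Weir-Cockerham variance components (a, b, c).

    a: among-subpopulation; b: among individuals within subpopulations;
    c: within individuals.  Loci represented in fewer than two clusters are
    skipped.
    """
    geno = gm.genotypes
    n, L, _ = geno.shape
    K = part.K
    jmax = int(gm.alleles_per_locus.max())
    obs_ind = geno[:, :, 0] >= 0  # (N, L): whole genotype observed or not

    # per cluster-locus: sample sizes, allele freqs, heterozygote proportions
    n_il = np.zeros((K, L))
    np.add.at(n_il, (part.assignment[:, None], np.arange(L)[None, :]), obs_ind * 1.0)

    counts = np.zeros((K, L, jmax))
    kidx = np.broadcast_to(part.assignment[:, None, None], geno.shape)
    lidx = np.broadcast_to(np.arange(L)[None, :, None], geno.shape)
    sel = geno >= 0
    np.add.at(counts, (kidx[sel], lidx[sel], geno[sel]), 1.0)

    het = np.zeros((K, L, jmax))  # individuals heterozygous for allele j
    is_het = (geno[:, :, 0] != geno[:, :, 1]) & obs_ind
    for a in (0, 1):
        np.add.at(
            het,
            (part.assignment[:, None], np.arange(L)[None, :], np.clip(geno[:, :, a], 0, None)),
            (is_het * 1.0),
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = counts / (2.0 * n_il[:, :, None])
        h_i = het / n_il[:, :, None]

    present = n_il > 0  # (K, L)
    r = present.sum(axis=0)  # populations represented per locus
    usable = r >= 2
    a_list, b_list, c_list = [], [], []
    for l in np.flatnonzero(usable):
        ks = np.flatnonzero(present[:, l])
        ni = n_il[ks, l]
        r_l = ks.size
        nbar = ni.mean()
        if nbar <= 1:
            continue
        nc = (r_l * nbar - np.sum(ni**2) / (r_l * nbar)) / (r_l - 1)
        if nc <= 0:
            continue
        for j in range(int(gm.alleles_per_locus[l])):
            p = p_i[ks, l, j]
            h = h_i[ks, l, j]
            pbar = np.sum(ni * p) / (r_l * nbar)
            s2 = np.sum(ni * (p - pbar) ** 2) / ((r_l - 1) * nbar)
            hbar = np.sum(ni * h) / (r_l * nbar)
            a_ = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r_l - 1) / r_l * s2 - hbar / 4.0) / (nbar - 1)
            )
            b_ = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r_l - 1) / r_l * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_ = hbar / 2.0
            a_list.append(a_)
            b_list.append(b_)
            c_list.append(c_)
    return np.array(a_list), np.array(b_list), np.array(c_list)


def f_statistics(gm: GenotypeMatrix, part: ClusterPartition) -> tuple[float, float]:
    """Multilocus Weir-Cockerham (theta, f) = (F_ST, F_IS) over the partition."""
    if part.K < 2:
        raise ValueError("F_ST is undefined for a single cluster")
    a, b, c = _wc_components(gm, part)
    if a.size == 0:
        raise ValueError("no locus is represented in two or more clusters")
    tot = np.sum(a + b + c)
    fst = float(np.sum(a) / tot) if tot != 0 else float("nan")
    bc = np.sum(b + c)
    fis = float(1.0 - np.sum(c) / bc) if bc != 0 else float("nan")
    return fst, fis


def dlk2(k_values: np.ndarray, logliks: np.ndarray) -> tuple[np.ndarray, int]:
    """Curvature scores |L(K-1) - 2 L(K) + L(K+1)| and the best interior K."""
    k_values = np.asarray(k_values)
    logliks = np.asarray(logliks, dtype=float)
    if k_values.size < 3:
        raise ValueError("D_LK2 needs at least three consecutive K values")
    if np.any(np.diff(k_values) != 1):
        raise ValueError("K grid must be consecutive integers")
    scores = np.full(k_values.size, np.nan)
    scores[1:-1] = np.abs(logliks[:-2] - 2 * logliks[1:-1] + logliks[2:])
    best = int(k_values[1:-1][np.argmax(scores[1:-1])])  # argmax takes smaller K on ties
    return scores, best


def fstis(
    k_values: np.ndarray, fst: np.ndarray, fis: np.ndarray
) -> tuple[np.ndarray, int]:
    """F-statistics scores F_ST - |F_IS| and the arg-max K (ties toward small K)."""
    fst = np.asarray(fst, dtype=float)
    fis = np.asarray(fis, dtype=float)
    scores = fst - np.abs(fis)
    best = int(np.asarray(k_values)[np.nanargmax(scores)])
    return scores, best


@dataclass
class KScanResult:
    """Per-K clustering log-likelihoods, F-statistics and both K estimators."""

    k_values: np.ndarray
    logliks: np.ndarray
    fst: np.ndarray
    fis: np.ndarray
    dlk2: np.ndarray
    fstis: np.ndarray
    best_k_dlk2: int | None
    best_k_fstis: int | None
    partitions: list[ClusterPartition]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.k_values,
                "loglik": self.logliks,
                "F_ST": self.fst,
                "F_IS": self.fis,
                "D_LK2": self.dlk2,
                "F_STIS": self.fstis,
            }
        )

    def summary(self) -> str:
        lines = ["K selection scan", self.to_dataframe().to_string(index=False)]
        if self.best_k_dlk2 is not None:
            lines.append(f"best K (D_LK2, likelihood curvature): {self.best_k_dlk2}")
        if self.best_k_fstis is not None:
            lines.append(f"best K (F_STIS = F_ST - |F_IS|):      {self.best_k_fstis}")
        return "\n".join(lines)


def k_scan(
    gm: GenotypeMatrix,
    k_min: int,
    k_max: int,
    replicates: int = 2,
    cfg: SAConfig | None = None,
) -> KScanResult:
    """Run replicate clustering searches per K and assemble both estimators.

    Each replicate is an independent single-restart annealing run; the best
    objective per K is kept.  ``cfg.seed`` seeds the whole scan.
    """
    cfg = cfg or SAConfig()
    if k_min < 1 or k_max > gm.n_individuals or k_min > k_max:
        raise ValueError("invalid K range")
    ks = np.arange(k_min, k_max + 1)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(ks.size * replicates)
    logliks = np.empty(ks.size)
    fst = np.full(ks.size, np.nan)
    fis = np.full(ks.size, np.nan)
    partitions: list[ClusterPartition] = []
    for idx, K in enumerate(ks):
        best = None
        for rep in range(replicates):
            seed = int(seeds[idx * replicates + rep]) & 0x7FFFFFFF
            res = sa_search(gm, int(K), replace(cfg, n_restarts=1, seed=seed))
            if best is None or res.objective > best.objective:
                best = res
        logliks[idx] = best.loglik
        partitions.append(best.partition)
        if K >= 2:
            fst[idx], fis[idx] = f_statistics(gm, best.partition)

    if ks.size >= 3:
        d_scores, best_d = dlk2(ks, logliks)
    else:
        d_scores, best_d = np.full(ks.size, np.nan), None
    mask = ks >= 2
    if mask.sum() >= 1:
        f_scores_sub, best_f = fstis(ks[mask], fst[mask], fis[mask])
        f_scores = np.full(ks.size, np.nan)
        f_scores[mask] = f_scores_sub
    else:
        f_scores, best_f = np.full(ks.size, np.nan), None
    return KScanResult(ks, logliks, fst, fis, d_scores, f_scores, best_d, best_f, partitions)
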