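"""Genotype data model and I/O.

Diploid multilocus genotypes are held as an ``N x L x 2`` integer tensor of
dense allele indices (``-1`` marks a missing allele copy).  Raw allele labels
(microsatellite sizes, VCF allele indices, ...) are recoded per locus to
``0 .. J_l - 1`` in ascending order of the raw label, and the recode map is
retained so files can be round-tripped.  Half-missing genotypes (one copy
observed, one missing) are rejected: the likelihoods treat the two allele
copies of a genotype independently, and an unambiguous convention for a
single observed copy is not defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "GenotypeFormatError",
    "DegenerateLocusError",
    "read_structure_genotypes",
    "write_structure_genotypes",
    "read_vcf_genotypes",
    "write_q_matrix",
    "write_p_tables",
    "dimension_count",
    "drop_monomorphic",
]


class GenotypeFormatError(ValueError):
    """Malformed genotype input (ragged rows, bad ploidy, half-missing calls...)."""


class DegenerateLocusError(ValueError):
    """A locus with no observed allele copies at all."""


@dataclass
class GenotypeMatrix:
    """Recoded diploid genotypes for N individuals at L loci.

    Attributes
    ----------
    genotypes : ndarray of shape (N, L, 2), dtype int32
        Dense allele indices in ``[0, J_l - 1]``; ``-1`` where missing.
    alleles_per_locus : ndarray of shape (L,)
        Number of distinct observed alleles ``J_l`` per locus.
    individual_ids, locus_ids : lists of str
    allele_labels : list of ndarray
        Per locus, the raw allele labels in ascending order; position ``j``
        is the raw label of dense index ``j``.
    """

    genotypes: np.ndarray
    alleles_per_locus: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    allele_labels: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int32)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (N, L, 2)")
        self.alleles_per_locus = np.asarray(self.alleles_per_locus, dtype=np.int64)
        self.validate()

    # -- dimension accounting -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def total_alleles(self) -> int:
        """A = sum_l J_l."""
        return int(self.alleles_per_locus.sum())

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes < 0

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean flag per locus: only one allele observed in the sample."""
        return self.alleles_per_locus == 1

    def validate(self) -> None:
        g = self.genotypes
        if g.shape[1] != len(self.alleles_per_locus):
            raise ValueError("alleles_per_locus length does not match L")
        miss = g < 0
        if np.any(miss[:, :, 0] != miss[:, :, 1]):
            raise GenotypeFormatError("half-missing genotype (one allele copy observed)")
        if np.any((g >= self.alleles_per_locus[None, :, None]) & ~miss):
            raise ValueError("allele index out of range for its locus")
        if np.any(self.alleles_per_locus < 1):
            raise DegenerateLocusError("locus with zero observed alleles")

    @classmethod
    def from_raw(
        cls,
        raw: np.ndarray,
        missing: np.ndarray,
        individual_ids: list[str],
        locus_ids: list[str],
    ) -> "GenotypeMatrix":
        """Build from raw (unrecoded) allele labels.

        ``raw`` is (N, L, 2) integer labels, ``missing`` a boolean mask of the
        same shape.  Labels are recoded per locus to dense ascending indices.
        """
        raw = np.asarray(raw)
        n, L, _ = raw.shape
        if np.any(missing[:, :, 0] != missing[:, :, 1]):
            bad = np.argwhere(missing[:, :, 0] != missing[:, :, 1])[0]
            raise GenotypeFormatError(
                f"half-missing genotype for individual {individual_ids[bad[0]]} "
                f"at locus {locus_ids[bad[1]]}"
            )
        geno = np.full((n, L, 2), MISSING, dtype=np.int32)
        labels: list[np.ndarray] = []
        j_l = np.empty(L, dtype=np.int64)
        for l in range(L):
            obs = raw[:, l, :][~missing[:, l, :]]
            if obs.size == 0:
                raise DegenerateLocusError(
                    f"locus {locus_ids[l]} has zero observed alleles"
                )
            labs = np.unique(obs)  # ascending
            labels.append(labs)
            j_l[l] = labs.size
            idx = np.searchsorted(labs, raw[:, l, :])
            geno[:, l, :] = np.where(missing[:, l, :], MISSING, idx)
        return cls(geno, j_l, list(individual_ids), list(locus_ids), labels)


def dimension_count(K: int, N: int, A: int, L: int) -> int:
    """Number of independent variables of the admixture problem.

    ``V = (K - 1) N + (A - L) K``: the ancestry matrix Q contributes
    ``(K - 1) N`` free parameters (rows on the simplex) and the allele
    frequencies P contribute ``(A - L) K``.
    """
    if K < 1 or N < 1 or L < 1:
        raise ValueError("K, N and L must be positive")
    if A < L:
        raise ValueError("total alleles A cannot be smaller than the number of loci L")
    return (K - 1) * N + (A - L) * K


# -- STRUCTURE text format -----------------------------------------------------


def _parse_rows(path: str) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if toks:
                rows.append((lineno, toks))
    return rows


def read_structure_genotypes(
    path: str,
    one_row_per_individual: bool = False,
    missing_code: int = -9,
) -> GenotypeMatrix:
    """Read whitespace-delimited genotypes in STRUCTURE's text convention.

    Two-row mode (default): each individual occupies two consecutive rows of
    ``ID`` + L allele columns.  One-row mode: one row of ``ID`` + 2L columns
    with the two copies of each locus adjacent.
    """
    rows = _parse_rows(path)
    if not rows:
        raise GenotypeFormatError(f"{path}: empty genotype file")
    width = len(rows[0][1])
    for lineno, toks in rows:
        if len(toks) != width:
            raise GenotypeFormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(toks)} columns, expected {width})"
            )
    ncols = width - 1
    if ncols < 1:
        raise GenotypeFormatError(f"{path}: no genotype columns")

    def _ints(toks: list[str], lineno: int) -> list[int]:
        try:
            return [int(t) for t in toks]
        except ValueError as exc:
            raise GenotypeFormatError(f"{path}: non-integer allele at line {lineno}") from exc

    if one_row_per_individual:
        if ncols % 2:
            raise GenotypeFormatError(f"{path}: odd number of allele columns in one-row mode")
        L = ncols // 2
        ids = [toks[0] for _, toks in rows]
        raw = np.empty((len(rows), L, 2), dtype=np.int64)
        for i, (lineno, toks) in enumerate(rows):
            vals = _ints(toks[1:], lineno)
            raw[i] = np.asarray(vals).reshape(L, 2)
    else:
        if len(rows) % 2:
            raise GenotypeFormatError(f"{path}: odd number of rows in two-row mode")
        L = ncols
        n = len(rows) // 2
        ids = [rows[2 * i][1][0] for i in range(n)]
        raw = np.empty((n, L, 2), dtype=np.int64)
        for i in range(n):
            for a in range(2):
                lineno, toks = rows[2 * i + a]
                raw[i, :, a] = _ints(toks[1:], lineno)
    missing = raw == missing_code
    locus_ids = [f"locus{l + 1}" for l in range(L)]
    return GenotypeMatrix.from_raw(raw, missing, ids, locus_ids)


def write_structure_genotypes(
    gm: GenotypeMatrix,
    path: str,
    one_row_per_individual: bool = False,
    missing_code: int = -9,
) -> None:
    """Write genotypes back out with the original raw allele labels."""
    n, L, _ = gm.genotypes.shape
    raw = np.full((n, L, 2), missing_code, dtype=np.int64)
    for l in range(L):
        labs = gm.allele_labels[l]
        obs = gm.genotypes[:, l, :] >= 0
        raw[:, l, :][obs] = labs[gm.genotypes[:, l, :][obs]]
    with open(path, "w") as fh:
        for i in range(n):
            if one_row_per_individual:
                vals = " ".join(str(v) for v in raw[i].reshape(-1))
                fh.write(f"{gm.individual_ids[i]} {vals}\n")
            else:
                for a in range(2):
                    vals = " ".join(str(v) for v in raw[i, :, a])
                    fh.write(f"{gm.individual_ids[i]} {vals}\n")


# -- VCF ------------------------------------------------------------------------


def read_vcf_genotypes(path: str) -> GenotypeMatrix:
    """Read diploid GT calls from a (possibly bgzipped) VCF.

    REF maps to raw label 0 and ALT alleles to 1, 2, ... in record order;
    dense recoding then keeps that order for the observed alleles.  The
    phasing separator is ignored; non-diploid calls raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = list(vcf.samples)
    raw_rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    for var in vcf:
        gts = var.genotypes
        if gts is None:
            raise GenotypeFormatError(f"{path}: record {var.CHROM}:{var.POS} has no GT field")
        row = np.empty((len(ids), 2), dtype=np.int64)
        for i, gt in enumerate(gts):
            if len(gt) != 3:  # [allele0, allele1, phased]
                raise GenotypeFormatError(
                    f"{path}: non-diploid genotype at {var.CHROM}:{var.POS} sample {ids[i]}"
                )
            row[i, 0], row[i, 1] = gt[0], gt[1]
        raw_rows.append(row)
        locus_ids.append(f"{var.CHROM}:{var.POS}")
    vcf.close()
    if not raw_rows:
        raise GenotypeFormatError(f"{path}: no variant records")
    raw = np.stack(raw_rows, axis=1)  # (N, L, 2)
    missing = raw < 0
    return GenotypeMatrix.from_raw(raw, missing, ids, locus_ids)


_VCF_ALLELES = ("A", "G", "T", "C")


def write_vcf_genotypes(gm: GenotypeMatrix, path: str) -> None:
    """Write genotypes as a minimal VCF (dense allele index i -> i-th symbol).

    Intended for diallelic/few-allele data; loci with more than four alleles
    cannot be represented and raise.
    """
    if int(gm.alleles_per_locus.max()) > len(_VCF_ALLELES):
        raise ValueError("VCF output supports at most four alleles per locus")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids) + "\n"
        )
        for l in range(gm.n_loci):
            j_l = int(gm.alleles_per_locus[l])
            alt = ",".join(_VCF_ALLELES[1:max(j_l, 2)])
            gts = "\t".join(
                "./." if gm.genotypes[i, l, 0] < 0
                else f"{gm.genotypes[i, l, 0]}/{gm.genotypes[i, l, 1]}"
                for i in range(gm.n_individuals)
            )
            fh.write(f"1\t{l + 1}\t{gm.locus_ids[l]}\tA\t{alt}\t.\t.\t.\tGT\t{gts}\n")


# -- derived outputs ------------------------------------------------------------


def drop_monomorphic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy without loci at which a single allele is observed."""
    keep = ~gm.monomorphic
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        gm.genotypes[:, idx, :].copy(),
        gm.alleles_per_locus[idx].copy(),
        list(gm.individual_ids),
        [gm.locus_ids[l] for l in idx],
        [gm.allele_labels[l] for l in idx],
    )


def write_q_matrix(path: str, individual_ids: list[str], q: np.ndarray) -> None:
    """One row per individual: ID then K ancestry proportions at 6 decimals."""
    q = np.asarray(q)
    with open(path, "w") as fh:
        for i, ind in enumerate(individual_ids):
            fh.write(ind + " " + " ".join(f"{v:.6f}" for v in q[i]) + "\n")


def write_p_tables(path: str, gm: GenotypeMatrix, p: np.ndarray) -> None:
    """Per-cluster allele frequency tables keyed by locus and allele index."""
    K = p.shape[0]
    with open(path, "w") as fh:
        fh.write("locus\tallele\traw_label\t" + "\t".join(f"cluster{k + 1}" for k in range(K)) + "\n")
        for l in range(gm.n_loci):
            for j in range(int(gm.alleles_per_locus[l])):
                raw = gm.allele_labels[l][j] if gm.allele_labels else j
                freqs = "\t".join(f"{p[k, l, j]:.6f}" for k in range(K))
                fh.write(f"{gm.locus_ids[l]}\t{j}\t{raw}\t{freqs}\n")
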