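"""Label-free scoring of ancestry estimates via pairwise coancestry.

The coancestry of individuals i and j is the co-assignment probability
``sum_k q_ik q_jk``: the chance that one allele drawn from each comes from
the same source population.  Because it is a quadratic form in Q, it is
invariant to permuting cluster labels, which removes the label-switching
problem when comparing a truth and an estimate (possibly with different K).

The average assignment error is the root mean square coancestry difference
over the N(N-1)/2 unordered pairs:

    AAE = sqrt( mean_{i<j} (C_true[i,j] - C_est[i,j])^2 ),

0 for a perfect estimate and at most 1 (attained when purebred individuals
are grouped exactly wrongly).
"""

from __future__ import annotations

import numpy as np

__all__ = ["coancestry", "aae"]


def coancestry(q: np.ndarray) -> np.ndarray:
    """Pairwise co-assignment probabilities, an N x N symmetric matrix.

    The diagonal entry for individual i equals ``1 - M_i`` where M_i is the
    admixture measure.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2:
        raise ValueError("Q must be a 2-D (N x K) matrix")
    return q @ q.T


def aae(q_true: np.ndarray, q_est: np.ndarray) -> float:
    """Average assignment error between a true and an estimated Q.

    The two matrices must share N but may have different K.
    """
    q_true = np.asarray(q_true, dtype=float)
    q_est = np.asarray(q_est, dtype=float)
    n = q_true.shape[0]
    if q_est.shape[0] != n:
        raise ValueError("Q matrices must describe the same individuals")
    if n < 2:
        raise ValueError("AAE is undefined for fewer than two individuals")
    diff = coancestry(q_true) - coancestry(q_est)
    iu = np.triu_indices(n, k=1)
    return float(np.sqrt(np.mean(diff[iu] ** 2)))
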