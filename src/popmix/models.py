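"""Model/Results front end.

``MixtureClustering`` and ``AdmixtureModel`` wrap the functional layer in
the fit-then-inspect style familiar from statistical modelling packages: a
model object is built from a :class:`~popmix.genodata.GenotypeMatrix`,
``fit`` runs the computation, and the returned results object carries the
estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .admixture import EMConfig, admixture_measure, fit_admixture
from .evaluate import coancestry
from .genodata import GenotypeMatrix, write_p_tables, write_q_matrix
from .mixture import ClusteringResults, ClusterPartition, SAConfig, sa_search

__all__ = ["MixtureClustering", "AdmixtureModel", "AdmixtureResults"]


class MixtureClustering:
    """Hard clustering of individuals under the mixture (no-admixture) model."""

    def __init__(self, data: GenotypeMatrix):
        self.data = data

    def fit(self, K: int, config: SAConfig | None = None) -> ClusteringResults:
        return sa_search(self.data, K, config)


@dataclass
class AdmixtureResults:
    """Estimates from the clustering + EM pipeline."""

    model: "AdmixtureModel"
    K: int
    q: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_trace: list[float]
    clustering: ClusteringResults | None
    em_config: EMConfig

    @property
    def admixture(self) -> np.ndarray:
        """Per-individual admixture extent M_i = 1 - sum_k q_ik^2."""
        return np.asarray(admixture_measure(self.q))

    def coancestry(self) -> np.ndarray:
        return coancestry(self.q)

    def summary(self, max_rows: int = 10) -> str:
        gm = self.model.data
        m = self.admixture
        lines = [
            "Admixture model fit (mixture clustering + EM refinement)",
            f"  individuals: {gm.n_individuals}   loci: {gm.n_loci}   K: {self.K}",
            f"  log-likelihood: {self.loglik:.6f}   outer iterations: {len(self.loglik_trace)}",
            f"  leave-one-out frequencies: {self.em_config.use_loo}"
            f"   frequency prior: {self.em_config.freq_pseudocount}",
            f"  mean admixture M: {m.mean():.4f}   max M: {m.max():.4f}",
            "",
            "  ancestry (first rows): id  " + "  ".join(f"q{k + 1}" for k in range(self.K)),
        ]
        for i in range(min(max_rows, gm.n_individuals)):
            row = "  ".join(f"{v:.4f}" for v in self.q[i])
            lines.append(f"    {gm.individual_ids[i]}  {row}")
        if gm.n_individuals > max_rows:
            lines.append(f"    ... ({gm.n_individuals - max_rows} more)")
        return "\n".join(lines)

    def save(self, prefix: str) -> None:
        write_q_matrix(f"{prefix}.Q", self.model.data.individual_ids, self.q)
        write_p_tables(f"{prefix}.P", self.model.data, self.p)


class AdmixtureModel:
    """Two-step admixture inference: anneal a hard partition, refine with EM."""

    def __init__(self, data: GenotypeMatrix):
        self.data = data

    def fit(
        self,
        K: int,
        init: ClusterPartition | None = None,
        sa_config: SAConfig | None = None,
        em_config: EMConfig | None = None,
        seed: int | None = None,
    ) -> AdmixtureResults:
        """Fit Q and P for a given K.

        ``init`` skips the clustering step; otherwise a simulated-annealing
        search provides the starting partition.  ``seed`` overrides the seed
        in ``sa_config`` for convenience.
        """
        em_config = em_config or EMConfig()
        clustering = None
        if init is None:
            sa_config = sa_config or SAConfig()
            if seed is not None:
                sa_config = replace(sa_config, seed=seed)
            clustering = sa_search(self.data, K, sa_config)
            init = clustering.partition
        q, p, ll, trace = fit_admixture(self.data, K, init, em_config)
        return AdmixtureResults(
            model=self,
            K=K,
            q=q,
            p=p,
            loglik=ll,
            loglik_trace=trace,
            clustering=clustering,
            em_config=em_config,
        )
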