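# popmix

Population structure and admixture inference from diploid multilocus
genotypes (SNPs or microsatellites), for population geneticists who want
STRUCTURE-style ancestry estimates with a deterministic, globally optimised
two-step procedure:

1. **Mixture-model clustering.** Individuals are partitioned into K
   non-empty clusters by maximising the partition log-likelihood
   `L(Ω) = Σ_k Σ_l Σ_j c_klj log p_klj` with simulated annealing, where the
   cluster allele frequencies blend the observed counts with the
   whole-sample frequency as a unit-weight prior,
   `p_klj = (p_lj + c_klj) / (1 + Σ_m c_klm)`.  For unbalanced sampling the
   per-cluster likelihood can be scaled by cluster size,
   `L_Sk = L_k / (1 + e^{sN_k/(8N)})` with s ∈ {1,2,3}, which suppresses the
   split-large/merge-small pathology.
2. **EM admixture refinement.** Starting from the hard partition, ancestry
   vectors `q_i` on the K-simplex and cluster frequencies P are refined
   under the admixture likelihood
   `L(Q,P|X) = Σ_i Σ_l Σ_a log Σ_k q_ik p_{k,l,x_ila}`, updating Q to
   convergence under fixed P and optionally using leave-one-out
   frequencies when updating each individual.

The package also provides two estimators of the number of populations
(`D_LK2`, the curvature of the clustering log-likelihood across K, and
`F_STIS`, based on multilocus Weir–Cockerham F-statistics), a genotype
simulator with known truth (island and spatial models, full-sib families,
selfing, F1/F2 hybrids, unbalanced sampling), and the label-free accuracy
metric AAE (root-mean-square difference of pairwise coancestries).
See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
import popmix as pm

# simulate three island populations (F_ST = 0.1, 1000 SNPs, 50 diploids each)
spec = pm.SimulationSpec(K=3, fst=0.1, n_loci=1000,
                         sample_sizes=(50, 50, 50), seed=42)
genotypes, q_true, p_true = pm.simulate_sample(spec)

# step 1: mixture clustering by simulated annealing
clust = pm.MixtureClustering(genotypes).fit(3, pm.SAConfig(seed=1, n_restarts=2))
print(clust.summary())

# step 2: EM admixture refinement from that partition
fit = pm.AdmixtureModel(genotypes).fit(
    3, init=clust.partition, em_config=pm.EMConfig(use_loo=False))
print(f"admixture log-likelihood: {fit.loglik:.1f}")
print(f"AAE against simulated truth: {pm.aae(q_true, fit.q):.4f}")
print("first individual q:", np.round(fit.q[0], 3))
```

prints

```
Mixture-model clustering (simulated annealing)
  individuals: 150   clusters: 3
  cluster sizes: 50, 50, 50
  scaling level s = 0   restarts: 2
  objective (scaled): -134592.361111
  log-likelihood (unscaled): -134592.361111
admixture log-likelihood: -134538.8
AAE against simulated truth: 0.0502
first individual q: [0. 1. 0.]
```

The clustering recovers the three simulated populations exactly (cluster
sizes 50/50/50; AAE of the hard partition is 0).  The EM step then
estimates each individual's ancestry proportions; with 1000 SNPs at
F_ST = 0.1 the maximum-likelihood estimates of truly purebred individuals
scatter a few percent into the interior of the simplex, which is ordinary
sampling noise at this marker information, giving an AAE of ≈ 0.05.

The same pipeline runs from the shell:

```
popmix simulate --spec spec.json --seed 42 --out data
popmix admix --in data.str --k 3 --seed 1 --out run      # writes run.Q, run.P
popmix selectk --in data.str --kmin 1 --kmax 6 --out ks  # D_LK2 / F_STIS scan
popmix evaluate --truth data.trueQ --est run.Q
```

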