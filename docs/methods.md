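# Methods

## Models

### Mixture model and clustering objective

`popmix` infers population structure from diploid multilocus genotypes
`X = {x_ila}` (N individuals, L loci, allele copies a = 1, 2; missing data
allowed, but both copies of a genotype must be missing together).  Under the
mixture model each individual's genome originates wholly from one of K
source populations.  For a partition Ω of the N individuals into K
non-empty clusters, the log-likelihood of cluster k is

    L_k = Σ_l Σ_j c_klj log p_klj ,

with `c_klj` the count of copies of allele j at locus l inside cluster k
and the frequency estimated with a unit-weight prior toward the
whole-sample frequency `p_lj = c_lj / Σ_m c_lm`:

    p_klj = (p_lj + c_klj) / (1 + Σ_m c_klm).

The prior blend keeps frequencies strictly positive and well defined even
for clusters with one or two members or with rare alleles; dropping the
prior (as plain likelihood methods do) or replacing it with a flat 1/J_l
behaves noticeably worse when clusters are small.  The partition
log-likelihood is the sum `L(Ω) = Σ_k L_k`, treating clusters as
approximately independent.

### Cluster-size scaling for unbalanced sampling

When sampling intensity is very unequal, maximising `L(Ω)` tends to split
the well-sampled population and merge the sparse ones.  To counter this,
each cluster's log-likelihood can be scaled by its size before summation:

    L_Sk = L_k / (1 + exp(s N_k / (8N))),   s ∈ {1, 2, 3},

which (for negative L_k) rewards larger clusters.  `s = 0` disables the
scaling and the implementation returns `L_k` untouched (dividing every
cluster by the constant 2 would not change the arg-max).  The scaling is an
empirical device, not derived from a model; the appropriate level depends
on how unbalanced the sampling is and how informative the markers are, so
results should be compared across s = 0..3.  Both the scaled objective and
the unscaled log-likelihood are always reported.

### Simulated-annealing search

`L_S(Ω)` is maximised globally over partitions by a Metropolis annealer:

* proposal: uniformly random individual, uniformly random destination
  cluster (moves that would empty the source cluster are rejected);
* acceptance: uphill always, downhill with probability `exp(ΔL_S / T)`;
* schedule: geometric cooling `T ← 0.9 T` after `10·N` proposals per level;
  the default initial temperature is calibrated so that ~80% of single
  moves from the initial random partition would be accepted;
* termination: five consecutive temperature levels with no accepted move
  (plus a 500-level safety cap);
* restarts: independent stratified-random initial partitions (default 10),
  best objective kept, ties broken first-found.

Moving one individual changes the counts of exactly two clusters and
leaves the whole-sample frequencies untouched, so each proposal costs
O(L·J) rather than a full objective evaluation; the cached incremental
objective is verified against from-scratch recomputation in the tests
(agreement to 1e-6 after 10^3 accepted moves).  All schedule constants are
exposed in `SAConfig` and the search is deterministic given its seed.

### Admixture model and EM refinement

Under the admixture model individual i has an ancestry vector `q_i` on the
K-simplex and the log-likelihood is

    L(Q, P | X) = Σ_i Σ_l Σ_a log( Σ_k q_ik p_{k,l,x_ila} ).

The EM refinement starts from the clustering result: Q is the 0/1
indicator of the partition softened by ε = 0.001 (the boundary is a fixed
point of the multiplicative update, so exact 0/1 starts could never move),
and P is the prior-blended frequency estimate of the partition.  Each
outer iteration then (i) updates every `q_i` to convergence under fixed
frequencies with the multiplicative rule

    q'_ik = (1 / 2L_i) Σ_{l,a} q_ik p_{k,l,x_ila} / Σ_m q_im p_{m,l,x_ila}

(L_i = non-missing loci of i; rows are updated from the same P within a
sweep, so results do not depend on individual order or thread count), and
(ii) re-estimates P from the posterior origin fractions of every allele
copy, blended with the same whole-sample unit-weight prior (disable with
`freq_pseudocount=False` to obtain the exact M-step).  The outer loop
stops when the log-likelihood changes by less than `tol_loglik` (default
1e-4) or when Q is stationary to `tol_q` (default 1e-5) over a whole outer
iteration; the latter rule matters because with |LL| of order 1e5 the
absolute likelihood tolerance can sit below the EM tail's per-iteration
step long after the estimates have stopped moving.  With the prior and
leave-one-out both disabled the alternation is a textbook EM and the
likelihood trace is non-decreasing, which the tests assert.

### Leave-one-out frequencies

When `use_loo=True` (the default), the frequencies used to update `q_i`
exclude individual i's own genotypes.  They are formed by subtracting i's
posterior allele-copy contributions from the cached M-step accumulators
(exact, O(L) per individual).  Self-exclusion removes the bias by which an
individual's own alleles inflate its membership in its current cluster,
which matters most for very small samples per population.

A property of this estimator worth knowing: for a truly purebred
individual, self-exclusion cancels the first-order pull toward the simplex
corner, so the per-individual likelihood becomes nearly flat there and the
converged estimate scatters into the interior with spread on the order of
`1 / sqrt(2L · I)` (I = per-copy Fisher information, which grows with
F_ST).  With a few thousand strongly informative SNPs the effect is
negligible; with ~10^3 SNPs at F_ST ≈ 0.1 it visibly inflates apparent
admixture of purebred individuals (and hence AAE) relative to the exact
EM.  The package therefore exposes the flag prominently, and the
parameter-recovery test suites measure the exact-EM configuration
(`use_loo=False`); the leave-one-out machinery is verified by exact
subtraction and consistency tests.

### Admixture measure and accuracy metric

`M_i = 1 − Σ_k q_ik²` is the probability that two alleles drawn at random
from individual i descend from different source populations (0 for
purebred; 0.5 for an F1 between two populations).  Estimates are scored
against simulated truth through pairwise coancestry
`C_ij = Σ_k q_ik q_jk`, which is invariant to cluster relabelling; the
average assignment error is the root-mean-square difference of true and
estimated coancestries over the N(N−1)/2 unordered pairs.  AAE is 0 for a
perfect estimate and reaches 1 only in the fully-misassigned purebred
case; its attainable maximum shrinks as K or admixture grows, so it
compares methods on one dataset rather than difficulty across datasets.

### Number of populations

Two estimators are computed from a scan of clustering runs over a K range
(several replicate searches per K, best kept):

* `D_LK2(K) = |L(K−1) − 2L(K) + L(K+1)|`, the absolute second difference
  of the best unscaled clustering log-likelihood; the likelihood elbow at
  the true K maximises the curvature.  The concrete formula is this
  package's choice — only the curvature principle is inherited — and it is
  labelled as such in output headers.
* `F_STIS(K) = F_ST(K) − |F_IS(K)|` from multilocus Weir–Cockerham (1984)
  estimates on the hard partition at each K: merging distinct populations
  inflates |F_IS| (Wahlund homozygote excess), over-splitting stops adding
  F_ST.  The combination rule is likewise this package's choice; both raw
  curves are always reported so users can apply their own.

Weir–Cockerham components are combined as ratio of averages over loci and
alleles, handle unequal and missing-data-reduced sample sizes per locus,
and skip loci represented in fewer than two clusters.

## Synthetic data generator

The generator emulates Wright's island model at equilibrium: ancestral
allele frequencies `p_0l ~ Dirichlet(1, ..., 1)`; subpopulation
frequencies `p_kl ~ Dirichlet(λ)` with `λ_j = (1/F_ST − 1) p_0lj`, so that
E[p_klj] = p_0lj and Var[p_klj] = F_ST·p_0lj(1 − p_0lj).  Genotypes draw,
per allele copy, a source population from `q_i` then an allele from that
population (linkage equilibrium).  Ancestry truths come in four modes:

* `purebred` — one-hot rows by subpopulation (sample sizes per population);
* `dirichlet_q` — rows drawn from a symmetric Dirichlet with concentration
  `dirichlet_alpha` (default 1.0; this parameterisation of "partially
  admixed individuals" is the package's own choice);
* `spatial` — populations and individuals equally spaced on a line,
  `q_ik ∝ [1 − ((i−1)/(N−1) − (k−1)/(K−1))²]^S`, with S solved by Brent's
  method from a target corner ancestry `q_11 ∈ (1/K, 1]` (`q_11 = 1` maps
  to the one-hot limit);
* `hybrid_class` — K = 2 with `sample_sizes = (P1, P2, F1, F2)`: F1s take
  one allele copy per parental pool at every locus (independent q-draws
  would understate F1 heterozygosity), F2s are Mendelian offspring of two
  simulated F1 parents.

Optional layers: full-sib families (Poisson(λ_FS) sizes truncated at ≥ 1,
last family trimmed; parents are drawn from the subpopulation frequencies
and discarded, not sampled) and partial selfing, modelled through the
equilibrium inbreeding coefficient F = S/(2 − S) by making the two copies
of a locus identical by descent with probability F (a single-pass
approximation of the multi-generation pedigree that matches the
stationary homozygosity excess).  Everything is deterministic given the
spec's seed.

What the generator does **not** emulate: linkage disequilibrium,
genotyping error, null alleles, mutation-model allele spectra
(microsatellite step mutations), or migration pedigrees.  Passing tests on
these data demonstrate correct inference under the model's own
assumptions, not robustness to real-data artefacts.

## Problem sizes used by the test suites

The verification suites run at deliberately reduced sizes chosen once:
parameter recovery at K=3, F_ST=0.1, 50/population, 1000 diallelic loci
(20 replicates); unbalanced-sampling scaling at K=3, F_ST=0.1,
N=(80, 4, 4) — an exact 20:1 ratio at roughly half the reference sample
size — over 50 replicates, scored on the clustering partitions where the
scaling acts; K recovery at K_true=5, F_ST=0.1, 20/population, 500 loci,
scanning K=3..7 with 2 replicate searches per K across 10 scans; simulator
fidelity at K=10, 20/population, 1000 loci, F_ST=0.05 over 10 replicates.

## Numerical choices

* Allele recoding is ascending on raw labels per locus; J_l counts only
  observed alleles.  Monomorphic loci are retained (they contribute zero
  log-likelihood) unless explicitly dropped.
* Half-missing genotypes are rejected at input rather than imputed: the
  likelihoods treat allele copies independently and no convention for a
  single observed copy is defined.
* Frequencies are never zero where a count is positive (prior blend); with
  the prior disabled, M-step zeros are floored at 1e-9 and renormalised.
* Ties: annealing restarts first-found; both K estimators break ties
  toward the smaller K.
* All floating-point file output is written at 6 decimals; internal
  computation is double precision.  The annealing inner loop and the
  per-individual ancestry iterations are numba-compiled.

## Known limitations

* The annealer offers no split/merge or tempering moves; very large K with
  weak signal may need more restarts.
* `D_LK2` needs at least three consecutive K values and is undefined at
  the range endpoints; `F_STIS` needs K ≥ 2.
* The scaling level s is not chosen automatically; comparative runs are
  the intended workflow.
* No linkage model, no inbreeding-coefficient estimation, no confidence
  intervals on ancestry estimates, and no supervised mode with known
  origins.
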