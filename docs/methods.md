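# Methods

`mgforest` implements module-guided Random Forests (mgRF): a regression
forest for high-dimensional, mixed-type genetic data (categorical markers +
continuous transcripts, n ≪ m) whose candidate-split sampling is guided by
the correlation structure of the predictors. The pipeline has four stages:
a mixed-type correlation network, modularity-based module detection,
iterated module-guided forest construction with importance re-weighting,
and a hypergeometric co-occurrence test of pairwise variable interactions.

## 1. Correlation network

Pairwise association `c_ij` is dispatched by variable type:

* continuous–continuous: Pearson correlation;
* categorical–categorical: normalized mutual information,
  `NMI = MI / sqrt(H_x · H_y)` with natural-log empirical entropies
  (0 when either entropy is 0);
* categorical–continuous: the continuous variable is discretized into three
  bins at `mu ± delta` (sample standard deviation, boundaries in the middle
  bin; a constant vector is all-mid), then NMI against the categorical one.

The `sqrt` normalization is symmetric and bounds NMI in [0, 1]; the
`mu ± delta` rule is the standard three-bin scheme for this construction.
Edges use absolute scores (negative co-expression is still dependence; the
network only groups and weights variables): an edge (i, j) exists iff
(1) `|c_ij| > t1 = 0.5` and one variable is within the other's top
`r1 = 5` partners, or (2) `|c_ij| > t2 = 0.8` and one is within the other's
top `r2 = 50`. Because association scales differ across data types,
rankings are computed separately within each (source_i, source_j) block
(marker–marker, transcript–transcript, marker–transcript). Rank lists use
strict ordering with ties broken by variable order, making the network
deterministic. Constant variables get association 0 everywhere and end up
isolated. `audit_edges` re-checks every emitted edge pair-by-pair,
independently of the vectorized construction path.

## 2. Module detection

Modules maximize Newman's weighted modularity
`Q = Σ_c [ w_in(c)/W − (s(c)/2W)² ]` (W total edge weight, `w_in`
intra-module weight, `s` module strength). The default `spectral` method
recursively bipartitions each connected component by the leading
eigenvector of the generalized modularity matrix, refines every split with
Kernighan–Lin-style single-node moves (each accepted move strictly
increases Q), and stops when no split increases Q — so the module count is
automatic. The linear algebra is seedless and deterministic; near-zero
eigenvector components (|v| < 1e−12) join the positive group. Groups
smaller than 2 are not split; isolated nodes become singleton modules. A
`greedy` CNM-style agglomeration (via networkx) is available as a fallback,
and the interface accepts any externally computed partition, so a different
modularity optimizer can be dropped in.

## 3. Module-guided forest

Trees are CART regression trees minimizing squared loss. Continuous splits
are thresholds at midpoints of consecutive sorted distinct values;
categorical splits are binary level-set partitions found by ordering levels
by node-local mean response, which is exact for squared loss and
O(L log L). Split ties are broken by (larger gain, smaller variable index,
smaller threshold), making training bit-reproducible under a fixed seed.
Each tree grows on a bootstrap of size n; out-of-bag (OOB) samples give the
internal error estimate. Defaults: `ntrees = 1000`, `nodesize = 3` (suited
to the small-n regime these datasets live in; nodes at or below `nodesize`
samples, or with zero response variance, become leaves).

**Two-stage candidate sampling.** At every node, candidates are drawn by
first sampling `k_mod` distinct modules, then exactly one representative
variable per module — so candidates always come from pairwise-distinct
modules, and tightly correlated variables never compete within one node.
The default `k_mod = max(1, ceil(#modules/3))` mirrors the conventional
`mtry = m/3` at the module level. Both stages use *modified weighted
sampling*: stage 1 draws N1 items without replacement with probability
proportional to the weights (implemented by exponential sort keys, which is
exactly successive weighted sampling without replacement); stage 2 keeps a
uniform subset. N1 is `ceil(N/3)` of the candidate pool (clipped to at
least N2); the variable stage uses N2 = 1.

**Iteration.** The first forest samples modules and variables uniformly.
After each forest, variable importance VI (summed SSE reduction per
variable across all trees, divided by `ntrees` — the regression analog of
Gini importance, chosen over permutation importance for its cost on m in
the thousands) and module importance MI (sum of member VIs) are
re-estimated, not accumulated, and become the sampling weights of the next
forest. Every weight gets `eps = 1e−6 · max(max weight, 1)` added so
zero-VI variables keep a nonzero selection probability. Iteration stops
when the L1 distance between successive sum-normalized VI vectors drops
below `vi_tol = 0.01` (i.e. less than 1% of total importance mass moved),
or after `max_iters = 10`.

**Corrected importance.** From the final forest only,
`cVI(v_i) = VI(v_i) + Σ_j c_ij · VI(v_j)` over j that are both network
neighbors of i and members of i's module, with `c_ij` the absolute edge
weight and self-weight 1, unnormalized. This undoes the dilution of
importance across correlated groups (the two-stage sampler admits one
member per node, so group evidence is spread across members) and makes hub
variables of important modules rank high. VI, MI and cVI are reported raw
and as percent of total.

With singleton modules, uniform weights and one iteration, the sampler
reduces exactly to uniform mtry-of-m sampling: `guided=False` exposes the
same engine as a conventional random forest, which is also the baseline in
the equivalence and stability checks.

## 4. Interaction test

Trees condition later splits on earlier ones, so interacting variables
co-occur in trees. For variables u, v present (split on at least once —
presence is per tree, not per node) in n and m of N trees, the overlap k
under independence is hypergeometric; the p-value is the right tail
P(K ≥ k), evaluated through scipy's log-space survival function and checked
against an exhaustive enumeration oracle in the tests. The test runs on a
dedicated ensemble (default N = 6000) grown at the converged weights, large
enough to stabilize the ranking. Pairs need `min_presence = 5` in both
margins; results are typed (SNP–SNP, gene–gene, SNP–gene), ranked by raw p,
and annotated with Benjamini–Hochberg q-values over the tested family.

## 5. Synthetic data

The generators emulate the structure of an F2 intercross resource and are
the test bed for every stage:

* **Genotypes**: two parental gametes per sample follow Markov chains along
  each chromosome with crossover probability r between adjacent markers
  (r ∈ [0, 0.5]); the genotype code is the allele dosage {0, 1, 2}, giving
  1:2:1 Mendelian ratios and LD that decays with r.
* **Expression**: each module has a latent factor, optionally loaded on an
  eQTL marker's standardized dosage; gene = `sqrt(rho)·factor +
  sqrt(1−rho)·noise`, so within-module Pearson correlation ≈ rho and
  between-module correlation ≈ 0.
* **Phenotype**: `y = Σ beta·x + Σ gamma·(x_i−mean)(x_j−mean) + N(0, σ²)`;
  interaction terms use centered products so they carry no marginal signal.
* **Desk-scale default** (`bxh_spec()`): 150 samples, 19 chromosomes × 10
  markers (r = 0.1), 60 modules × 10 genes (rho = 0.7), 15 eQTL-driven
  modules, a trait with two marker terms, three transcript terms, one
  marker×gene and one gene×gene interaction, σ = 1.9. This preserves the
  shape of the motivating application (markers ≪ genes, n ≪ m) at
  minutes-scale runtime.
* **Correlated-group benchmark** (`make_group_benchmark`): group G1
  (configurable size, pairwise ρ = 0.9, all signal-bearing), group G2
  (size 10), independent relevant singletons filling to 110 relevant
  variables, 1000 pure-noise variables, 200 samples; the response is
  additive over the group latent factors and singletons with noise scaled
  for an oracle R² ≈ 0.7.
* **Planted-partition graphs** feed the module-detection tests.

What the generators do *not* emulate: dominance, epistatic variance beyond
pairwise products, realistic recombination maps, heavy-tailed expression
noise, batch effects, or missing data. Passing checks therefore demonstrate
the algorithmic properties (bias correction, calibration, equivalence), not
performance on any particular real dataset.

## 6. Evaluation protocol

`run_benchmark` repeats k-fold cross-validation over several trials. All
data-type arms (genotype-only / expression-only / combined) and methods
share identical fold splits within a trial, so per-fold RMSEs are compared
with a one-tail paired t-test (zero-variance differences: p = 1 when the
mean difference is ≥ 0, a numeric floor otherwise). The network, modules
and all importance weights are rebuilt from the training fold only, so no
test information leaks into module detection or weighting.

## Problem sizes used in the automated checks

The property checks run at sizes chosen for clear effect separation at
minutes-scale cost: the forest-equivalence check uses 150×300 data with
4000 trees (large ensembles shrink the Monte Carlo error of the importance
ranking that the comparison measures); the bias-correction check runs 20
seeds of the group benchmark with 100-tree, 2-iteration fits on half
samples of 100; the data-integration check runs 10 trials of 5-fold CV at
200 trees and 2 iterations on a 24-module × 8-gene variant of the
desk-scale blueprint. The interaction-test calibration uses 4950
independent pairs at N = 1000 trees and marginal presence 0.3.

## Known limitations

* No statistical significance test of module validity is performed;
  modules are whatever maximizes Q.
* The spectral method densifies each connected component; components beyond
  ~10⁴ nodes would need a sparse eigensolver.
* cVI weights use absolute correlations; strongly negatively correlated
  neighbors contribute positively by design.
* Tree growth is single-threaded; ensembles are embarrassingly parallel but
  no parallel driver is included.
* Missing data are rejected, never imputed silently (`impute` is explicit).
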