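# Methods

`mfge` implements a hybrid filter–wrapper gene-selection system for labeled
expression matrices (genes × samples, a categorical class per sample). The
design targets the classic microarray regime: thousands of genes, a few
dozen samples, and the goal of a small, generalizable discriminative gene
set. This note records the model, the parameters that matter, the numerical
conventions, and what the synthetic benchmark does and does not show.

## Pipeline

1. **Preprocessing.** Each gene row is standardized to mean 0 / variance 1
   (population convention, divisor *n*) and then min–max rescaled into
   [0, 1]. Constant rows map to all-zeros (with a warning) and then to 0.5.
   Standardization statistics are computed over all samples before any
   split; this mildly leaks scale information but no label information.
2. **Nested cross-validation.** An external stratified 3-fold split
   reserves test samples untouched by every selection step; within each
   external training set an internal stratified 3-fold split drives the
   wrapper search. `CVPlan.validate` asserts the no-leakage invariants.
3. **Pre-filter.** Genes in each external training set are ranked by the
   between-group/within-group sum-of-squares ratio
   BSS_j/WSS_j = Σ_c N_c (x̄_cj − x̄_j)² / Σ_c Σ_{i∈c} (x_ij − x̄_cj)²,
   and the top 200 kept. WSS = 0 with BSS > 0 ranks first (+∞ sentinel);
   0/0 (constant gene) ranks last. Ties keep original gene order.
4. **Filter scoring.** Five filters score every candidate gene:
   χ² statistic, information gain, gain ratio, symmetrical uncertainty
   (all on a shared Fayyad–Irani MDL discretization of each gene), and
   ReliefF on the continuous [0, 1] values. ReliefF uses the single nearest
   hit/miss by Euclidean distance over all genes, probes every sample by
   default (making it deterministic), normalizes by the probe count (which
   bounds W in [−1, 1] for [0, 1] data), and weights multi-class miss terms
   by the opposing class priors — the two-class case reduces to the plain
   miss-minus-hit form.
5. **Score fusion.** Per filter, the score vector across genes is softmax
   scaled — standardize (population sd), then logistic — into (0, 1);
   per gene the scaled scores are summed, ×10, rounded half-up, floored at
   1. The integer score is the gene's multiplicity in the **gene frequency
   map**, the multiset from which GA initialization and mutation draw, so
   no candidate is ever excluded and filter-favoured genes are drawn in
   proportion to their fused score. The map is built once per external
   fold, from that fold's training samples only.
6. **Genetic-ensemble search.** A niched GA over 15-slot chromosomes (slot
   = gene code or 0 = empty; non-zero entries distinct). Fitness of a
   subset is the mean over internal folds of
   w₁·blocking + w₂·voting, where blocking is the mean balanced accuracy
   of the five classifiers (decision tree, random forest of 7 trees, 3-NN,
   7-NN, Gaussian naive Bayes) fit on the internal-train slice, and voting
   is the balanced accuracy of their per-sample majority vote (ties to the
   earliest classifier in bank order). Balanced accuracy is mean per-class
   sensitivity; a class absent from a fold contributes 0 so degenerate
   folds penalize rather than inflate.
7. **Ranking and evaluation.** Each GA iteration contributes its best
   subset; genes are ranked by selection frequency (count of contributing
   iterations), ties broken by fused integer score, then gene order. The
   top 5/10/15/20 genes are finally evaluated on the external test fold,
   reporting per-classifier balanced accuracy, their mean, and the
   majority-voting accuracy.

## Engine parameters

| parameter | default | notes |
|---|---|---|
| iterations | 100 | independent evolutions collected into the ranking |
| population | 100 in 2 niches of 50 | niches evolve separately |
| migration | best 1 per niche, every 10 generations | ring exchange |
| chromosome size | 15 slots | subsets of size 0–15 |
| selection | tournament, size 3 | ties: smaller subset, then earlier index |
| crossover | single point, p = 0.7 | duplicate genes repaired by zeroing the later slot |
| mutation | chained multi-point, 0.1 then 0.25 | E[M] = 0.1/0.75 ≈ 0.133 per chromosome; a point writes 0 with the init empty rate, else a map draw |
| fill probability | 0.4 | expected initial subset size 6, midpoint of the 2–10 operating band |
| termination | generation 100 or population similarity ≥ 0.9 | see below |
| weights w₁, w₂ | 0.5, 0.5 | blocking / voting contribution |

**Similarity termination.** Similarity is the mean pairwise Jaccard index
of decoded subsets over the *pooled* population (both niches together;
empty-vs-empty counts as 1). Pooling is deliberate: each niche converges
internally within a handful of generations, and population-level
convergence additionally requires migration to spread one consensus subset
across niches. With pooling, termination generations on synthetic data land
in the low-to-mid 20s, the regime this class of niched engines typically
reports; per-niche checking would terminate around generation 6–10 and
truncate the dynamics the method is built around.

**Replacement** is generational with elitism 1 per niche, which makes
best-fitness monotonicity a testable invariant. Mutation can write the
empty marker, so subset size evolves in both directions. One master seed
fans out through `numpy` `SeedSequence` streams to folds → iterations →
operators; every stage is replayable in isolation and byte-identical under
the same seed.

## Synthetic benchmark

`SyntheticSpec` plants `n_informative` genes (default 10) among `n_genes`
(default 200, matching a post-prefilter candidate set) over iid standard
Gaussian noise; each informative gene shifts exactly one class (assigned
round-robin) by `effect_size` noise-sd units (default 1.5). Defaults use
25 + 25 samples; a 24/20/28 three-class layout mirrors a public
leukemia-subtype composition. Options: Student-t noise (heavy tails) and
equicorrelated informative genes (redundancy). The generator does **not**
model batch effects, probe saturation, heteroscedastic noise, or gene–gene
pathway structure, so passing tests demonstrate correctness of the
machinery and sane statistical behaviour, not performance on real arrays.

## What the checks compute, at what size

Test and script problem sizes are scaled-down study conditions chosen once
for a single-CPU desk run; thresholds are not adjusted to fit.

- *Oracle checks*: the four table filters against double-loop references on
  1000 random contingency tables (1e-9); ReliefF against an exhaustive
  all-pairs oracle on 10-sample × 30-gene fixtures (exact).
- *Sampling laws*: pool size conservation, ≥1 multiplicity, 10⁵ draws
  vs the multinomial (χ² GOF, α = 0.01); 10⁵ chained-mutation draws within
  3 SE of 0.1/0.75.
- *Null-model safety*: effect size 0, 60 genes, 15+15 samples, 6 seeds,
  reduced engine (2 iterations, population 20, ≤6 generations): external
  mean balanced accuracy must be indistinguishable from 1/2 (one-sample
  t, α = 0.01). This is the leakage canary: the wrapper maximizes internal
  fitness, so any external signal under the null means the CV firewall is
  broken.
- *Recovery*: default generator (10 planted at effect 1.5 among 200), one
  external fold, 10 iterations, population 20, ≤8 generations, 5 seeds:
  ≥8 of 10 planted genes in the top-20 ranking for ≥80% of seeds.
- *Map-vs-uniform comparison*: paired runs at full engine fidelity
  (population 100, ≤100 generations) on the default generator, sharing the
  fitness cache within a pair; mean termination generation and mean subset
  size per engine, one-tailed paired t reported. Run at this fidelity
  because the convergence advantage of the biased map is a population-level
  effect: with small populations or truncated generations the two engines
  are statistically indistinguishable.

## Known limitations

- The frequency map's bias is mild by construction (logistic squashing
  keeps per-filter scores in ≈[0.05, 0.95], so fused integer scores span
  roughly 15–40): the engine is nudged, not driven, toward filter-favoured
  genes. Consequently the convergence/subset-size advantage over the
  uniform-map baseline is a small effect with large per-run variance, and
  single-digit seed counts can show either direction; the subset-size
  margin is the noisier of the two criteria at desk scale.
- Discrete filters depend on the MDL discretizer; genes it leaves unsplit
  (B = 1) score 0 on all four, which under a pure null collapses those
  score columns to a constant (handled by the all-0.5 softmax convention).
- ReliefF's exhaustive neighbour search is O(n² g); fine for ≤ a few
  hundred samples, not for thousands.
- Balanced accuracy on ~11-sample internal test folds is coarse
  (increments of ~1/11 per class), so fitness plateaus and ties are
  common; tie-breaking (smaller subset, earlier index) is therefore part
  of the engine's observable behaviour, not a hidden detail.
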