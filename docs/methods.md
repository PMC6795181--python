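# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `coexcross`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Differential expression screen

Counts are modeled per gene as negative binomial with Var = μ + αμ²
(a single global dispersion shape, one α estimated per gene). Library
sizes are corrected by median-of-ratios size factors: only genes positive
in every sample contribute, and the factors carry the usual overall-scale
indeterminacy — multiplying one of *n* samples by *k* scales its factor by
k^((n−1)/n) and every other factor by k^(−1/n), so all normalized counts
rescale by a common k^(1/n) and fold changes are exactly invariant.

The test statistic is a Wald z on the difference of log group means of
normalized counts. The dispersion is method-of-moments: within each group,
α̂ = (v − m·mean(1/s<sub>j</sub>))/m² from the sample mean m and variance v
of normalized counts, pooled across the two groups by degrees of freedom
and floored at 10⁻⁸. The variance of a group mean follows the delta method,
Var(log(m + c)) ≈ (m·Σ1/s<sub>j</sub>/n² + α̂m²/n)/(m + c)², with
pseudo-count c = 0.5 shared with the reported log2 fold change so that
zero group means stay finite. p-values use the normal reference,
two-sided; BH adjustment runs across tested genes (all-zero genes are
reported NA and excluded from the family).

The DEG flag is |FC| > 1.2 AND raw p < 0.05, both strict; the raw p
drives the flag (the convention the thresholds are quoted in) and the
adjusted p is always reported alongside. With 12 vs 12 samples and an
estimated dispersion, the normal reference is mildly anti-conservative
(a t reference with ~22 df would reject |z| > 1.96 about 6% of the time);
the measured type-I error on simulated null genes stays in the 5–7% range,
which the acceptance checks bound explicitly.

## Co-expression modules

The module chain follows the weighted co-expression (WGCNA) recipe on
log2(normalized count + 1) expression, zero-variance genes dropped:

* **Adjacency**: unsigned, a<sub>ij</sub> = |pearson(x_i, x_j)|^β,
  diagonal 0 for connectivity. The soft-threshold powers default to 12 and
  8 for the two tissues. Unsigned + Pearson are the family defaults; the
  biweight midcorrelation and signed variants are out of scope.
* **Topological overlap**: TOM<sub>ij</sub> = (ℓ<sub>ij</sub> +
  a<sub>ij</sub>)/(min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>)
  with ℓ<sub>ij</sub> = Σ<sub>u≠i,j</sub> a<sub>iu</sub>a<sub>uj</sub>,
  computed as a single matrix product (the diagonal is zero, so the
  u ∈ {i, j} terms vanish), symmetrized, clipped to [0, 1], diagonal 1.
* **Clustering**: average-linkage agglomeration of 1 − TOM, then a
  **static cut** at height 0.99 with minModuleSize = 20. The dynamic
  hybrid cut of the reference R implementation has many undocumented
  internal parameters; the static cut is transparent, deterministic, and
  validated by planted-module recovery (adjusted Rand index ≥ 0.7 at
  factor loading 0.8 with 24 samples) rather than by output matching.
* **Merging**: the configured "minimum height = 0.15" is interpreted as a
  module-*merge* threshold on eigengene dissimilarity 1 − cor(ME_a, ME_b)
  — 0.15 is far below any plausible 1 − TOM cut height, so the merge
  reading is the coherent one. Pairs below the threshold merge greedily
  (closest first), eigengenes recomputed after each merge.
* **Eigengenes and kME**: the eigengene is the first right singular vector
  of the module's gene-standardized expression, unit norm, sign-flipped so
  its mean correlation with members is non-negative (exact zero resolves
  toward a positive first nonzero loading). kME is the Pearson correlation
  of a gene with its own module's eigengene; hubs are kME > 0.8, strict.
  Labels 1..M follow decreasing module size (ties: smallest original gene
  index); 0 is the unassigned/grey label.

Known behavior: with few samples, two independent planted factors can show
chance correlation ~0.4–0.5; raised to a modest power this leaks enough
topological overlap for the static cut occasionally to merge two planted
modules, or for a weakly covered module to fall below the size floor. The
planted-recovery tests quantify the net effect (ARI well above 0.7 at the
standing conditions).

## Enrichment machinery

All enrichment uses the hypergeometric upper tail P(X ≥ k) for k drawn of
n from a universe of N containing K list members, delegated to a log-gamma
survival function (k = 0 returns exactly 1). The universe for module
enrichment is the tissue's co-expression gene set — the genes eligible for
module membership — the minimal self-consistent choice; it is
configurable because published analyses rarely state theirs.

* Candidate modules: ≥ 1 DEG member AND size < 500, both strict.
* Dysfunctional: raw p < 0.05 against either risk list (BH values
  reported, not gating — the convention the flag is quoted in).
* Pivot regulators: per regulator × candidate module,
  k = |targets ∩ module|, K = |targets ∩ universe|; pivot iff k ≥ 2 AND
  p < 0.05. The "> 1 interactions" rule is read module-locally (≥ 2
  targets *inside the tested module*), the stricter reading consistent
  with a per-module pivot; `min_targets` makes it configurable. Pivot
  tests default to all module genes (a DEG-restricted variant is a
  caller-side filter on the universe).
* Generic ORA against GMT collections mirrors the same test with BH
  across the collection; sets without universe overlap are skipped.

## Crosstalk permutation test

For a module pair (one per tissue) the statistic is the number of
distinct PPI edges with one endpoint in each set (an edge inside the
intersection counts once). The null redraws both sets per iteration —
same sizes, uniform without replacement from the *full* score-filtered
network node set, overlap between draws allowed (modules from different
tissues may share genes; forbidding overlap would bias the null).
p = b/n_perm with b the count of draws reaching the observed statistic and
no pseudo-count — an empirical p of 5.00E−05 at 100,000 draws is then
exactly 5 exceedances; b = 0 is reported as "< 1/n_perm". Default
n_perm = 100,000; granularity is 1/n_perm and p is monotone in the
observed count under a fixed draw sequence.

Tissue-specific modules are candidate modules containing at least one
gene that is simultaneously a DEG and on the tissue-specific list (strict
reading); the loose reading — the module touches the list and separately
contains a DEG — is available via a flag. Each tested pair draws from its
own substream keyed symmetrically in the two roles, so exchanging the
tissues transposes the result table with identical p-values. Edge scores
are ignored once the score filter has been applied.

The single-gene tissue-specific criterion is deliberately faithful and
therefore noisy: with 12 vs 12 samples a designated module whose handful
of qualifying genes all miss the DEG screen drops out of the tested set.
The acceptance script reports both the pipeline-table rank of the planted
pair and a direct permutation test of the recovered pair so that this
selection noise is visible rather than hidden.

## Synthetic data generator

The generator emulates the *shapes* and statistical structure of a
two-brain-region case/control study; defaults are the standing study
conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 600 | gene universe |
| module_sizes | 6 × 60 | planted PPI/co-expression modules |
| n_case / n_control | 12 / 12 | samples per tissue |
| module_loading λ | 0.8 | shared-factor strength, log scale |
| de_log2fc / de_fraction | 1.0 / 0.1 | planted effect and prevalence |
| nb_dispersion α | 0.2 | Var = μ + αμ² |
| intra / inter_edge_p | 0.3 / 0.01 | planted-partition densities |
| decoy_edge_fraction | 0.2 | low-score edges (150–899) |
| targeting_odds / risk_odds | 20 / 10 | planted pivot / risk-list bias |

Counts are Gamma–Poisson: log-mean = b<sub>i</sub> + λf<sub>m(i),j</sub> +
β<sub>i</sub>·case<sub>j</sub>, with baseline b<sub>i</sub> ~ N(log 100, 1),
sample depth s<sub>j</sub> ~ LogNormal(0, 0.2), per-module per-sample
standard-normal factors f, and β<sub>i</sub> = ±de_log2fc·log 2 for
planted DE genes. Co-expression structure is *tissue-specific*: each
module's factor acts only in its designated tissue (default modules
1, 3, 5 in tissue A and 2, 4, 6 in tissue B), mirroring a design in which
each region has its own module set on one shared PPI network — this is
what makes cross-tissue module pairs distinct objects worth testing.

The PPI graph is a planted partition (within-module edge probability
intra_edge_p, between inter_edge_p) with integer combined scores uniform
in [900, 1000]; a configurable fraction of decoy edges with scores in
[150, 899] exercises the score filter. For each planted crosstalk pair,
extra inter-module edges are added until the pair carries at least three
times the *larger* of the partition's expected inter-module count and the
expected inter-set count of two random same-size node sets — on an
assortative graph the random-set expectation dominates, and it is the
quantity the permutation null resamples, so the smaller target would
leave planted pairs undetectable by construction.

Risk lists draw genes with odds risk_odds from designated modules;
regulator target sets use Efraimidis–Spirakis weighted sampling with odds
targeting_odds for planted pivots (each guaranteed ≥ 2 in-module
targets). The tissue-specific list contains, per tissue, the planted DE
genes exclusive to that tissue inside its designated modules (exclusivity
prevents a module from qualifying in both tissues by chance DEG overlap),
topped up with background genes from outside all modules.

All randomness flows from one root seed through named substreams
(network / design / expression-per-tissue / regulators / lists), so
regenerating one stage never perturbs another and identical configurations
are byte-identical on disk.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: read-level artifacts and mapping bias, batch and
covariate structure (age, PMI, RIN), multiple factors per module or
overlapping modules, degree-corrected PPI topology, regulator identifier
semantics, and any annotation-database structure (GMT collections are
abstract gene sets).

## Pipeline and reproducibility

Stages exchange plain TSV/GMT text files; every output table carries a
`#` header recording its parameters (never timestamps), and the run
manifest stores SHA-256 checksums per output, so reruns under a fixed
configuration are bit-identical. One root seed expands into substreams
per (stage, tissue, module pair). Validation is fail-fast before any
stage runs; expression/network symbol overlap below 50% warns, zero
overlap aborts. Exit codes: 0 success, 2 validation error, 1 stage
failure.

Problem sizes in the shipped tests and the acceptance script (600-gene
universe, 2,000-gene DE simulations, 200 calibration replicates at 2,000
draws, 50-seed pivot recovery, 10,000-draw end-to-end crosstalk) are
chosen so the whole suite exercises every stage at full fidelity while
remaining a desk-scale computation.

## Limitations

* The DE stage is a documented stand-in, not a reimplementation of any
  published tool: no shrinkage of dispersions or fold changes, no
  covariates, no outlier handling, no independent filtering.
* The static cut is not the dynamic hybrid tree cut; module boundaries on
  real data will differ from the reference implementation's.
* Hypergeometric universes, the tissue-specific strictness, and the pivot
  locality rule are configurable precisely because the conventions vary
  between published analyses; defaults are the strictest self-consistent
  readings.
* The permutation null treats the network as fixed and resamples gene
  sets uniformly; it does not condition on degree sequences.
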