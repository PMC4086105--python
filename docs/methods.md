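# Methods

## Model and procedure

`phylink` predicts functional linkage between genes from two independent
signals and a deliberately simple combination rule.

**Presence/absence profiles.** The evolutionary history of a gene is
summarized as a binary vector over a fixed, ordered species universe.
Presence in a species is called when any domain of any homology hit in
that species has a per-domain conditional E-value strictly below the
threshold (default 1e-7). Two consequences of this rule are worth
stating plainly:

- The comparison is a strict `<`. A hit at exactly the threshold calls
  absence. E-value ties at a round cutoff do occur in practice (search
  tools print truncated decimals), so this is a behavioural contract,
  not a corner case, and is pinned by tests.
- Aggregation over domains and paralogous targets is a plain OR, so the
  result is independent of hit order and of whether paralogs are
  collapsed before or after thresholding.

Genes listed in a caller-supplied roster but absent from the hit tables
receive all-zero profiles rather than being dropped: silently removing
them would distort downstream rankings. Because an all-zero profile's
distance to any query equals the query's presence count and carries no
co-evolution signal, the pipeline's candidate pools exclude all-zero
rows by default (`exclude_all_zero` / `--keep-all-zero`); the library
function includes them unless asked otherwise.

**Distance.** Co-evolution is scored by the raw Hamming distance between
profiles. No tree-aware weighting is applied: the method treats species
as exchangeable coordinates, which is its main modelling simplification
(see Limitations).

**Expression.** The co-expression signal is the sample Pearson
correlation across a tissue-wide atlas. Raw matrices are
log2-transformed (`log2(x + offset)`, default offset 1) and
quantile-normalized; matrices declared pre-normalized are accepted
as-is. Probe-level background correction and probe-to-gene mapping are
upstream concerns and out of scope. A constant expression vector has no
defined correlation; the undefined value is propagated as a NaN sentinel
and never coerced to 0, because 0 is a meaningful correlation for the
ranking filter while the sentinel means "no usable evidence".

**Ranking.** Candidates with r below 0.2 — note this includes every
anti-correlated gene — or with undefined/missing correlation are
excluded; survivors are ordered by (Hamming ascending, r descending,
gene id ascending) and truncated to the top 125. The third key makes the
order total, hence bit-reproducible. The filter precedes truncation.
There is no composite score: evolution strictly dominates expression.

**Evaluation.** Two resampling tests:

1. *Split-half coherence.* Each query's result list is split uniformly
   at random into halves of sizes ceil(n/2) and floor(n/2); the overlap
   of the two halves' annotation-term unions is Jaccard,
   |T1∩T2|/|T1∪T2| (intersection-over-smaller-set available via
   `statistic="over_smaller"`). The per-query fractions are compared
   against a randomized control — all result genes pooled, shuffled and
   re-dealt into sets of the original sizes, conserving the global gene
   multiset — with a two-sided two-sample KS test (asymptotic p,
   effective n = n_a·n_b/(n_a+n_b)). A single seeded split per query is
   the default; `n_splits` averages over repeats.
2. *Does expression help?* Per query, each ranking mode's top-N list is
   scored by the mean Jaccard overlap between the query's term set and
   each result gene's term set, and the two score samples are compared
   with a Wilcoxon rank-sum test. The query-centric score is the point:
   it rewards relevance to the query, whereas the split-half statistic
   rewards any internal coherence — an evolution-only list that sweeps
   in a complete, coherent but irrelevant co-evolving module would score
   well on coherence while being exactly the false-positive load the
   expression filter exists to remove. The Wilcoxon convention is the
   rank-sum W of the first sample with mid-ranks and a tie-corrected
   normal approximation; the convention string travels with the result
   so the magnitude of W is interpretable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `evalue_threshold` | 1e-7 | presence cutoff, strict `<`; dimensionless expected hit count |
| `min_corr` | 0.2 | Pearson cutoff for inclusion in the output list |
| `top_n` | 125 | output list length |
| `missing_expression_policy` | exclude | drop candidates absent from the atlas (or keep with sentinel, sorted after real-r peers of equal distance) |
| `overlap_statistic` | jaccard | split-half and query-overlap denominator |
| log2 `offset` | 1 | pseudocount before the log transform |

The first three defaults are the reference operating point of the
method; changing them changes what "a result" means, not just its
precision.

## Synthetic data: what it emulates and what it does not

The generator plants `n_modules` functional modules of `module_size`
genes inside `n_genes` total, over `n_species` species:

- *Profiles*: each module draws a Bernoulli(`profile_template_density`)
  template; members copy it with independent per-coordinate flips at
  rate `flip_noise`, so the expected within-module pairwise Hamming
  distance is `2·n_species·flip_noise·(1−flip_noise)`. Background genes
  are i.i.d. Bernoulli(`background_density`).
- *Expression*: one latent factor per module per sample; a member's
  value is `√ρ·factor + √(1−ρ)·noise` (ρ = `module_expression_rho`),
  giving exact theoretical within-module correlation ρ. Values are
  centred on a log2-scale baseline of 8.0 and scaled by `noise_sd`;
  the matrix is emitted in the `log2` state.
- *Hits*: the inverse of profile construction — every 1-cell yields a
  hit log-uniform below the threshold, and a `decoy_fraction` of 0-cells
  yields hits at/above it, so round-trip tests prove the presence rule
  (not hit existence) drives the profile. E-values are sampled, never
  computed from sequences.
- *Annotations*: `terms_per_module` (default 3) dedicated terms per
  module; each background gene joins one random term with probability
  `annotation_noise` (default 0.3), emulating the incidental annotations
  real background genes carry.

Defaults (182 species; 20 modules × 10 genes + 300 background;
`flip_noise` 0.02; `background_density` and `profile_template_density`
0.5; ρ = 0.7 over 100 samples) define the desk-scale benchmark used by
the acceptance script: small enough to run in seconds, large enough
that all three evaluation signatures (partner recovery, KS separation
from control, Wilcoxon improvement from expression) are measured rather
than assumed.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: there is no phylogenetic tree, so no
correlated gene loss along lineages (real profiles are far from i.i.d.
across species); modules are disjoint and equally sized, whereas real
pathways overlap and vary; expression is a single Gaussian factor per
module, with no tissue structure, batch effects or heavy tails; and
annotation terms are clean module labels, not a redundant hierarchical
ontology. Results on this benchmark demonstrate that the machinery is
correct and that the ranking recovers planted structure under realistic
noise levels — not that any particular genome-scale performance figure
transfers.

## Numerical choices

- *Quantile normalization ties*: tied values within a column receive the
  mean of the reference distribution over their tied ranks. Under this
  convention the "all columns share sorted values" and idempotence
  guarantees are exact only for tie-free columns; with ties, tied groups
  coalesce to group means and columns with different tie patterns can
  differ in their value multisets. Property tests therefore use
  continuous data, and tie handling is tested separately against the
  hand-derived rule.
- *Pearson*: computed from centred dot products and clipped into
  [−1, 1] to absorb rounding; fewer than 3 samples is an error rather
  than a high-variance estimate.
- *KS p-values*: the asymptotic two-sided distribution is used at every
  sample size, matching the test's documented contract; the D statistic
  itself is exact and oracle-checked against a brute-force ECDF scan.
- *Wilcoxon*: normal approximation with tie correction and no continuity
  correction; when the pooled sample is constant the variance is 0 and
  p is reported as 1. Cross-checked against the Mann–Whitney U
  asymptotic p (U = W − n_a(n_a+1)/2).
- *Determinism*: all randomness flows through explicitly passed seeded
  generators; equal seeds give byte-identical outputs, and ranking
  ties are always broken lexicographically.
- *Degenerate inputs*: empty result lists and term-less halves score
  0.0 in the overlap statistics; a single-column matrix passes through
  quantile normalization unchanged with a warning; an empty species
  universe, duplicate taxa or duplicate gene rows are fatal at load
  time with coordinates in the message.

## Known limitations

- Raw Hamming distance ignores phylogenetic non-independence: a clade of
  50 closely related species contributes 50 nearly redundant
  coordinates. Tree-aware profiling methods address this; this package
  intentionally implements the tree-free variant.
- The 0.2 correlation filter discards anti-correlated genes by design,
  although strong negative co-expression can itself be functional
  signal (e.g. repression).
- The expression atlas and profile matrix must share a gene namespace;
  no identifier mapping is attempted.
- The split-half statistic depends on list length and annotation
  density; comparisons are meaningful within an evaluation run, not
  across differently parameterized runs.
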