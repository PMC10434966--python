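# Methods

This note documents the models and numerical choices behind `cofracnet`:
what each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Input model

A *dataset* is one co-fractionation experiment: a protein × fraction
abundance matrix, or equivalently a precomputed symmetric interaction-score
matrix. Datasets are grouped into *collections*; one collection represents
one complexome (one species × tissue/life-stage context) and its datasets
must share a protein identifier namespace. Missing abundance cells are read
as 0, not NaN: absence from a fraction is treated as an abundance
observation, which keeps Pearson correlation defined. Datasets of the same
species in *different* collections are linked by identifier identity (an
implicit self-orthology); across species, only the provided one-to-one
ortholog pairs define equivalence, and no transitive closure across three
species is taken.

## Within-dataset scoring

Interaction scores default to Pearson correlation over fractions. Proteins
with zero variance across fractions have undefined correlations; these are
stored as NaN and excluded from interactor rankings entirely rather than
given a sentinel score, since any sentinel would occupy rank positions and
distort the top-fraction cutoffs downstream. Ties in interactor rankings
are broken by identifier (lexicographic), making every ranking
deterministic.

## Rank-biased overlap

The similarity between two interactor profiles is the non-extrapolated
(truncated, lower-bound) rank-biased overlap: the weighted agreement sum
`Σ_{d=1..D} (1−p) p^(d−1) A_d` with no residual extrapolation and no
`1/(1−p^k)` renormalization. `A_d` is `|overlap of top-d prefixes| / d`,
with cross-species overlap counted through the ortholog map; unmapped
proteins are unique to their list. The evaluation depth is
`D = min(k, max(len_a, len_b))` where `k` is the smallest depth whose ranks
carry the configured share (default 99 %) of the total weight — `k = 44`
for `p = 0.9` — further capped at dataset size − 1. With this truncation
rule, identical lists of length `L < k` score exactly `1 − p^L`. The
compared proteins themselves are not removed from each other's profiles.

`p` (default 0.9) sets top-heaviness; smaller values concentrate weight on
the first few ranks and suit data where only nearest co-migrators are
informative. The implementation computes the sum per common element as a
tail-weight lookup (`Σ_e T(max(rank_a(e), rank_b(e)))` with
`T(m) = Σ_{d=m..D} (1−p)p^(d−1)/d`), which is algebraically identical to
the prefix-overlap sum and is verified against a brute-force prefix oracle
in the test suite.

## Edge selection and normalization

Raw RBO magnitudes are incomparable across protein pairs (small complexes
produce systematically lower scores than large ones) and across dataset
pairs (different proteome overlap). Two corrections are applied, in this
order:

1. **Reciprocal top hits.** For each dataset pair, an edge survives only if
   its score lies within the top `ceil(fraction · n_opposite)` scores of
   *both* endpoints against the opposite dataset (default fraction 0.01;
   ties at the cutoff value are kept; exact zeros are never edges). The
   cutoff is computed per protein against one opposite dataset, not pooled
   over all datasets.
2. **Per-pair mean normalization.** Each dataset pair's surviving edge
   weights are scaled multiplicatively to mean 1.0. The target constant is
   arbitrary since Markov clustering column-normalizes; equality of means
   is what matters.

Within-collection dataset pairs are compared exactly like cross-collection
pairs — their edges are what make the fraction-clustered score meaningful.

## Markov clustering

The hypernetwork is clustered with a native implementation of the Markov
Cluster algorithm on scipy sparse matrices: self-loops (weight = max
incident edge weight, 1.0 for isolated nodes), column normalization, then
alternating expansion (matrix power, default 2) and inflation (element-wise
power, default 2.0, entries below 1e-5 pruned, columns renormalized; a
column emptied by pruning is restored as a self-loop-only column) until the
maximum absolute entry change falls below 1e-8 or 100 iterations.
Clusters are read from the limit matrix's attractors: attractors occurring
in each other's rows form one attractor system, and every node joins the
system receiving most of its flow, ties to the lowest-indexed system — so
the output is always a partition, deterministic, and clusters never span
disconnected components. Bit-compatibility with the external `mcl` binary
is not promised; an adapter (`cofracnet.mcl.run_mcl_binary`) can run an
installed binary for cross-validation.

## Cluster post-processing

Superclusters are split by collection; each protein's FrC uses the
collection's *total* dataset count as denominator regardless of detection
(non-detection is lack of evidence, not counter-evidence). Coherence is
`Σ actual / Σ possible` over dataset pairs, with `possible = min(n, k)` per
pair; subcluster coherence restricts the sum to pairs with at least one
dataset from that collection — the pair universe for subcluster coherence
is not canonically defined, and this choice keeps cross-system evidence
while reflecting the collection in question. Filtering requires
`actual ≥ 2` and a protein at `FrC ≥ 0.5` (both inclusive). Best-guess
selection is strictly-greater (`FrC > 1/2`, plus the ortholog rescue rule);
annotation requires a cluster to contain strictly more than half (default,
configurable) of a reference complex, with ties broken by contained count,
then smaller subcluster, then cluster id.

## Evaluation

A raw reference set is processed in a fixed order: deduplicate identical
member sets, remove proper subsets (sub-assemblies), drop members detected
in fewer than 2 of the reference collection's datasets, then drop complexes
with fewer than 3 remaining members. The maximum matching ratio is computed
as a maximum-weight bipartite matching (rectangular linear assignment;
edges require `ω ≥ 0.25`) between processed complexes and cluster member
sets of the reference collection — by default all clustered proteins of
filtered clusters; best-guess-only is an option
(`PipelineParams.mmr_best_guess_only`), as the member-selection rule for
reference comparison is a free choice.

## Synthetic data generator

The generator emulates the *shape* of multi-species complexome studies, not
their biochemistry. Members of a planted complex share one Gaussian
migration peak per species (centre jittered per dataset by at most
`peak_jitter` fractions), scaled by a per-protein amplitude and
multiplicative log-normal noise per measurement. Background proteins
receive an independent random peak per dataset — background co-migration is
therefore not reproducible across replicates, which is what the FrC and
best-guess machinery exploits. Species-specific subunits co-migrate with
their complex but exist in only one species' namespace; conserved subunits
are paired in the emitted orthology maps minus a dropout probability.

Defaults describe a desk-scale two-species benchmark: 2 species × 1
collection × 2 replicates, 60 fractions, 10 complexes of 5–10 subunits,
20 % species-specific subunits, 10 % ortholog dropout, `noise_sd = 0.1`,
`peak_width = 2.0` fractions (FWHM ≈ 4.7), `peak_jitter = 1.0`, and 1000
background proteins per species.

Two defaults are structural rather than cosmetic:

* **Proteome scale.** The reciprocal top-hit rule keeps
  `ceil(0.01 · n_opposite)` hits per protein, so a complex of ~10 subunits
  can only stay internally connected when datasets contain on the order of
  1000 proteins — which is also the realistic scale of complexome
  profiles. Tiny toy worlds must relax `top_hit_fraction` accordingly (the
  plumbing tests do).
* **Resolvability.** Complex migration positions are evenly spaced
  (independently permuted per species, ±0.5-fraction offsets) and the
  generator refuses configurations whose implied spacing falls below ~2
  peak widths: complexes co-migrating within a peak width are physically
  indistinguishable to any co-fractionation method, so a benchmark planting
  them would measure nothing. Background peaks get heterogeneous widths
  (0.75–2.5 × `peak_width`), reflecting that non-complex background
  migrates as monomers and broad smears rather than sharp complex-like
  peaks; with a single shared width, dozens of background proteins sit on
  every complex peak at correlation ≈ 1 and form unresolvable blobs.

What a green recovery test does establish: under reproducible co-migration
with modest noise and jitter, the full chain — correlation, orthology-aware
RBO, reciprocal top hits, normalization, MCL, FrC/best-guess — isolates each
planted complex per species and rescues low-FrC members through orthologs.
What it does not establish: performance under real-data pathologies the
generator omits — sub-assemblies and module splits, multi-peak profiles,
detector missingness, systematic between-replicate shifts, or many-to-many
orthology.

## Determinism and degenerate inputs

No stage is stochastic: rankings break ties lexicographically, MCL is
deterministic for a given node set, and output tables have a fixed sort
order (cluster id, collection, FrC descending, identifier), so identical
inputs yield byte-identical outputs. Degenerate cases are defined
explicitly: empty interactor profiles score 0; an empty edge set passes
through normalization; coherence with zero possible matches is 0; a
network node without edges clusters as a singleton; `ω` is undefined (an
error) only for an empty reference complex.

## Known limitations

* One-to-one orthology only; paralog expansions are represented at most by
  the single best pairing.
* The MCL implementation targets desk-scale networks (up to ~10⁴ nodes);
  very large studies would need the external `mcl` adapter.
* Reference-based evaluation assumes the reference shares the collection's
  identifier namespace; no identifier mapping layer is provided.
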