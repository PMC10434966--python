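# cofracnet

Comparative clustering of protein co-fractionation (complexome profiling)
data across species and conditions.

Complexome profiling separates native protein complexes — typically by
blue-native gel electrophoresis — into fractions that are then quantified by
mass spectrometry, giving every protein a migration profile. Proteins that
co-migrate are candidate members of the same complex. A single experiment is
noisy and a single species view is incomplete: `cofracnet` integrates many
such datasets, from multiple species and conditions, into one analysis that
pools replicate evidence and transfers support across species through
orthology, without forcing any protein to have an ortholog.

## Method

For each dataset, Pearson correlations between migration profiles rank
every protein's potential interactors into its *interactor profile*. Two
proteins *i*, *j* from different datasets are compared by the non-extrapolated
**rank-biased overlap** of their interactor profiles,

```
RBO(i, j) = Σ_{d=1..k} (1 − p) p^(d−1) · A_d ,
```

where `A_d` is the fraction of the top-`d` list prefixes shared (orthologous
proteins count as shared across species), `p = 0.9` controls top-heaviness,
and the depth `k` keeps the ranks carrying 99 % of the total weight
(`k = 44` at the defaults). For each dataset pair, only **reciprocal top
hits** are kept — pairs scoring in the top 1 % of both proteins' score lists
— and the retained edge weights are normalized to a common mean. The union
of all pairs forms a hypernetwork over `(dataset, protein)` elements, which
is clustered with the **Markov Cluster algorithm** (inflation 2.0).

Each resulting *supercluster* is split into per-collection *subclusters*
(a collection = the datasets of one complexome, e.g. one species), and
every protein gets a **fraction clustered** score
`FrC = (datasets contributing it) / (datasets in the collection)`. The
*best guess* member set holds proteins with `FrC > 1/2` plus lower-scoring
proteins whose ortholog exceeds 1/2 in another subcluster of the same
supercluster. Cluster quality is summarized by **coherence** — equivalent
element pairs (same protein, or orthologs) actually co-clustered divided by
the possible pairs `Σ min(n, k)` over dataset pairs — and clusters need at
least 2 matches and one protein at `FrC ≥ 0.5` to pass filtering. Clusters
can be annotated against a reference complex set (e.g. CORUM), and
agreement with the reference is quantified by the **maximum matching
ratio** with overlap weight `ω(A,B) = |A∩B|² / (|A|·|B|)`.

## Worked example

Simulate a two-species benchmark with planted complexes, run the full
workflow, and inspect the output tables:

```
cofracnet simulate --out demo --seed 7 --n-complexes 4 --background-proteins 200
cofracnet run --samples demo/samples.tsv --ortho-dir demo \
    --out demo_out --th-fraction 0.05
```

The run prints (to stderr):

```
207 superclusters (5 passed filtering); tables written to demo_out
```

`demo_out/cluster_summary.tsv` lists one row per supercluster. The clusters
that pass filtering are the planted complexes:

```
supercluster_id  n_subclusters  actual_matches  possible_matches  coherence  passed_filter  annotation
13               2              40              62                0.645161   1
42               2              52              79                0.658228   1
58               2              50              69                0.724638   1
80               2              44              67                0.656716   1
```

Cluster 13 recovers one planted complex: in `cluster_members.tsv` its eight
subunits appear in both replicates (`frc = 1.0`) and enter the best-guess
selection, while background proteins that co-migrated in only one replicate
stay at `frc = 0.5` and are excluded:

```
supercluster_id  collection_id  protein         frc  best_guess
13               sp1_c1         sp1_cplx02s01   1.0  1
13               sp1_c1         sp1_cplx02s02   1.0  1
...
13               sp1_c1         sp1_bg014       0.5  0
```

The same workflow runs on real data: point the sample sheet at your
profile TSVs (rows = proteins, columns = fraction abundances) or
precomputed symmetric score matrices, and supply one two-column orthology
TSV per species pair. The library API (`cofracnet.run_pipeline`) exposes
every stage separately; see `docs/methods.md` for the model details and
parameter guidance.

## Acceptance script

`scripts/acceptance.py` recomputes the worked-example quantity that
anchors the coherence definition — aggregating a rubisco supercluster's 15
per-dataset-pair actual/possible match counts into a single coherence score
via the package's own scoring code — and writes the result as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
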