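"""Scoring, filtering and annotation of raw MCL clusters.

A raw MCL cluster (*supercluster*) mixes (dataset, protein) elements from all
input datasets. It is split into per-collection *subclusters*, whose proteins
get a fraction-clustered score

    FrC = (number of the collection's datasets contributing the protein
           to this cluster) / (total datasets in the collection),

with the total dataset count always the denominator: a protein not being
detected is treated as absence of evidence, not evidence of absence. Cluster
quality is measured by *coherence*: the number of equivalent element pairs
(same protein within a species, orthologs across species) actually
co-clustered, divided by the number possible given the cluster's composition
(sum of min pair-counts over dataset pairs). Clusters with at least 2 matches
and at least one protein at FrC >= 0.5 pass filtering; a reference-complex
set can annotate clusters containing more than a threshold fraction of a
known complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import (
    Collection,
    Element,
    OrthologyMap,
    ReferenceComplexSet,
    SubCluster,
    SuperCluster,
    ValidationError,
)

__all__ = [
    "EquivalenceIndex",
    "split_superclusters",
    "fraction_clustered",
    "count_matches",
    "coherence_score",
    "subcluster_coherence",
    "best_guess_selection",
    "filter_clusters",
    "annotate_with_reference",
    "postprocess_clusters",
]


@dataclass
class EquivalenceIndex:
    """Resolves protein equivalence across datasets and species.

    Two elements are equivalent when they are the same identifier within one
    species (datasets of one species share a namespace, also across
    collections) or a provided one-to-one ortholog pair across species. No
    transitive closure across three species is taken.
    """

    dataset_species: dict[str, str]
    dataset_collection: dict[str, str]
    collection_species: dict[str, str]
    orthologies: list[OrthologyMap] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._maps: dict[tuple[str, str], dict[str, str]] = {}
        for om in self.orthologies:
            a, b = om.species_pair
            self._maps[(a, b)] = om.mapping(a, b)
            self._maps[(b, a)] = om.mapping(b, a)

    def translate(self, protein: str, from_species: str,
                  to_species: str) -> str | None:
        """Equivalent identifier in the target species, or None."""
        if from_species == to_species:
            return protein
        m = self._maps.get((from_species, to_species))
        if m is None:
            raise KeyError(
                f"no orthology provided for species pair "
                f"({from_species}, {to_species})"
            )
        return m.get(protein)

    def has_pair(self, species_a: str, species_b: str) -> bool:
        return species_a == species_b or (species_a, species_b) in self._maps

    def directed_map(self, from_species: str,
                     to_species: str) -> dict[str, str] | None:
        """Identifier mapping between species; None means identity."""
        if from_species == to_species:
            return None
        m = self._maps.get((from_species, to_species))
        if m is None:
            raise KeyError(
                f"no orthology provided for species pair "
                f"({from_species}, {to_species})"
            )
        return m


def split_superclusters(raw_cluster: set[Element],
                        equiv: EquivalenceIndex) -> dict[str, set[Element]]:
    """Partition a cluster's elements by input collection."""
    out: dict[str, set[Element]] = {}
    for el in raw_cluster:
        cid = equiv.dataset_collection.get(el[0])
        if cid is None:
            raise ValidationError(f"element {el} has unknown dataset")
        out.setdefault(cid, set()).add(el)
    return out


def fraction_clustered(elements: set[Element],
                       collection: Collection) -> dict[str, float]:
    """FrC per protein: datasets contributing it / collection.n_datasets."""
    counts: dict[str, int] = {}
    members = set(collection.dataset_ids)
    for ds, prot in elements:
        if ds in members:
            counts[prot] = counts.get(prot, 0) + 1
    n = collection.n_datasets
    return {prot: c / n for prot, c in counts.items()}


def count_matches(elements: set[Element], equiv: EquivalenceIndex,
                  ) -> tuple[int, int, dict[tuple[str, str], tuple[int, int]]]:
    """Actual and possible equivalent-pair matches per dataset pair.

    For each unordered dataset pair with members in the cluster, possible
    matches = min of the two member counts, and actual matches = equivalent
    element pairs present in both. Returns totals plus the per-pair table.
    """
    by_dataset: dict[str, set[str]] = {}
    for ds, prot in elements:
        by_dataset.setdefault(ds, set()).add(prot)
    datasets = sorted(by_dataset)
    per_pair: dict[tuple[str, str], tuple[int, int]] = {}
    for i, da in enumerate(datasets):
        for db in datasets[i + 1:]:
            pa, pb = by_dataset[da], by_dataset[db]
            sa = equiv.dataset_species[da]
            sb = equiv.dataset_species[db]
            if sa == sb:
                actual = len(pa & pb)
            else:
                actual = sum(
                    1 for x in pa
                    if (y := equiv.translate(x, sa, sb)) is not None
                    and y in pb
                )
            per_pair[(da, db)] = (actual, min(len(pa), len(pb)))
    actual_total = sum(a for a, _ in per_pair.values())
    possible_total = sum(p for _, p in per_pair.values())
    return actual_total, possible_total, per_pair


def coherence_score(actual: int, possible: int) -> float:
    """Fraction of possible matches; 0 when no match is possible."""
    if possible < 0:
        raise ValidationError("possible match count cannot be negative")
    return actual / possible if possible > 0 else 0.0


def subcluster_coherence(per_pair: dict[tuple[str, str], tuple[int, int]],
                         collection: Collection) -> float:
    """Coherence restricted to pairs touching one collection's datasets."""
    members = set(collection.dataset_ids)
    actual = possible = 0
    for (da, db), (a, p) in per_pair.items():
        if da in members or db in members:
            actual += a
            possible += p
    return coherence_score(actual, possible)


def best_guess_selection(super_cluster: SuperCluster,
                         equiv: EquivalenceIndex,
                         threshold: float = 0.5) -> None:
    """Fill each subcluster's best-guess member set in place.

    Selected are proteins with FrC above the threshold, plus lower-FrC
    proteins that cluster with an equivalent protein (ortholog, or the same
    identifier in another collection of the same species) whose FrC exceeds
    the threshold in another subcluster of the same supercluster.
    """
    subs = super_cluster.subclusters
    high = {
        cid: {p for p, frc in sub.members.items() if frc > threshold}
        for cid, sub in subs.items()
    }
    for cid, sub in subs.items():
        selected = set(high[cid])
        sp = equiv.collection_species[cid]
        for prot in sub.members:
            if prot in selected:
                continue
            for other_cid, other_high in high.items():
                if other_cid == cid or not other_high:
                    continue
                other_sp = equiv.collection_species[other_cid]
                if not equiv.has_pair(sp, other_sp):
                    continue
                eq = equiv.translate(prot, sp, other_sp)
                if eq is not None and eq in other_high:
                    selected.add(prot)
                    break
        sub.best_guess = selected


def filter_clusters(superclusters: list[SuperCluster],
                    min_matches: int = 2,
                    min_frc: float = 0.5) -> list[SuperCluster]:
    """Flag clusters with >= min_matches matches and a protein at
    FrC >= min_frc (both thresholds inclusive); all clusters are retained."""
    for sc in superclusters:
        max_frc = max(
            (frc for sub in sc.subclusters.values()
             for frc in sub.members.values()),
            default=0.0,
        )
        sc.passed_filter = (sc.actual_matches >= min_matches
                            and max_frc >= min_frc)
    return superclusters


def annotate_with_reference(superclusters: list[SuperCluster],
                            ref: ReferenceComplexSet,
                            reference_collection: str,
                            min_fraction: float = 0.5,
                            ) -> dict[str, int]:
    """Annotate clusters with reference complexes.

    For each reference complex the cluster whose reference-collection
    subcluster contains most of its members is found; it is annotated iff
    the contained fraction strictly exceeds ``min_fraction``. Ties go to the
    larger contained count, then the smaller subcluster, then the smaller
    cluster id. Returns the complex -> cluster_id assignment.
    """
    assignment: dict[str, int] = {}
    annotations: dict[int, list[str]] = {}
    for name in sorted(ref.complexes):
        members = ref.complexes[name]
        best: tuple[int, int, int] | None = None  # (-count, sub size, id)
        for sc in superclusters:
            sub = sc.subclusters.get(reference_collection)
            if sub is None:
                continue
            count = len(members & sub.members.keys())
            if count == 0:
                continue
            key = (-count, len(sub.members), sc.cluster_id)
            if best is None or key < best:
                best = key
        if best is None:
            continue
        count = -best[0]
        if count / len(members) > min_fraction:
            assignment[name] = best[2]
            annotations.setdefault(best[2], []).append(name)
    for sc in superclusters:
        names = annotations.get(sc.cluster_id)
        sc.annotation = ";".join(sorted(names)) if names else None
    return assignment


def postprocess_clusters(raw_clusters: list[set[Element]],
                         collections: dict[str, Collection],
                         equiv: EquivalenceIndex,
                         best_guess_threshold: float = 0.5,
                         min_matches: int = 2,
                         min_frc: float = 0.5,
                         reference: ReferenceComplexSet | None = None,
                         reference_collection: str | None = None,
                         annotation_threshold: float = 0.5,
                         ) -> list[SuperCluster]:
    """Run the full post-processing chain on raw MCL clusters."""
    supers: list[SuperCluster] = []
    for cid, raw in enumerate(raw_clusters, 1):
        sc = SuperCluster(cluster_id=cid, elements=set(raw))
        by_collection = split_superclusters(sc.elements, equiv)
        actual, possible, per_pair = count_matches(sc.elements, equiv)
        sc.actual_matches = actual
        sc.possible_matches = possible
        sc.coherence = coherence_score(actual, possible)
        for ccid, els in by_collection.items():
            coll = collections[ccid]
            sc.subclusters[ccid] = SubCluster(
                collection_id=ccid,
                members=fraction_clustered(els, coll),
                coherence=subcluster_coherence(per_pair, coll),
            )
        best_guess_selection(sc, equiv, best_guess_threshold)
        supers.append(sc)
    filter_clusters(supers, min_matches=min_matches, min_frc=min_frc)
    if reference is not None:
        if reference_collection is None:
            raise ValidationError(
                "a reference collection must be named when a reference "
                "complex set is provided"
            )
        annotate_with_reference(supers, reference, reference_collection,
                                min_fraction=annotation_threshold)
    return supers
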