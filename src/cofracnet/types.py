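"""Core domain types for comparative complexome-profile clustering.

The central objects are per-experiment profile/score matrices, the grouping of
experiments into *collections* (one collection = one complexome: a species or
tissue/life-stage context assumed to share a single true set of complexes),
pairwise one-to-one orthology maps between species, and the cluster structures
produced downstream.

A hypernetwork *element* is the pair ``(dataset_id, protein)``: the same
protein identifier measured in two datasets gives two distinct elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Element",
    "ProfileDataset",
    "InteractionMatrix",
    "Collection",
    "OrthologyMap",
    "ReferenceComplexSet",
    "EdgeSet",
    "HyperNetwork",
    "SubCluster",
    "SuperCluster",
    "ValidationError",
]

#: a node of the hypernetwork: (dataset_id, protein identifier)
Element = tuple[str, str]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _check_unique(names, what: str) -> None:
    seen: set[str] = set()
    dupes: set[str] = set()
    for n in names:
        if n in seen:
            dupes.add(n)
        seen.add(n)
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(dupes)}")


@dataclass
class ProfileDataset:
    """One co-fractionation experiment: a protein x fraction abundance matrix.

    Parameters
    ----------
    dataset_id, collection_id, species_id
        Identify the experiment and the complexome/species it belongs to.
    proteins
        Ordered, unique protein identifiers (rows).
    abundances
        Nonnegative real matrix of shape ``(len(proteins), n_fractions)``;
        missing measurements are stored as 0 (absence of evidence), never NaN.
    fractions
        Optional column labels.
    """

    dataset_id: str
    collection_id: str
    species_id: str
    proteins: list[str]
    abundances: np.ndarray
    fractions: list[str] | None = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 2:
            raise ValidationError("abundances must be a 2-D matrix")
        if self.abundances.shape[0] != len(self.proteins):
            raise ValidationError(
                f"{self.dataset_id}: {len(self.proteins)} proteins but "
                f"{self.abundances.shape[0]} abundance rows"
            )
        if self.abundances.shape[1] < 2:
            raise ValidationError(
                f"{self.dataset_id}: needs >=2 fractions, got "
                f"{self.abundances.shape[1]}"
            )
        _check_unique(self.proteins, f"protein identifiers in {self.dataset_id}")
        if not np.isfinite(self.abundances).all():
            raise ValidationError(f"{self.dataset_id}: non-finite abundance values")

    @property
    def n_fractions(self) -> int:
        return self.abundances.shape[1]


@dataclass
class InteractionMatrix:
    """Symmetric within-dataset interaction scores (diagonal never consulted).

    Invalid pairs (e.g. correlations involving a zero-variance profile) are
    stored as NaN and excluded from interactor rankings.
    """

    dataset_id: str
    collection_id: str
    species_id: str
    proteins: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.proteins)
        if self.scores.shape != (n, n):
            raise ValidationError(
                f"{self.dataset_id}: score matrix shape {self.scores.shape} "
                f"does not match {n} proteins"
            )
        _check_unique(self.proteins, f"protein identifiers in {self.dataset_id}")
        off = ~np.eye(n, dtype=bool)
        a, b = self.scores, self.scores.T
        both = off & ~(np.isnan(a) & np.isnan(b))
        dev = np.nanmax(np.abs(a - b)[both], initial=0.0) if n > 1 else 0.0
        if dev > 1e-9:
            raise ValidationError(
                f"{self.dataset_id}: asymmetric score matrix "
                f"(max deviation {dev:.3g})"
            )

    @property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}


@dataclass
class Collection:
    """A group of datasets representing one complexome.

    ``n_datasets`` is the denominator for the fraction-clustered (FrC) score:
    always the total number of datasets in the collection, regardless of how
    many detected a given protein.
    """

    collection_id: str
    species_id: str
    dataset_ids: list[str]

    def __post_init__(self) -> None:
        if not self.dataset_ids:
            raise ValidationError(
                f"collection {self.collection_id} has no datasets"
            )
        _check_unique(self.dataset_ids, f"dataset ids in {self.collection_id}")

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_ids)


class OrthologyMap:
    """One-to-one orthologous identifier pairing between two species.

    Each identifier may occur in at most one pair; lookup is symmetric.
    """

    def __init__(self, species_pair: tuple[str, str],
                 pairs: set[tuple[str, str]]):
        self.species_pair = species_pair
        self.pairs = set(pairs)
        _check_unique((a for a, _ in self.pairs),
                      f"left identifiers in orthology {species_pair}")
        _check_unique((b for _, b in self.pairs),
                      f"right identifiers in orthology {species_pair}")
        self._fwd = {a: b for a, b in self.pairs}
        self._rev = {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def mapping(self, from_species: str, to_species: str) -> dict[str, str]:
        """Directed identifier mapping; raises for an unknown species pair."""
        if (from_species, to_species) == self.species_pair:
            return self._fwd
        if (to_species, from_species) == self.species_pair:
            return self._rev
        raise KeyError(
            f"orthology {self.species_pair} does not cover "
            f"({from_species}, {to_species})"
        )

    def reversed(self) -> "OrthologyMap":
        return OrthologyMap(
            (self.species_pair[1], self.species_pair[0]),
            {(b, a) for a, b in self.pairs},
        )


@dataclass
class ReferenceComplexSet:
    """Named reference complexes in one collection's identifier namespace."""

    complexes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            if not members:
                raise ValidationError(f"reference complex {name!r} is empty")

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class EdgeSet:
    """Weighted edges from one dataset-pair comparison.

    Edges are tuples ``(element_a, element_b, weight)`` with positive weights;
    element_a belongs to the first dataset of ``dataset_pair``.
    """

    dataset_pair: tuple[str, str]
    edges: list[tuple[Element, Element, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ea, eb, w in self.edges:
            if not (w > 0 and np.isfinite(w)):
                raise ValidationError(
                    f"non-positive/non-finite weight {w} on edge {ea}-{eb}"
                )

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.edges], dtype=float)

    def rescaled(self, factor: float) -> "EdgeSet":
        return EdgeSet(self.dataset_pair,
                       [(ea, eb, w * factor) for ea, eb, w in self.edges])


@dataclass
class HyperNetwork:
    """Combined undirected weighted graph over (dataset, protein) elements."""

    nodes: list[Element]
    edges: list[tuple[Element, Element, float]]
    #: detected elements that survived no edge (reported, not clustered)
    isolated: list[Element] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SubCluster:
    """One collection's projection of a supercluster.

    ``members`` maps each protein to its fraction-clustered score:
    (number of the collection's datasets contributing it) / n_datasets.
    ``best_guess`` is the prioritized member subset: FrC above threshold, plus
    lower-FrC proteins with an equivalent above-threshold member in another
    subcluster of the same supercluster.
    """

    collection_id: str
    members: dict[str, float]
    best_guess: set[str] = field(default_factory=set)
    coherence: float = 0.0


@dataclass
class SuperCluster:
    """An MCL cluster of hypernetwork elements plus derived scores."""

    cluster_id: int
    elements: set[Element]
    subclusters: dict[str, SubCluster] = field(default_factory=dict)
    actual_matches: int = 0
    possible_matches: int = 0
    coherence: float = 0.0
    passed_filter: bool = False
    annotation: str | None = None

    @property
    def n_elements(self) -> int:
        return len(self.elements)
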