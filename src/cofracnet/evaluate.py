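"""Reference-based evaluation of cluster results.

A curated complex reference (e.g. CORUM for human) is first processed to a
fair comparison set — duplicates and sub-assembly subsets removed, members
not detected in enough datasets dropped, then complexes of fewer than three
remaining members discarded. Agreement of cluster results with the processed
reference is summarized by the maximum matching ratio (MMR): reference
complexes and clusters form a bipartite graph weighted by the overlap score

    omega(A, B) = |A ∩ B|^2 / (|A| * |B|),

a maximum-weight matching (each complex and each cluster used at most once)
is computed over edges with omega above a minimum, and the matched weight sum
is divided by the number of reference complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import ReferenceComplexSet, ValidationError

__all__ = [
    "MatchingResult",
    "process_reference_set",
    "overlap_score",
    "maximum_matching_ratio",
    "recovery_jaccard",
]


@dataclass
class MatchingResult:
    """Outcome of matching reference complexes to clusters."""

    assignment: dict[str, tuple[int, float]]  # complex -> (cluster idx, omega)
    mmr: float


def process_reference_set(ref: ReferenceComplexSet,
                          detection_counts: dict[str, int],
                          min_detected: int = 2,
                          min_size: int = 3) -> ReferenceComplexSet:
    """Prepare a raw reference for evaluation.

    In order: deduplicate identical member sets (first name by sort order
    kept); remove complexes that are proper subsets of another; drop member
    proteins detected in fewer than ``min_detected`` datasets; remove
    complexes left with fewer than ``min_size`` members.
    """
    items = sorted(ref.complexes.items())
    seen: set[frozenset[str]] = set()
    deduped = []
    for name, members in items:
        if members in seen:
            continue
        seen.add(members)
        deduped.append((name, members))

    kept = []
    for name, members in deduped:
        if any(members < other for _, other in deduped):
            continue
        kept.append((name, members))

    out: dict[str, frozenset[str]] = {}
    for name, members in kept:
        detected = frozenset(
            p for p in members if detection_counts.get(p, 0) >= min_detected
        )
        if len(detected) >= min_size:
            out[name] = detected
    return ReferenceComplexSet(out)


def overlap_score(a: set[str], b: set[str]) -> float:
    """omega = |A∩B|^2 / (|A|·|B|); 1 iff the sets are equal."""
    if not a:
        raise ValidationError("overlap score undefined for an empty set A")
    if not b:
        return 0.0
    inter = len(set(a) & set(b))
    return inter * inter / (len(set(a)) * len(set(b)))


def maximum_matching_ratio(clusters: list[set[str]],
                           ref: ReferenceComplexSet,
                           min_overlap: float = 0.25) -> MatchingResult:
    """MMR of a cluster list against a processed reference.

    Edges with omega >= min_overlap enter a maximum-weight bipartite
    matching (solved as a rectangular assignment problem; omitting an edge
    is equivalent to weight 0 since all weights are nonnegative); the
    matched omega sum is divided by the number of reference complexes.
    """
    names = sorted(ref.complexes)
    if not names:
        return MatchingResult({}, 0.0)
    nonempty = [(j, c) for j, c in enumerate(clusters) if c]
    w = np.zeros((len(names), len(nonempty)))
    for i, name in enumerate(names):
        for col, (_, cluster) in enumerate(nonempty):
            om = overlap_score(ref.complexes[name], cluster)
            if om >= min_overlap:
                w[i, col] = om
    assignment: dict[str, tuple[int, float]] = {}
    total = 0.0
    if w.size and w.any():
        rows, cols = linear_sum_assignment(w, maximize=True)
        for i, col in zip(rows, cols):
            if w[i, col] > 0:
                assignment[names[i]] = (nonempty[col][0], float(w[i, col]))
                total += float(w[i, col])
    return MatchingResult(assignment, total / len(names))


def recovery_jaccard(selected: set[str], known: set[str]) -> float:
    """Jaccard index TP / (TP + FP + FN) of a selection against known
    members (the known set should be restricted to detected proteins)."""
    selected, known = set(selected), set(known)
    if not selected and not known:
        return 0.0
    tp = len(selected & known)
    return tp / (tp + len(selected - known) + len(known - selected))
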