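"""Cross-dataset comparison and hypernetwork assembly.

Every dataset pair (within or across collections) is compared all-against-all
with orthology-aware RBO, yielding a dense per-pair score table. Because raw
RBO magnitudes depend on complex size and dataset overlap, only *reciprocal
top hits* are kept — pairs whose score lies in the top fraction (default 1%)
of both proteins' score lists against the opposite dataset. Retained per-pair
edge weights are then normalized to a common mean so that every dataset pair
contributes comparably, and the union of all edges forms the hypernetwork
that is clustered downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scoring import InteractorProfile, RBOParams, _tail_table
from .types import EdgeSet, Element, HyperNetwork, InteractionMatrix, ValidationError

__all__ = [
    "ScoreTable",
    "dataset_profiles",
    "pairwise_interactor_similarity",
    "select_reciprocal_top_hits",
    "normalize_pair_scores",
    "build_hypernetwork",
]


@dataclass
class ScoreTable:
    """Dense RBO scores between all protein pairs of two datasets."""

    dataset_pair: tuple[str, str]
    proteins_a: list[str]
    proteins_b: list[str]
    scores: np.ndarray  # shape (len(proteins_a), len(proteins_b))


def dataset_profiles(m: InteractionMatrix,
                     params: RBOParams) -> list[InteractorProfile]:
    """Truncated interactor profiles for every protein of a dataset.

    Depth is capped at dataset size - 1 (a list cannot exceed the measured
    proteome). Vectorized but rank-for-rank identical to
    :func:`~cofracnet.scoring.rank_interactors` truncated to depth.
    """
    n = len(m.proteins)
    k = min(params.k, n - 1) if n > 1 else 1
    # tie-break by identifier: lexicographic rank of each protein
    lex = np.empty(n, dtype=int)
    lex[np.argsort(np.array(m.proteins, dtype=object))] = np.arange(n)
    profiles = []
    for i, prot in enumerate(m.proteins):
        row = m.scores[i].copy()
        row[i] = np.nan
        valid = np.isfinite(row)
        idx = np.nonzero(valid)[0]
        order = idx[np.lexsort((lex[idx], -row[idx]))][:k]
        ranked = [(m.proteins[j], float(row[j])) for j in order]
        profiles.append(InteractorProfile((m.dataset_id, prot), ranked))
    return profiles


def pairwise_interactor_similarity(
    ma: InteractionMatrix,
    mb: InteractionMatrix,
    mapping: dict[str, str] | None,
    params: RBOParams | None = None,
) -> ScoreTable:
    """RBO score for every (protein in A) x (protein in B) pair.

    ``mapping`` translates B identifiers into A's namespace; None is the
    identity map (same species). All scores are retained at this stage.
    """
    params = params or RBOParams()
    profs_a = dataset_profiles(ma, params)
    profs_b = dataset_profiles(mb, params)
    k = params.k
    na, nb = len(profs_a), len(profs_b)

    # inverted index: element -> (protein indices, ranks) per side; B ids are
    # translated into A's namespace, unmapped ones can never be common
    def invert(profiles, translate):
        occ: dict[str, tuple[list[int], list[int]]] = {}
        lengths = np.zeros(len(profiles), dtype=int)
        for i, prof in enumerate(profiles):
            prots = prof.proteins
            lengths[i] = len(prots)
            for r, prot in enumerate(prots, 1):
                if translate is not None:
                    prot = translate.get(prot)
                    if prot is None:
                        continue
                occ.setdefault(prot, ([], []))[0].append(i)
                occ[prot][1].append(r)
        return occ, lengths

    occ_a, len_a = invert(profs_a, None)
    occ_b, len_b = invert(profs_b, mapping)

    # score(a,b) = sum over common elements e of T_D(max(ra, rb)) with
    # T_D(m) = sum_{d=m..D} (1-p) p^(d-1) / d and D = min(k, max(la, lb)).
    # Using the global tail C(m) = T_k(m): T_D(m) = C(m) - C(D+1), so the
    # score is the C-weighted sum minus (common count) * C(D+1).
    c_tail = _tail_table(params.p, k)  # c_tail[m-1] = C(m); c_tail[k] = 0
    s1 = np.zeros((na, nb))
    counts = np.zeros((na, nb))
    for prot, (ia, ra) in occ_a.items():
        hit = occ_b.get(prot)
        if hit is None:
            continue
        ib, rb = hit
        ia = np.asarray(ia)
        ib = np.asarray(ib)
        maxr = np.maximum.outer(np.asarray(ra), np.asarray(rb))
        s1[np.ix_(ia, ib)] += c_tail[maxr - 1]
        counts[np.ix_(ia, ib)] += 1.0
    depth = np.minimum(k, np.maximum.outer(len_a, len_b))
    scores = s1 - counts * c_tail[depth]
    scores[scores < 0] = 0.0  # guard fp noise
    return ScoreTable((ma.dataset_id, mb.dataset_id),
                      list(ma.proteins), list(mb.proteins), scores)


def select_reciprocal_top_hits(table: ScoreTable,
                               fraction: float = 0.01) -> EdgeSet:
    """Keep edges whose score is a top hit for BOTH endpoints.

    A protein's top set against the opposite dataset holds its
    ceil(fraction * n_opposite) largest scores; ties at the cutoff value are
    kept. Scores of exactly 0 are never edges.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0,1], got {fraction}")
    s = table.scores
    na, nb = s.shape
    if na == 0 or nb == 0:
        return EdgeSet(table.dataset_pair, [])

    def row_thresholds(mat: np.ndarray) -> np.ndarray:
        c = min(math.ceil(fraction * mat.shape[1]), mat.shape[1])
        part = np.partition(mat, mat.shape[1] - c, axis=1)
        return part[:, mat.shape[1] - c]

    thr_a = row_thresholds(s)          # per protein of A, over its nb scores
    thr_b = row_thresholds(s.T)        # per protein of B, over its na scores
    keep = (s >= thr_a[:, None]) & (s >= thr_b[None, :]) & (s > 0)
    da, db = table.dataset_pair
    edges = [
        ((da, table.proteins_a[i]), (db, table.proteins_b[j]), float(s[i, j]))
        for i, j in zip(*np.nonzero(keep))
    ]
    return EdgeSet(table.dataset_pair, edges)


def normalize_pair_scores(edge_sets: list[EdgeSet]) -> list[EdgeSet]:
    """Scale each dataset pair's weights multiplicatively to mean 1.0.

    Empty edge sets pass through unchanged; a nonempty set with mean 0 is an
    error (weights are positive by construction, so this cannot normally
    happen).
    """
    out = []
    for es in edge_sets:
        if not es.edges:
            out.append(es)
            continue
        mean = float(es.weights.mean())
        if mean <= 0:
            raise ValidationError(
                f"edge set {es.dataset_pair} has mean weight 0; cannot "
                f"normalize"
            )
        out.append(es.rescaled(1.0 / mean))
    return out


def build_hypernetwork(edge_sets: list[EdgeSet],
                       all_elements: list[Element] | None = None,
                       ) -> HyperNetwork:
    """Union of normalized per-pair edges over the union of elements.

    Elements with no surviving edge are excluded from the network but listed
    in ``isolated`` when ``all_elements`` is provided.
    """
    seen_pairs: set[frozenset[Element]] = set()
    edges: list[tuple[Element, Element, float]] = []
    nodes: set[Element] = set()
    for es in edge_sets:
        for ea, eb, w in es.edges:
            key = frozenset((ea, eb))
            if key in seen_pairs:
                raise AssertionError(f"duplicate edge {ea}-{eb} across sets")
            seen_pairs.add(key)
            edges.append((ea, eb, w))
            nodes.add(ea)
            nodes.add(eb)
    isolated = []
    if all_elements is not None:
        isolated = sorted(set(all_elements) - nodes)
    return HyperNetwork(sorted(nodes), edges, isolated)
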