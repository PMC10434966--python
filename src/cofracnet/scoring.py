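"""Within-dataset interaction scoring and rank-biased overlap (RBO).

Each protein's *interactor profile* is the list of all other proteins in its
dataset ranked by interaction score (here Pearson correlation of migration
profiles), highest first. Two proteins — possibly from different datasets and
species — are compared by the top-weighted similarity of their interactor
profiles: the non-extrapolated rank-biased overlap

    RBO(a, b) = sum_{d=1..D} (1 - p) p^(d-1) * A_d,

where A_d is the fraction of the top-d prefixes shared (orthologous proteins
across species count as common elements) and p in (0, 1) sets the
top-heaviness. The sum is truncated at depth D: the smallest k whose ranks
cumulatively carry a given share of the total weight (99% by default),
further capped by list length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import InteractionMatrix, ProfileDataset, ValidationError

__all__ = [
    "InteractorProfile",
    "RBOParams",
    "correlation_matrix",
    "rank_interactors",
    "rbo_depth",
    "rbo_score",
]


@dataclass
class InteractorProfile:
    """Ranked interactors of one protein within one dataset.

    ``ranked`` is ordered by score descending with ties broken by identifier
    (lexicographic ascending); the owner protein itself is excluded, as are
    pairs with undefined scores (e.g. zero-variance profiles).
    """

    owner: tuple[str, str]
    ranked: list[tuple[str, float]]

    @property
    def proteins(self) -> list[str]:
        return [p for p, _ in self.ranked]


@dataclass
class RBOParams:
    """Tunable RBO parameters.

    p : top-heaviness, in (0, 1). The default 0.9 gives the best ranking of
        true co-complex pairs on complexome-profiling data.
    coverage : share of the total rank weight retained when choosing the
        evaluation depth; default 0.99.
    depth : explicit depth override; when None the depth implied by
        ``coverage`` is used.
    """

    p: float = 0.9
    coverage: float = 0.99
    depth: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValidationError(f"p must be in (0,1), got {self.p}")
        if not 0.0 < self.coverage < 1.0:
            raise ValidationError(
                f"coverage must be in (0,1), got {self.coverage}"
            )
        if self.depth is not None and self.depth < 1:
            raise ValidationError(f"depth must be >=1, got {self.depth}")

    @property
    def k(self) -> int:
        return self.depth if self.depth is not None else rbo_depth(
            self.p, self.coverage)


def correlation_matrix(ds: ProfileDataset) -> InteractionMatrix:
    """Pearson correlation between all protein pairs of one dataset.

    Rows with zero variance yield undefined correlations, stored as NaN and
    excluded from rankings downstream.
    """
    if ds.n_fractions < 2:
        raise ValidationError(
            f"{ds.dataset_id}: correlation needs >=2 fractions"
        )
    x = ds.abundances
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.asarray(r, dtype=float)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    r = (r + r.T) / 2.0  # enforce exact symmetry against fp noise
    np.fill_diagonal(r, np.nan)
    return InteractionMatrix(ds.dataset_id, ds.collection_id, ds.species_id,
                             ds.proteins, r)


def rank_interactors(m: InteractionMatrix, protein: str) -> InteractorProfile:
    """Full ranking of all other proteins by score, highest first."""
    idx = m.index
    if protein not in idx:
        raise KeyError(f"{protein!r} not in dataset {m.dataset_id}")
    i = idx[protein]
    entries = [
        (m.proteins[j], m.scores[i, j])
        for j in range(len(m.proteins))
        if j != i and np.isfinite(m.scores[i, j])
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return InteractorProfile((m.dataset_id, protein), entries)


def rbo_depth(p: float, coverage: float) -> int:
    """Smallest depth k whose ranks carry >= ``coverage`` of the RBO weight.

    Rank d has weight (1-p) p^(d-1), so ranks 1..k carry 1 - p^k; the result
    is the smallest k with 1 - p^k >= coverage.
    """
    if not 0.0 < p < 1.0 or not 0.0 < coverage < 1.0:
        raise ValidationError("p and coverage must lie in (0,1)")
    k = math.ceil(math.log(1.0 - coverage) / math.log(p))
    # guard against fp edge cases of the closed form
    while 1.0 - p ** k < coverage:
        k += 1
    while k > 1 and 1.0 - p ** (k - 1) >= coverage:
        k -= 1
    return max(k, 1)


def _tail_table(p: float, depth: int) -> np.ndarray:
    """T[m] = sum_{d=m..depth} (1-p) p^(d-1) / d for m in 1..depth.

    An element common to both prefixes from rank m onward contributes T[m] to
    the truncated weighted-agreement sum.
    """
    d = np.arange(1, depth + 1, dtype=float)
    w = (1.0 - p) * p ** (d - 1.0) / d
    tail = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    return tail  # tail[m-1] == T(m); tail[depth] == 0


def rbo_score(a: InteractorProfile | list[str],
              b: InteractorProfile | list[str],
              params: RBOParams | None = None,
              mapping: dict[str, str] | None = None) -> float:
    """Non-extrapolated RBO between two ranked lists.

    Parameters
    ----------
    a, b
        Interactor profiles or plain ranked identifier lists.
    params
        RBO parameters; defaults to p=0.9, coverage=0.99.
    mapping
        Identifier mapping from b's namespace into a's (one-to-one
        orthology); None means identity (same namespace). Unmapped elements
        are unique to their list.

    The weighted-agreement sum is truncated at
    D = min(k, max(len(a), len(b))); for identical lists of length L < k the
    score is exactly 1 - p^L.
    """
    params = params or RBOParams()
    la = a.proteins if isinstance(a, InteractorProfile) else list(a)
    lb = b.proteins if isinstance(b, InteractorProfile) else list(b)
    k = params.k
    la = la[:k]
    lb = lb[:k]
    if not la or not lb:
        return 0.0
    depth = min(k, max(len(la), len(lb)))
    tail = _tail_table(params.p, depth)
    rank_a = {prot: r for r, prot in enumerate(la, 1)}
    score = 0.0
    for rb, prot in enumerate(lb, 1):
        if mapping is not None:
            prot = mapping.get(prot)
            if prot is None:
                continue
        ra = rank_a.get(prot)
        if ra is not None:
            score += tail[max(ra, rb) - 1]
    return float(score)
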