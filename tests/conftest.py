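import numpy as np
import pytest

from cofracnet import (
    Collection,
    InteractionMatrix,
    OrthologyMap,
    ProfileDataset,
)
from cofracnet.postprocess import EquivalenceIndex


def brute_rbo(list_a, list_b, p, k, mapping=None):
    """Independent prefix-overlap oracle for the truncated RBO sum."""
    la, lb = list(list_a)[:k], list(list_b)[:k]
    if not la or not lb:
        return 0.0
    depth = min(k, max(len(la), len(lb)))
    total = 0.0
    for d in range(1, depth + 1):
        a = set(la[:d])
        b = set(lb[:d])
        if mapping is not None:
            b = {mapping.get(x) for x in b} - {None}
        total += (1 - p) * p ** (d - 1) * len(a & b) / d
    return total


def symmetric_matrix(rng, proteins, dataset_id="d", collection_id="c",
                     species_id="s"):
    n = len(proteins)
    raw = rng.uniform(-1, 1, (n, n))
    sym = (raw + raw.T) / 2
    np.fill_diagonal(sym, np.nan)
    return InteractionMatrix(dataset_id, collection_id, species_id,
                             list(proteins), sym)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_profiles():
    """Two tiny datasets of one species sharing a namespace."""
    x = np.array([
        [1.0, 5.0, 9.0, 5.0, 1.0],
        [2.0, 10.0, 18.0, 10.0, 2.0],
        [9.0, 5.0, 1.0, 0.0, 0.0],
        [0.0, 1.0, 2.0, 8.0, 9.0],
    ])
    rng = np.random.default_rng(7)
    ds1 = ProfileDataset("hs_r1", "hs", "human", ["P1", "P2", "P3", "P4"], x)
    ds2 = ProfileDataset("hs_r2", "hs", "human", ["P1", "P2", "P3", "P4"],
                         x * np.exp(rng.normal(0, 0.05, x.shape)))
    return [ds1, ds2]


@pytest.fixture
def two_species_meta():
    collections = {
        "hs": Collection("hs", "human", ["hs_r1", "hs_r2"]),
        "yl": Collection("yl", "yeast", ["yl_r1", "yl_r2"]),
    }
    ortho = OrthologyMap(("human", "yeast"),
                         {("P1", "yP1"), ("P2", "yP2"), ("P3", "yP3")})
    equiv = EquivalenceIndex(
        dataset_species={"hs_r1": "human", "hs_r2": "human",
                         "yl_r1": "yeast", "yl_r2": "yeast"},
        dataset_collection={"hs_r1": "hs", "hs_r2": "hs",
                            "yl_r1": "yl", "yl_r2": "yl"},
        collection_species={"hs": "human", "yl": "yeast"},
        orthologies=[ortho],
    )
    return collections, ortho, equiv
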