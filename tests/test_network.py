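import math

import numpy as np
import pytest

from cofracnet import (
    RBOParams,
    build_hypernetwork,
    normalize_pair_scores,
    pairwise_interactor_similarity,
    rank_interactors,
    rbo_score,
    select_reciprocal_top_hits,
)
from cofracnet.network import ScoreTable, dataset_profiles
from cofracnet.types import EdgeSet
from conftest import symmetric_matrix


class TestPairwiseSimilarity:
    def test_table_equals_elementwise_rbo_loop(self, rng):
        ma = symmetric_matrix(rng, ["A", "B", "C", "D"], "d1", "c1", "hum")
        mb = symmetric_matrix(rng, ["yA", "yB", "yC"], "d2", "c2", "yst")
        mapping = {"yA": "A", "yB": "B"}  # yC has no ortholog
        params = RBOParams(p=0.8, coverage=0.95)
        table = pairwise_interactor_similarity(ma, mb, mapping, params)
        k = params.k
        for i, pa in enumerate(ma.proteins):
            prof_a = rank_interactors(ma, pa).proteins[:min(k, 3)]
            for j, pb in enumerate(mb.proteins):
                prof_b = rank_interactors(mb, pb).proteins[:min(k, 2)]
                expected = rbo_score(prof_a, prof_b, params, mapping=mapping)
                assert table.scores[i, j] == pytest.approx(expected,
                                                           abs=1e-12)

    def test_self_comparison_diagonal_is_row_maximum(self, rng):
        m = symmetric_matrix(rng, [f"P{i}" for i in range(8)])
        table = pairwise_interactor_similarity(m, m, None, RBOParams())
        for i in range(8):
            assert table.scores[i, i] == pytest.approx(table.scores[i].max())

    def test_no_orthologous_interactors_gives_all_zero(self, rng):
        ma = symmetric_matrix(rng, ["A", "B", "C"], "d1", "c1", "hum")
        mb = symmetric_matrix(rng, ["x", "y", "z"], "d2", "c2", "yst")
        table = pairwise_interactor_similarity(ma, mb, {}, RBOParams())
        assert np.all(table.scores == 0)

    def test_truncated_profiles_match_full_ranking(self, rng):
        m = symmetric_matrix(rng, [f"P{i}" for i in range(10)])
        params = RBOParams(p=0.5, coverage=0.9)
        for prof in dataset_profiles(m, params):
            full = rank_interactors(m, prof.owner[1])
            assert prof.ranked == full.ranked[:min(params.k, 9)]


class TestReciprocalTopHits:
    @staticmethod
    def _oracle(scores, fraction):
        """Brute-force: keep (i,j) iff mutually within each other's top set."""
        na, nb = scores.shape
        ca = math.ceil(fraction * nb)
        cb = math.ceil(fraction * na)
        kept = set()
        for i in range(na):
            row_cut = sorted(scores[i], reverse=True)[ca - 1]
            for j in range(nb):
                col_cut = sorted(scores[:, j], reverse=True)[cb - 1]
                s = scores[i, j]
                if s > 0 and s >= row_cut and s >= col_cut:
                    kept.add((i, j))
        return kept

    def test_matches_brute_force_oracle(self, rng):
        scores = rng.uniform(0, 1, (60, 45))
        scores[scores < 0.2] = 0.0
        table = ScoreTable(("d1", "d2"),
                           [f"a{i}" for i in range(60)],
                           [f"b{j}" for j in range(45)], scores)
        for fraction in (0.05, 0.1, 1.0):
            es = select_reciprocal_top_hits(table, fraction)
            got = {(int(ea[1][1:]), int(eb[1][1:]))
                   for ea, eb, _ in es.edges}
            assert got == self._oracle(scores, fraction)

    def test_fraction_one_keeps_all_positive_pairs(self, rng):
        scores = rng.uniform(0, 1, (10, 10))
        scores[0, :] = 0.0
        table = ScoreTable(("d1", "d2"),
                           [f"a{i}" for i in range(10)],
                           [f"b{j}" for j in range(10)], scores)
        es = select_reciprocal_top_hits(table, 1.0)
        assert len(es.edges) == int((scores > 0).sum())

    def test_non_mutual_best_hit_is_dropped(self):
        # X's best hit is Y, but X is not among Y's top scores
        scores = np.array([
            [0.9, 0.0],    # X: best hit is Y (col 0)
            [0.95, 0.0],   # another protein outranks X for Y
            [0.96, 0.5],
        ])
        table = ScoreTable(("d1", "d2"), ["X", "W", "V"], ["Y", "Z"], scores)
        es = select_reciprocal_top_hits(table, 0.5)  # top-1 per side
        pairs = {(ea[1], eb[1]) for ea, eb, _ in es.edges}
        assert ("X", "Y") not in pairs

    def test_symmetric_under_dataset_swap(self, rng):
        scores = rng.uniform(0, 1, (30, 20))
        ta = ScoreTable(("d1", "d2"), [f"a{i}" for i in range(30)],
                        [f"b{j}" for j in range(20)], scores)
        tb = ScoreTable(("d2", "d1"), [f"b{j}" for j in range(20)],
                        [f"a{i}" for i in range(30)], scores.T)
        ea = {frozenset((x, y)) for x, y, _ in
              select_reciprocal_top_hits(ta, 0.1).edges}
        eb = {frozenset((x, y)) for x, y, _ in
              select_reciprocal_top_hits(tb, 0.1).edges}
        assert ea == eb


class TestNormalization:
    def test_scales_to_unit_mean(self):
        es = EdgeSet(("d1", "d2"), [(("d1", "A"), ("d2", "B"), 2.0),
                                    (("d1", "C"), ("d2", "D"), 4.0)])
        out, = normalize_pair_scores([es])
        np.testing.assert_allclose(out.weights, [2 / 3, 4 / 3])

    def test_all_means_equal_one_and_idempotent(self, rng):
        sets = []
        for pair in (("d1", "d2"), ("d1", "d3"), ("d2", "d3")):
            n = int(rng.integers(3, 20))
            sets.append(EdgeSet(pair, [
                ((pair[0], f"p{i}"), (pair[1], f"q{i}"),
                 float(rng.uniform(0.01, 5)))
                for i in range(n)]))
        out = normalize_pair_scores(sets)
        for es in out:
            assert es.weights.mean() == pytest.approx(1.0, abs=1e-9)
        again = normalize_pair_scores(out)
        for a, b in zip(out, again):
            np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)
        # relative order preserved
        for before, after in zip(sets, out):
            assert (np.argsort(before.weights)
                    == np.argsort(after.weights)).all()


class TestBuildHypernetwork:
    def test_disjoint_sets_give_disconnected_components(self):
        es1 = EdgeSet(("d1", "d2"), [(("d1", "A"), ("d2", "A"), 1.0)])
        es2 = EdgeSet(("d3", "d4"), [(("d3", "B"), ("d4", "B"), 1.0)])
        net = build_hypernetwork([es1, es2])
        assert net.n_nodes == 4 and net.n_edges == 2

    def test_duplicate_edge_triggers_invariant_guard(self):
        e = (("d1", "A"), ("d2", "A"), 1.0)
        with pytest.raises(AssertionError):
            build_hypernetwork([EdgeSet(("d1", "d2"), [e]),
                                EdgeSet(("d1", "d2"), [e])])

    def test_counts_match_hand_enumeration_and_isolated_reported(self):
        sets = [
            EdgeSet(("d1", "d2"), [(("d1", "A"), ("d2", "A"), 1.0),
                                   (("d1", "B"), ("d2", "B"), 2.0)]),
            EdgeSet(("d1", "d3"), [(("d1", "A"), ("d3", "A"), 1.0)]),
            EdgeSet(("d2", "d3"), [(("d2", "A"), ("d3", "A"), 0.5)]),
        ]
        everything = [(d, p) for d in ("d1", "d2", "d3")
                      for p in ("A", "B", "C")]
        net = build_hypernetwork(sets, everything)
        assert net.n_nodes == 5       # A in 3 datasets, B in 2
        assert net.n_edges == 4
        assert ("d3", "B") in net.isolated and ("d1", "C") in net.isolated
        assert len(net.isolated) == 4
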