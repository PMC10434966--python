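import pytest

from cofracnet import (
    Collection,
    ReferenceComplexSet,
    SubCluster,
    SuperCluster,
    best_guess_selection,
    coherence_score,
    count_matches,
    filter_clusters,
    fraction_clustered,
    split_superclusters,
)
from cofracnet.postprocess import annotate_with_reference, subcluster_coherence


@pytest.fixture
def equiv(two_species_meta):
    return two_species_meta[2]


class TestSplitAndFrC:
    def test_split_by_collection(self, equiv):
        cluster = {("hs_r1", "P1"), ("hs_r2", "P1"), ("yl_r1", "yP1"),
                   ("yl_r2", "yP2"), ("hs_r1", "P2")}
        parts = split_superclusters(cluster, equiv)
        assert set(parts) == {"hs", "yl"}
        assert len(parts["hs"]) == 3 and len(parts["yl"]) == 2
        assert sum(len(v) for v in parts.values()) == len(cluster)

    def test_unknown_dataset_rejected(self, equiv):
        with pytest.raises(Exception, match="unknown"):
            split_superclusters({("bogus", "P1")}, equiv)

    def test_frc_denominator_is_total_dataset_count(self):
        coll = Collection("c", "s", ["d1", "d2", "d3", "d4"])
        elements = {("d1", "P"), ("d2", "P"), ("d3", "P"), ("d1", "Q")}
        frc = fraction_clustered(elements, coll)
        assert frc["P"] == pytest.approx(3 / 4)   # 3 of 4 datasets
        assert frc["Q"] == pytest.approx(1 / 4)   # detection count ignored
        full = {(d, "R") for d in coll.dataset_ids}
        assert fraction_clustered(full, coll)["R"] == 1.0

    def test_frc_values_are_rationals_over_n(self):
        coll = Collection("c", "s", ["d1", "d2", "d3"])
        elements = {("d1", "P"), ("d2", "P"), ("d3", "Q")}
        for frc in fraction_clustered(elements, coll).values():
            assert (frc * coll.n_datasets) == int(frc * coll.n_datasets)
            assert 0 < frc <= 1


class TestMatchesAndCoherence:
    def test_same_species_pair(self, equiv):
        elements = {("hs_r1", "P1"), ("hs_r1", "P2"),
                    ("hs_r2", "P1"), ("hs_r2", "P3")}
        actual, possible, per_pair = count_matches(elements, equiv)
        assert (actual, possible) == (1, 2)
        assert per_pair[("hs_r1", "hs_r2")] == (1, 2)

    def test_cross_species_via_orthology(self, equiv):
        elements = {("hs_r1", "P1"), ("hs_r1", "P2"), ("hs_r1", "P4"),
                    ("yl_r1", "yP1"), ("yl_r1", "yP2")}
        actual, possible, per_pair = count_matches(elements, equiv)
        # P1-yP1 and P2-yP2 are orthologous; P4 has no ortholog
        assert per_pair[("hs_r1", "yl_r1")] == (2, 2)
        assert actual == 2 and possible == 2

    def test_multi_dataset_enumeration(self, equiv):
        elements = {
            ("hs_r1", "P1"), ("hs_r1", "P2"),
            ("hs_r2", "P1"),
            ("yl_r1", "yP1"), ("yl_r1", "yP3"),
            ("yl_r2", "yP2"),
        }
        actual, possible, per_pair = count_matches(elements, equiv)
        expected = {
            ("hs_r1", "hs_r2"): (1, 1),
            ("hs_r1", "yl_r1"): (1, 2),
            ("hs_r1", "yl_r2"): (1, 1),
            ("hs_r2", "yl_r1"): (1, 1),
            ("hs_r2", "yl_r2"): (0, 1),
            ("yl_r1", "yl_r2"): (0, 1),
        }
        assert per_pair == expected
        assert actual == sum(a for a, _ in expected.values())
        assert possible == sum(p for _, p in expected.values())
        for a, p in per_pair.values():
            assert a <= p

    def test_coherence_ratio(self):
        assert coherence_score(46, 71) == pytest.approx(0.648, abs=5e-4)
        assert coherence_score(0, 5) == 0.0
        assert coherence_score(5, 5) == 1.0
        assert coherence_score(0, 0) == 0.0

    def test_subcluster_coherence_restricted_to_collection_pairs(self, equiv):
        per_pair = {
            ("hs_r1", "hs_r2"): (1, 2),
            ("hs_r1", "yl_r1"): (2, 2),
            ("yl_r1", "yl_r2"): (0, 3),
        }
        hs = Collection("hs", "human", ["hs_r1", "hs_r2"])
        yl = Collection("yl", "yeast", ["yl_r1", "yl_r2"])
        assert subcluster_coherence(per_pair, hs) == pytest.approx(3 / 4)
        assert subcluster_coherence(per_pair, yl) == pytest.approx(2 / 5)
        absent = Collection("zz", "other", ["z1"])
        assert subcluster_coherence(per_pair, absent) == 0.0


class TestBestGuess:
    def _super(self):
        sc = SuperCluster(1, set())
        sc.subclusters["hs"] = SubCluster("hs", {"P1": 0.75, "P2": 0.25,
                                                 "P4": 0.25})
        sc.subclusters["yl"] = SubCluster("yl", {"yP2": 1.0, "yP3": 0.5})
        return sc

    def test_threshold_and_ortholog_rescue(self, equiv):
        sc = self._super()
        best_guess_selection(sc, equiv, threshold=0.5)
        # P1 above threshold; P2 rescued by ortholog yP2 at FrC 1.0;
        # P4 has no qualifying equivalent; yP3 at exactly 0.5 not rescued
        assert sc.subclusters["hs"].best_guess == {"P1", "P2"}
        assert sc.subclusters["yl"].best_guess == {"yP2"}

    def test_raising_threshold_never_adds_members(self, equiv):
        sc1, sc2 = self._super(), self._super()
        best_guess_selection(sc1, equiv, threshold=0.5)
        best_guess_selection(sc2, equiv, threshold=0.8)
        for cid in sc1.subclusters:
            assert (sc2.subclusters[cid].best_guess
                    <= sc1.subclusters[cid].best_guess)

    def test_same_identifier_rescue_across_collections_one_species(self):
        from cofracnet.postprocess import EquivalenceIndex
        equiv = EquivalenceIndex(
            dataset_species={"a1": "hum", "b1": "hum", "b2": "hum"},
            dataset_collection={"a1": "cA", "b1": "cB", "b2": "cB"},
            collection_species={"cA": "hum", "cB": "hum"},
        )
        sc = SuperCluster(1, set())
        sc.subclusters["cA"] = SubCluster("cA", {"P1": 1.0})
        sc.subclusters["cB"] = SubCluster("cB", {"P1": 0.5})
        best_guess_selection(sc, equiv, threshold=0.5)
        assert sc.subclusters["cB"].best_guess == {"P1"}


class TestFilterAndAnnotation:
    @pytest.mark.parametrize("matches,max_frc,expected", [
        (1, 1.0, False),    # too few matches
        (3, 0.25, False),   # no protein at FrC >= 0.5
        (2, 0.5, True),     # both thresholds inclusive
    ])
    def test_filter_rule(self, matches, max_frc, expected):
        sc = SuperCluster(1, set())
        sc.actual_matches = matches
        sc.subclusters["c"] = SubCluster("c", {"P": max_frc})
        filter_clusters([sc])
        assert sc.passed_filter is expected

    def _clusters(self, member_sets):
        out = []
        for i, members in enumerate(member_sets, 1):
            sc = SuperCluster(i, set())
            sc.subclusters["hs"] = SubCluster(
                "hs", {p: 1.0 for p in members})
            out.append(sc)
        return out

    def test_strict_majority_required(self):
        ref = ReferenceComplexSet(
            {"big": frozenset(f"P{i}" for i in range(10))})
        six = self._clusters([{f"P{i}" for i in range(6)}])
        assert annotate_with_reference(six, ref, "hs") == {"big": 1}
        assert six[0].annotation == "big"
        five = self._clusters([{f"P{i}" for i in range(5)}])
        assert annotate_with_reference(five, ref, "hs") == {}
        assert five[0].annotation is None

    def test_absent_complex_and_tie_breaks(self):
        ref = ReferenceComplexSet({
            "gone": frozenset({"Z1", "Z2", "Z3"}),
            "cplx": frozenset({"P1", "P2", "P3"}),
        })
        clusters = self._clusters([
            {"P1", "P2", "Q1", "Q2"},        # 2 members, size 4
            {"P1", "P2"},                    # 2 members, size 2 -> preferred
            {"P3"},
        ])
        assignment = annotate_with_reference(clusters, ref, "hs")
        assert assignment == {"cplx": 2}
        assert "gone" not in assignment

    def test_each_complex_assigned_at_most_once(self):
        ref = ReferenceComplexSet({
            "a": frozenset({"P1", "P2", "P3"}),
            "b": frozenset({"P1", "P2", "P4"}),
        })
        clusters = self._clusters([{"P1", "P2", "P3", "P4"}])
        assignment = annotate_with_reference(clusters, ref, "hs")
        assert set(assignment.values()) == {1}
        assert clusters[0].annotation == "a;b"
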