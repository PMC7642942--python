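"""Linkage-group graphs: orientation regression, node collapsing, maximal
consistent marker subsets (with an exhaustive oracle) and intra-LG splits."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from chromanchor.datamodel import FORWARD, REVERSE, UNORIENTED
from chromanchor.lg_graph import (
    build_lg_graph,
    consistent_marker_set,
    finalize_orientation,
    provisional_orientation,
    split_intra_lg,
)

from conftest import make_hits, make_scaffold


def hits_from_pairs(pairs, sid="s1", lg="LG1"):
    return make_hits(sid, *[(f"m{i}", lg, cm, bp) for i, (cm, bp) in enumerate(pairs)])


class TestProvisionalOrientation:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(0, 100), (1, 200), (2, 300)], FORWARD),
            ([(0, 300), (1, 200), (2, 100)], REVERSE),
            ([(4.5, 100), (4.5, 900)], UNORIENTED),  # one cM position only
            ([(0, 100)], UNORIENTED),
        ],
    )
    def test_regression_sign(self, pairs, expected):
        call = provisional_orientation(hits_from_pairs(pairs))
        assert call.orientation == expected

    def test_unoriented_iff_degenerate(self):
        call = provisional_orientation(hits_from_pairs([(0, 100), (1, 200)]))
        assert call.n_cm_positions == 2 and call.slope > 0


class TestGraph:
    def test_consecutive_nodes_collapse_into_one_placement(self):
        hits = {"s1": hits_from_pairs([(1.0, 100), (1.5, 200), (2.0, 300)])}
        graph = build_lg_graph("LG1", hits)
        assert [n.cm for n in graph.nodes] == [1.0, 1.5, 2.0]
        (p,) = graph.placements
        assert [n.cm for n in p.nodes] == [1.0, 1.5, 2.0]

    def test_non_consecutive_anchors_yield_two_placements(self):
        hits = {
            "s1": hits_from_pairs([(1.0, 100), (9.0, 5000)]),
            "s2": hits_from_pairs([(5.0, 100), (5.5, 200)], sid="s2"),
        }
        graph = build_lg_graph("LG1", hits)
        assert len(graph.placements_of("s1")) == 2
        assert len(graph.placements_of("s2")) == 1

    def test_two_scaffolds_share_one_node(self):
        hits = {
            "s1": hits_from_pairs([(3.0, 100)]),
            "s2": hits_from_pairs([(3.0, 50)], sid="s2"),
        }
        graph = build_lg_graph("LG1", hits)
        (node,) = graph.nodes
        assert len(node.anchors) == 2
        assert all(p.orientation == UNORIENTED for p in graph.placements)


def brute_force_max_consistent(cms, decreasing=False):
    """Largest subset whose cM sequence is monotone (ties allowed)."""
    best = 0
    for r in range(len(cms), 0, -1):
        for combo in itertools.combinations(range(len(cms)), r):
            vals = [cms[i] for i in combo]
            pairs = zip(vals, vals[1:])
            ok = all(b <= a for a, b in pairs) if decreasing else all(a <= b for a, b in zip(vals, vals[1:]))
            if ok:
                return r
    return best


class TestConsistentMarkerSet:
    def _placement(self, cms, orientation):
        hits = {"s1": hits_from_pairs([(cm, 100 * (i + 1)) for i, cm in enumerate(cms)])}
        graph = build_lg_graph("LG1", hits)
        placements = graph.placements_of("s1")
        merged = placements[0]
        # force a single placement carrying all markers for the test
        merged.retained_markers = [h for p in placements for h in p.retained_markers]
        merged.orientation = orientation
        return merged

    @pytest.mark.parametrize(
        "cms,orientation,expected_kept",
        [
            ([1, 3, 2, 4], FORWARD, 3),  # brute force over 2^4 subsets gives 3
            ([5, 5, 5], FORWARD, 3),  # single node: ties always consistent
            ([4, 3, 2, 1], REVERSE, 4),
            ([4, 3, 2, 1], UNORIENTED, 4),  # both directions tried, reverse wins
        ],
    )
    def test_examples(self, cms, orientation, expected_kept):
        p = self._placement(cms, orientation)
        consistent_marker_set(p)
        assert len(p.retained_markers) == expected_kept
        assert all(reason == "order conflict" for _, _, reason in p.discarded_markers)

    def test_lexicographically_earliest_optimum_kept(self):
        # [2,1,3]: {2,3} and {1,3} are both optimal; earliest by bp keeps m0
        p = self._placement([2, 1, 3], FORWARD)
        consistent_marker_set(p)
        assert [m.id for m, _ in p.retained_markers] == ["m0", "m2"]

    @given(st.lists(st.integers(0, 6), min_size=1, max_size=10))
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_optimum(self, cms):
        for orientation in (FORWARD, REVERSE):
            p = self._placement([float(c) for c in cms], orientation)
            consistent_marker_set(p)
            assert len(p.retained_markers) == brute_force_max_consistent(
                cms, decreasing=orientation == REVERSE
            )


class TestIntraSplit:
    def _graph_and_scaffolds(self, scaffold, hit_groups):
        hits = {"s1": [h for g in hit_groups for h in g]}
        graph = build_lg_graph("LG1", hits)
        for p in graph.placements:
            consistent_marker_set(p)
        scaffolds = {"s1": scaffold}
        return graph, scaffolds

    def test_split_at_gap_between_placements(self):
        scaffold = make_scaffold("c:30000 g:1000 c:30000")
        near = hits_from_pairs([(1.0, 10_000), (1.5, 15_000), (2.0, 20_000)])
        far = hits_from_pairs([(8.0, 50_000), (8.5, 55_000), (9.0, 60_000)])
        # another scaffold occupies the intervening nodes
        other = hits_from_pairs([(5.0, 100), (5.5, 200)], sid="s2")
        graph = build_lg_graph("LG1", {"s1": near + far, "s2": other})
        for p in graph.placements:
            consistent_marker_set(p)
        scaffolds = {"s1": scaffold, "s2": make_scaffold("c:1000", "s2")}
        records, discards = split_intra_lg(graph, scaffolds)
        assert [r.origin_bp for r in records] == [30_000]
        assert sorted(scaffolds) == ["s1__1", "s1__2", "s2"]
        ids = {p.scaffold_id for p in graph.placements}
        assert ids == {"s1__1", "s1__2", "s2"}
        assert discards == {}

    def test_gapless_conflict_discards_smaller_placement(self):
        scaffold = make_scaffold("c:70000")
        near = hits_from_pairs([(1.0, 10_000), (1.5, 15_000), (2.0, 20_000)])
        far = hits_from_pairs([(8.0, 50_000), (8.5, 55_000)])
        other = hits_from_pairs([(5.0, 100), (5.5, 200)], sid="s2")
        graph = build_lg_graph("LG1", {"s1": near + far, "s2": other})
        for p in graph.placements:
            consistent_marker_set(p)
        scaffolds = {"s1": scaffold, "s2": make_scaffold("c:1000", "s2")}
        records, discards = split_intra_lg(graph, scaffolds)
        assert records == []
        assert len(graph.placements_of("s1")) == 1  # placed once, unsplit
        assert [m.id for m, _, _ in discards["s1"]] == ["m0", "m1"]  # the far pair

    def test_monotone_retained_series_after_split(self):
        scaffold = make_scaffold("c:30000 g:1000 c:30000")
        near = hits_from_pairs([(1.0, 10_000), (2.0, 20_000)])
        far = hits_from_pairs([(9.0, 50_000), (8.0, 60_000)])  # reverse-ordered block
        other = hits_from_pairs([(5.0, 100), (5.5, 200)], sid="s2")
        graph = build_lg_graph("LG1", {"s1": near + far, "s2": other})
        for p in graph.placements:
            consistent_marker_set(p)
        scaffolds = {"s1": scaffold, "s2": make_scaffold("c:1000", "s2")}
        split_intra_lg(graph, scaffolds)
        finalize_orientation(graph)
        for p in graph.placements:
            cms = [m.cm for m, _ in p.retained_markers]
            if p.orientation == REVERSE:
                assert cms == sorted(cms, reverse=True)
            else:
                assert cms == sorted(cms)


class TestFinalizeOrientation:
    def test_regression_on_retained_markers(self):
        graph = build_lg_graph("LG1", {"s1": hits_from_pairs([(0.0, 100), (2.0, 900)])})
        for p in graph.placements:
            consistent_marker_set(p)
        finalize_orientation(graph)
        (p,) = graph.placements
        assert p.orientation == FORWARD and p.definitive

    def test_single_node_placement_stays_unoriented(self):
        graph = build_lg_graph("LG1", {"s1": hits_from_pairs([(1.0, 100), (1.0, 500)])})
        finalize_orientation(graph)
        (p,) = graph.placements
        assert p.orientation == UNORIENTED and not p.definitive
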