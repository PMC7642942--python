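"""Inter-linkage-group conflict resolution: bucketing, run partitioning and
chimera splitting, with a brute-force oracle over discard choices."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from chromanchor.inter_lg import (
    bucket_markers_by_lg,
    partition_into_runs,
    split_inter_lg,
)

from conftest import make_hits, make_scaffold


class TestBuckets:
    def test_buckets_grouped_and_bp_sorted(self):
        hits = make_hits(
            "s1", ("m2", "LG1", 1.0, 500), ("m1", "LG1", 0.0, 100), ("m3", "LG2", 0.0, 900)
        )
        buckets = bucket_markers_by_lg(hits)
        assert {b.linkage_group: [m.id for m, _ in b.hits] for b in buckets} == {
            "LG1": ["m1", "m2"],
            "LG2": ["m3"],
        }

    def test_no_markers_gives_no_buckets(self):
        assert bucket_markers_by_lg([]) == []


class TestRuns:
    @pytest.mark.parametrize(
        "lgs,expected",
        [
            (["LG1", "LG1", "LG2", "LG2"], 2),
            (["LG1", "LG2", "LG1"], 3),
            (["LG1", "LG1", "LG1"], 1),
        ],
    )
    def test_run_counts(self, lgs, expected):
        hits = make_hits(
            "s1", *[(f"m{i}", lg, float(i), 100 * (i + 1)) for i, lg in enumerate(lgs)]
        )
        runs = partition_into_runs(bucket_markers_by_lg(hits))
        assert len(runs) == expected
        for a, b in zip(runs, runs[1:]):
            assert a.linkage_group != b.linkage_group

    @given(st.lists(st.sampled_from(["LG1", "LG2", "LG3"]), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_runs_match_naive_segmentation(self, lgs):
        hits = make_hits(
            "s1", *[(f"m{i}", lg, float(i), 10 * (i + 1)) for i, lg in enumerate(lgs)]
        )
        runs = partition_into_runs(bucket_markers_by_lg(hits))
        naive = [lg for lg, _ in itertools.groupby(lgs)]
        assert [r.linkage_group for r in runs] == naive
        assert sum(r.n for r in runs) == len(lgs)


class TestSplit:
    def test_split_at_gap_between_runs(self):
        scaf = make_scaffold("c:1000 g:500 c:1000")
        hits = make_hits(
            "s1",
            ("a1", "LG1", 0.0, 100), ("a2", "LG1", 1.0, 600),
            ("b1", "LG2", 0.0, 1600), ("b2", "LG2", 1.0, 2000), ("b3", "LG2", 2.0, 2300),
        )
        runs = partition_into_runs(bucket_markers_by_lg(hits))
        frags, frag_hits, discarded, records = split_inter_lg(scaf, runs)
        assert [f.id for f in frags] == ["s1__1", "s1__2"]
        assert discarded == []
        assert records[0].origin_bp == 1000
        # marker positions remapped into fragment coordinates
        assert [a.position for _, a in frag_hits["s1__2"]] == [100, 500, 800]

    def test_largest_gap_chosen(self):
        scaf = make_scaffold("c:1000 g:200 c:500 g:800 c:1000")
        hits = make_hits(
            "s1",
            ("a1", "LG1", 0.0, 100), ("a2", "LG1", 1.0, 500),
            ("b1", "LG2", 0.0, 2600), ("b2", "LG2", 1.0, 3000),
        )
        runs = partition_into_runs(bucket_markers_by_lg(hits))
        _, _, _, records = split_inter_lg(scaf, runs)
        assert records[0].origin_bp == 1700  # the 800 bp gap, not the 200 bp one

    def test_gapless_minority_run_discarded(self):
        scaf = make_scaffold("c:3000")
        hits = make_hits(
            "s1",
            *[(f"a{i}", "LG1", float(i), 100 + 200 * i) for i in range(5)],
            ("b1", "LG2", 0.0, 2500),
        )
        runs = partition_into_runs(bucket_markers_by_lg(hits))
        frags, frag_hits, discarded, records = split_inter_lg(scaf, runs)
        assert [f.id for f in frags] == ["s1"] and records == []
        assert [(m.id, reason) for m, _, reason in discarded] == [
            ("b1", "inter-LG conflict, insufficient support")
        ]
        assert len(frag_hits["s1"]) == 5

    def test_single_marker_run_never_forces_split_even_with_gap(self):
        scaf = make_scaffold("c:1000 g:100 c:1000")
        hits = make_hits(
            "s1",
            ("a1", "LG1", 0.0, 100), ("a2", "LG1", 1.0, 900),
            ("b1", "LG2", 0.0, 1500),
        )
        runs = partition_into_runs(bucket_markers_by_lg(hits))
        frags, _, discarded, records = split_inter_lg(scaf, runs)
        assert len(frags) == 1 and records == []
        assert [m.id for m, _, _ in discarded] == ["b1"]

    def test_post_condition_single_lg_per_fragment(self):
        scaf = make_scaffold("c:500 g:50 c:500 g:50 c:500")
        hits = make_hits(
            "s1",
            ("a1", "LG1", 0.0, 100), ("a2", "LG1", 1.0, 400),
            ("b1", "LG2", 0.0, 650), ("b2", "LG2", 1.0, 1000),
            ("c1", "LG3", 0.0, 1200), ("c2", "LG3", 1.0, 1500),
        )
        runs = partition_into_runs(bucket_markers_by_lg(hits))
        frags, frag_hits, _, records = split_inter_lg(scaf, runs)
        assert len(frags) == 3 and len(records) == 2
        for fid, hits_f in frag_hits.items():
            assert len({m.linkage_group for m, _ in hits_f}) == 1
        assert sorted(c for f in frags for c in f.contig_ids()) == sorted(scaf.contig_ids())


def _oracle_min_discard(scaffold, runs):
    """Exhaustive search over run-discard subsets: fewest markers discarded
    such that, after merging same-LG neighbours, every adjacent pair of the
    surviving runs has a usable gap between them."""
    from chromanchor._split import find_gap_in_interval

    best = None
    n = len(runs)
    for keep_mask in itertools.product([0, 1], repeat=n):
        kept = [runs[i] for i in range(n) if keep_mask[i]]
        if not kept:
            continue
        merged = []
        for run in kept:
            if merged and merged[-1].linkage_group == run.linkage_group:
                from chromanchor.inter_lg import Run

                hits = sorted(
                    merged[-1].hits + run.hits, key=lambda h: h[1].position
                )
                merged[-1] = Run(run.linkage_group, hits)
            else:
                from chromanchor.inter_lg import Run

                merged.append(Run(run.linkage_group, list(run.hits)))
        ok = all(
            find_gap_in_interval(scaffold, a.bp_last, b.bp_first) is not None
            for a, b in zip(merged, merged[1:])
        )
        if not ok:
            continue
        dropped = sum(runs[i].n for i in range(n) if not keep_mask[i])
        if best is None or dropped < best:
            best = dropped
    return best


@given(st.data())
@settings(max_examples=150, deadline=None)
def test_iterative_discard_matches_exhaustive_minimum(data):
    """For small conflicts the iterative smallest-set rule discards exactly
    as many markers as the exhaustive-search optimum."""
    n_runs = data.draw(st.integers(2, 6))
    gap_after = [data.draw(st.booleans()) for _ in range(n_runs - 1)]
    lgs = [data.draw(st.sampled_from(["LG1", "LG2", "LG3"])) for _ in range(n_runs)]
    sizes = [data.draw(st.integers(1, 3)) for _ in range(n_runs)]
    spec, marker_tuples, pos = [], [], 0
    for i in range(n_runs):
        seg = 100 * sizes[i] + 100
        spec.append(f"c:{seg}")
        for k in range(sizes[i]):
            marker_tuples.append((f"m{i}_{k}", lgs[i], float(k), pos + 50 + 100 * k))
        pos += seg
        if i < n_runs - 1 and gap_after[i]:
            spec.append("g:50")
            pos += 50
    scaffold = make_scaffold(" ".join(spec))
    hits = make_hits("s1", *marker_tuples)
    runs = partition_into_runs(bucket_markers_by_lg(hits))
    _, _, discarded, _ = split_inter_lg(scaffold, runs, min_split_support=1)
    oracle = _oracle_min_discard(scaffold, runs)
    assert len(discarded) == oracle
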