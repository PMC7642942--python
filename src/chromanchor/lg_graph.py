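"""Stages 2-4: linkage-group graphs, consistent marker subsets, intra-LG
splitting, and final orientation.

Each distinct cM position of a linkage group is a graph node.  A scaffold is
anchored at every node holding at least one of its markers; maximal runs of
consecutive anchored nodes collapse into a single placement (which makes the
scaffold definitively orientable when the run spans two or more nodes).  A
scaffold left in several non-adjacent placements indicates a misassembly and
is split between them.

Marker consistency follows the assembly-over-single-marker rule: within each
placement the maximum-cardinality subset of markers whose cM sequence is
monotone (non-decreasing forward, non-increasing reverse; equal cM values tie
within one node and never conflict) is retained via longest-monotone-
subsequence dynamic programming, and the rest are discarded as order
conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._split import find_gap_in_interval, remap_hits, split_at_gaps
from .datamodel import (
    FORWARD,
    REVERSE,
    UNORIENTED,
    MapNode,
    MarkerHit,
    Scaffold,
    ScaffoldPlacement,
    SplitRecord,
)


@dataclass
class OrientationCall:
    orientation: str
    slope: float
    n_cm_positions: int


@dataclass
class LinkageGroupGraph:
    linkage_group: str
    nodes: list[MapNode] = field(default_factory=list)
    placements: list[ScaffoldPlacement] = field(default_factory=list)

    def refresh_anchors(self) -> None:
        for node in self.nodes:
            node.anchors = []
        for placement in self.placements:
            for node in placement.nodes:
                node.anchors.append(placement)

    def placements_of(self, scaffold_id: str) -> list[ScaffoldPlacement]:
        return [p for p in self.placements if p.scaffold_id == scaffold_id]


def ols_slope(xs: list[float], ys: list[float]) -> float:
    """Ordinary-least-squares slope of ys on xs (0.0 when xs is degenerate)."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    if sxx == 0:
        return 0.0
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    return sxy / sxx


def provisional_orientation(hits: list[MarkerHit]) -> OrientationCall:
    """Regression of bp on cM; sign gives the direction.  Requires markers at
    two or more distinct cM positions, else the scaffold stays unoriented."""
    cms = [m.cm for m, _ in hits]
    bps = [float(a.position) for _, a in hits]
    n_cm = len(set(cms))
    if n_cm < 2:
        return OrientationCall(UNORIENTED, 0.0, n_cm)
    slope = ols_slope(cms, bps)
    if slope > 0:
        return OrientationCall(FORWARD, slope, n_cm)
    if slope < 0:
        return OrientationCall(REVERSE, slope, n_cm)
    return OrientationCall(UNORIENTED, 0.0, n_cm)


def build_lg_graph(
    linkage_group: str, hits_by_scaffold: dict[str, list[MarkerHit]]
) -> LinkageGroupGraph:
    """One node per distinct cM (ascending); scaffolds anchored at every node
    holding one of their markers, consecutive anchored nodes collapsed into a
    single placement, non-consecutive anchors yielding multiple placements."""
    cms = sorted({m.cm for hits in hits_by_scaffold.values() for m, _ in hits})
    graph = LinkageGroupGraph(linkage_group, [MapNode(linkage_group, cm) for cm in cms])
    index = {cm: i for i, cm in enumerate(cms)}
    for sid, hits in hits_by_scaffold.items():
        if not hits:
            continue
        call = provisional_orientation(hits)
        anchored = sorted({index[m.cm] for m, _ in hits})
        runs: list[list[int]] = [[anchored[0]]]
        for idx in anchored[1:]:
            if idx == runs[-1][-1] + 1:
                runs[-1].append(idx)
            else:
                runs.append([idx])
        for run in runs:
            node_set = set(run)
            run_hits = sorted(
                (h for h in hits if index[h[0].cm] in node_set),
                key=lambda h: (h[1].position, h[0].id),
            )
            placement = ScaffoldPlacement(
                scaffold_id=sid,
                nodes=[graph.nodes[i] for i in run],
                orientation=call.orientation,
                retained_markers=run_hits,
                slope=call.slope,
            )
            graph.placements.append(placement)
    graph.refresh_anchors()
    return graph


def _longest_monotone(cms: list[float], decreasing: bool) -> list[int]:
    """Indices of the maximum-cardinality monotone (non-strict) subsequence;
    among equal-cardinality optima, the lexicographically earliest."""

    def ok(a: float, b: float) -> bool:
        return b <= a if decreasing else a <= b

    n = len(cms)
    # best[i]: length of the longest valid subsequence starting at i
    best = [1] * n
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            if ok(cms[i], cms[j]) and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
    target = max(best, default=0)
    chosen: list[int] = []
    need = target
    last: float | None = None
    for i in range(n):
        if best[i] == need and (last is None or ok(last, cms[i])):
            chosen.append(i)
            last = cms[i]
            need -= 1
            if need == 0:
                break
    return chosen


def consistent_marker_set(placement: ScaffoldPlacement) -> None:
    """Retain the maximal consistently ordered marker subset in-place.

    Markers are bp-sorted; the retained subset's cM sequence must be
    non-decreasing (forward) or non-increasing (reverse).  An unoriented
    placement is evaluated in both directions and the larger set wins
    (ties favour forward)."""
    hits = sorted(placement.retained_markers, key=lambda h: (h[1].position, h[0].id))
    cms = [m.cm for m, _ in hits]
    if placement.orientation == FORWARD:
        keep = _longest_monotone(cms, decreasing=False)
    elif placement.orientation == REVERSE:
        keep = _longest_monotone(cms, decreasing=True)
    else:
        fwd = _longest_monotone(cms, decreasing=False)
        rev = _longest_monotone(cms, decreasing=True)
        keep = fwd if len(fwd) >= len(rev) else rev
    keep_set = set(keep)
    placement.retained_markers = [hits[i] for i in keep]
    for i, hit in enumerate(hits):
        if i not in keep_set:
            placement.discarded_markers.append((hit[0], hit[1], "order conflict"))


def _placement_sort_key(p: ScaffoldPlacement) -> tuple[int, int]:
    return p.bp_interval()


def _smallest_placement(placements: list[ScaffoldPlacement]) -> ScaffoldPlacement:
    """Fewest retained markers; ties -> fewer bp spanned, then higher cM."""
    return min(
        placements,
        key=lambda p: (
            len(p.retained_markers),
            p.bp_interval()[1] - p.bp_interval()[0],
            -p.cm_first,
        ),
    )


def split_intra_lg(
    graph: LinkageGroupGraph,
    scaffolds: dict[str, Scaffold],
    name_pattern: str = "{id}__{n}",
    min_split_support: int = 2,
) -> tuple[list[SplitRecord], dict[str, list]]:
    """Split every scaffold anchored at two or more placements.

    Cuts go at the best gap (real or virtual) in the bp interval between the
    retained marker groups of each adjacent placement pair; when an adjacency
    has no usable gap, the smallest conflicting placement is discarded and the
    search repeats, so the terminal state is one placement per scaffold or a
    clean multi-way split.  Single-marker placements never force a split.
    Mutates ``graph`` and ``scaffolds``; returns split records and per-origin
    discarded hits."""
    records: list[SplitRecord] = []
    discards: dict[str, list] = {}

    for sid in [p.scaffold_id for p in graph.placements]:
        placements = graph.placements_of(sid)
        if len(placements) <= 1:
            continue
        scaffold = scaffolds[sid]
        origin = scaffold.origin_id

        def drop(p: ScaffoldPlacement, reason: str) -> None:
            for marker, aln in p.retained_markers:
                discards.setdefault(origin, []).append((marker, aln, reason))
            graph.placements.remove(p)
            placements.remove(p)
        while len(placements) > 1:
            weak = [p for p in placements if len(p.retained_markers) < min_split_support]
            if weak:
                drop(_smallest_placement(weak), "intra-LG conflict, insufficient support")
                continue
            placements.sort(key=_placement_sort_key)
            gaps: list[int | None] = []
            for up, down in zip(placements, placements[1:]):
                lo = up.bp_interval()[1]
                hi = down.bp_interval()[0]
                gaps.append(find_gap_in_interval(scaffold, lo, hi))
            gapless = [i for i, g in enumerate(gaps) if g is None]
            if not gapless:
                break
            involved: list[ScaffoldPlacement] = []
            for i in gapless:
                for p in (placements[i], placements[i + 1]):
                    if p not in involved:
                        involved.append(p)
            drop(_smallest_placement(involved), "intra-LG conflict, no gap")

        if len(placements) <= 1:
            continue

        gap_indices = []
        for up, down in zip(placements, placements[1:]):
            gap_indices.append(
                find_gap_in_interval(scaffold, up.bp_interval()[1], down.bp_interval()[0])
            )
        fragments, recs = split_at_gaps(
            scaffold, gap_indices, name_pattern, reason="intra-LG conflict"
        )
        records.extend(recs)
        all_hits = [h for p in placements for h in p.retained_markers]
        hits_by_frag, lost = remap_hits(all_hits, scaffold, fragments)
        for marker, aln in lost:
            discards.setdefault(origin, []).append((marker, aln, "marker inside consumed gap"))
        del scaffolds[sid]
        for frag, placement in zip(fragments, placements):
            scaffolds[frag.id] = frag
            placement.scaffold_id = frag.id
            placement.retained_markers = hits_by_frag.get(frag.id, [])
    graph.refresh_anchors()
    return records, discards


def finalize_orientation(graph: LinkageGroupGraph) -> None:
    """Re-run the regression on retained markers only.  Placements spanning
    two or more collapsed nodes with a non-zero slope are definitively
    oriented; single-node placements stay unoriented (synteny candidates)."""
    for placement in graph.placements:
        call = provisional_orientation(placement.retained_markers)
        placement.orientation = call.orientation
        placement.slope = call.slope
        placement.definitive = call.n_cm_positions >= 2 and call.orientation != UNORIENTED
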