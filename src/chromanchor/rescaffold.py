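"""Map-priority rescaffolding: reorder the physical sequence to match marker
order, creating breakpoints inside gapless contigs.

The basal stages trust contig structure over individual markers, so an
inverted or translocated block *inside* a contig is normally resolved by
discarding the minority markers.  Rescaffold mode flips the priority: each
map node owns the sequence its markers span.  Markers are bucketed by node,
nodes are re-sorted by their mean physical position, physically overlapping
adjacent nodes are pruned (removing the marker farthest from its own node
mean first), and the scaffold is cut wherever the physical node progression
breaks cM adjacency — at the best real gap in the break interval, or at a
depth-derived virtual gap when the sequence is gapless.  The resulting
fragments re-enter the basal pipeline, which re-sorts them to cM order and
re-orients each by regression on its own markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._split import find_gap_in_interval, remap_hits, split_at_gaps
from .datamodel import MarkerHit, Scaffold, SplitRecord


@dataclass
class NodeSpan:
    """One map node's markers on one scaffold."""

    cm: float
    hits: list[MarkerHit] = field(default_factory=list)

    @property
    def mean_bp(self) -> float:
        return sum(a.position for _, a in self.hits) / len(self.hits)

    @property
    def bp_min(self) -> int:
        return min(a.position for _, a in self.hits)

    @property
    def bp_max(self) -> int:
        return max(a.position for _, a in self.hits)

    @property
    def n(self) -> int:
        return len(self.hits)


def bucket_by_node(hits: list[MarkerHit]) -> list[NodeSpan]:
    """One span per distinct cM with >=1 marker, ascending cM."""
    spans: dict[float, NodeSpan] = {}
    for marker, aln in hits:
        spans.setdefault(marker.cm, NodeSpan(marker.cm)).hits.append((marker, aln))
    return [spans[cm] for cm in sorted(spans)]


def resort_nodes_by_bp(spans: list[NodeSpan]) -> list[NodeSpan]:
    """Ascending mean physical position; ties fall back to cM order."""
    return sorted(spans, key=lambda s: (s.mean_bp, s.cm))


def prune_overlaps(
    spans: list[NodeSpan], min_split_support: int = 2
) -> tuple[list[NodeSpan], list[tuple]]:
    """Make adjacent bp intervals strictly disjoint.

    While an adjacent pair overlaps: an uncorroborated span (fewer than
    ``min_split_support`` markers) in the pair is discarded whole; otherwise
    the single marker with maximal |bp - own-span mean| is removed (ties:
    the marker in the smaller span, then lexicographic id).  Spans emptied of
    markers are deleted.  Returns (spans, discarded hits with reasons)."""
    spans = [NodeSpan(s.cm, list(s.hits)) for s in spans]
    discarded: list[tuple] = []
    while True:
        spans = resort_nodes_by_bp([s for s in spans if s.hits])
        offending = None
        for a, b in zip(spans, spans[1:]):
            if a.bp_max >= b.bp_min:
                offending = (a, b)
                break
        if offending is None:
            return spans, discarded
        a, b = offending
        weak = [s for s in (a, b) if s.n < min_split_support]
        if weak:
            victim_span = min(weak, key=lambda s: (s.n, s.bp_max - s.bp_min))
            for marker, aln in victim_span.hits:
                discarded.append((marker, aln, "rescaffold: uncorroborated node span"))
            victim_span.hits.clear()
            continue
        def overlap_after(span: NodeSpan, hit: MarkerHit) -> int:
            rest = {
                id(s): [h for h in s.hits if h is not hit] for s in (a, b)
            }
            if not rest[id(span)]:
                return 0
            ordered = sorted(
                (a, b),
                key=lambda s: (
                    sum(h[1].position for h in rest[id(s)]) / len(rest[id(s)]),
                    s.cm,
                ),
            )
            first, second = (rest[id(s)] for s in ordered)
            return max(
                0,
                max(h[1].position for h in first)
                - min(h[1].position for h in second),
            )

        # farthest from its own node mean goes first; ties prefer the
        # removal that most reduces the pair's physical overlap, then id
        best = min(
            (
                (-abs(hit[1].position - span.mean_bp), overlap_after(span, hit), hit[0].id, span, hit)
                for span in (a, b)
                for hit in span.hits
            ),
        )
        _, _, _, span, hit = best
        span.hits.remove(hit)
        discarded.append((hit[0], hit[1], "rescaffold: node overlap prune"))


def group_monotone_runs(spans: list[NodeSpan]) -> list[list[NodeSpan]]:
    """Group bp-sorted spans into maximal runs whose cM values are adjacent
    in the scaffold's own node order and monotone in one direction.  A break
    between runs marks a candidate cut point."""
    rank = {cm: i for i, cm in enumerate(sorted(s.cm for s in spans))}
    runs: list[list[NodeSpan]] = []
    direction = 0
    for span in spans:
        if not runs:
            runs.append([span])
            continue
        step = rank[span.cm] - rank[runs[-1][-1].cm]
        if step in (1, -1) and (direction == 0 or step == direction or len(runs[-1]) == 1):
            if len(runs[-1]) == 1:
                direction = step
            runs[-1].append(span)
        else:
            runs.append([span])
            direction = 0
    return runs


def rescaffold_scaffold(
    scaffold: Scaffold,
    hits: list[MarkerHit],
    name_pattern: str = "{id}__{n}",
    min_split_support: int = 2,
) -> tuple[
    list[Scaffold], dict[str, list[MarkerHit]], list[tuple], list[SplitRecord], list[str]
]:
    """Apply the rescaffold algorithm to one scaffold.

    Returns (fragments, hits per fragment, discarded hits, split records,
    log lines).  A scaffold whose node progression is already cM-monotone
    comes back unchanged."""
    log: list[str] = []
    spans = bucket_by_node(hits)
    if len(spans) < 2:
        return [scaffold], {scaffold.id: hits}, [], [], log

    spans, discarded = prune_overlaps(resort_nodes_by_bp(spans), min_split_support)

    # Drop uncorroborated spans and runs, re-deriving node adjacency from
    # the surviving spans each round: a discarded node must not leave a ghost
    # rank that makes truly neighbouring nodes look non-adjacent.  A single
    # uncorroborated span is sacrificed whenever that alone reduces the
    # number of map-order breaks (the parsimonious reading: one stray marker
    # never fabricates a misassembly); whole runs below the support floor
    # are dropped the same way.
    while True:
        kept_runs = group_monotone_runs(spans)
        if len(kept_runs) <= 1:
            break
        best = None  # (resulting run count, span position) for weak-span removal
        for i, span in enumerate(spans):
            if span.n >= min_split_support:
                continue
            reduced = group_monotone_runs(spans[:i] + spans[i + 1 :])
            if len(reduced) < len(kept_runs) and (
                best is None or len(reduced) < best[0]
            ):
                best = (len(reduced), i)
        if best is not None:
            victim_span = spans.pop(best[1])
            for marker, aln in victim_span.hits:
                discarded.append((marker, aln, "rescaffold: insufficient support"))
            log.append(
                f"{scaffold.id}: dropped {victim_span.n}-marker node at cM "
                f"{victim_span.cm} (insufficient support)"
            )
            continue
        weak = [r for r in kept_runs if sum(s.n for s in r) < min_split_support]
        if not weak:
            break
        victim = min(weak, key=lambda r: (sum(s.n for s in r), r[0].cm))
        for span in victim:
            for marker, aln in span.hits:
                discarded.append((marker, aln, "rescaffold: insufficient support"))
        log.append(
            f"{scaffold.id}: dropped {sum(s.n for s in victim)}-marker node run "
            f"at cM {victim[0].cm}..{victim[-1].cm} (insufficient support)"
        )
        victim_ids = {id(s) for s in victim}
        spans = [s for s in spans if id(s) not in victim_ids]

    if len(kept_runs) <= 1:
        remaining = [h for run in kept_runs for s in run for h in s.hits]
        return [scaffold], {scaffold.id: remaining}, discarded, [], log

    # one cut between each adjacent pair of runs, where a gap allows it
    gap_indices: list[int] = []
    merged: list[list[NodeSpan]] = [kept_runs[0]]
    for run in kept_runs[1:]:
        lo = max(s.bp_max for s in merged[-1])
        hi = min(s.bp_min for s in run)
        gi = find_gap_in_interval(scaffold, lo, hi)
        if gi is None:
            log.append(
                f"{scaffold.id}: no gap between bp {lo} and {hi}; "
                "node runs merged unsplit"
            )
            merged[-1] = merged[-1] + run
        else:
            gap_indices.append(gi)
            merged.append(run)

    if not gap_indices:
        remaining = [h for run in merged for s in run for h in s.hits]
        return [scaffold], {scaffold.id: remaining}, discarded, [], log

    fragments, records = split_at_gaps(
        scaffold, gap_indices, name_pattern, reason="rescaffold: map-order conflict"
    )
    kept_hits = [h for run in merged for s in run for h in s.hits]
    hits_by_frag, lost = remap_hits(kept_hits, scaffold, fragments)
    for marker, aln in lost:
        discarded.append((marker, aln, "marker inside consumed gap"))
    return fragments, hits_by_frag, discarded, records, log


def resolve_rescaffold(
    scaffolds: dict[str, Scaffold],
    hits_by_scaffold: dict[str, list[MarkerHit]],
    name_pattern: str = "{id}__{n}",
    min_split_support: int = 2,
) -> tuple[
    dict[str, Scaffold],
    dict[str, list[MarkerHit]],
    dict[str, list[tuple]],
    list[SplitRecord],
    list[str],
]:
    """Run rescaffolding over every marker-bearing scaffold."""
    new_scaffolds: dict[str, Scaffold] = {}
    new_hits: dict[str, list[MarkerHit]] = {}
    discards: dict[str, list[tuple]] = {}
    records: list[SplitRecord] = []
    log: list[str] = []
    for sid, scaffold in scaffolds.items():
        hits = hits_by_scaffold.get(sid)
        if not hits:
            new_scaffolds[sid] = scaffold
            continue
        frags, frag_hits, disc, recs, lines = rescaffold_scaffold(
            scaffold, hits, name_pattern, min_split_support
        )
        for frag in frags:
            new_scaffolds[frag.id] = frag
            if frag_hits.get(frag.id):
                new_hits[frag.id] = sorted(
                    frag_hits[frag.id], key=lambda h: (h[1].position, h[0].id)
                )
        if disc:
            discards.setdefault(scaffold.origin_id, []).extend(disc)
        records.extend(recs)
        log.extend(lines)
    return new_scaffolds, new_hits, discards, records, log
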