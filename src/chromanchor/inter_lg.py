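"""Stage 1: resolve scaffolds whose markers map to more than one linkage
group.

Linkage-group assignment is statistically robust, so when one scaffold's
markers belong to several linkage groups the scaffold — not the map — is
presumed chimeric.  The scaffold is cut at the largest gap between adjacent
same-LG marker runs; where no gap is available the smaller run is pruned
until the scaffold is splittable or a single run remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._split import find_gap_in_interval, remap_hits, split_at_gaps
from .datamodel import MarkerHit, Scaffold, SplitRecord

DiscardedHit = tuple  # (Marker, MarkerAlignment, reason)


@dataclass
class LgBucket:
    """All of one scaffold's markers from one linkage group, bp-sorted."""

    linkage_group: str
    hits: list[MarkerHit] = field(default_factory=list)


@dataclass
class Run:
    """A maximal bp-contiguous stretch of same-LG markers on a scaffold."""

    linkage_group: str
    hits: list[MarkerHit]

    @property
    def n(self) -> int:
        return len(self.hits)

    @property
    def bp_first(self) -> int:
        return self.hits[0][1].position

    @property
    def bp_last(self) -> int:
        return self.hits[-1][1].position

    @property
    def extent(self) -> int:
        return self.bp_last - self.bp_first


def bucket_markers_by_lg(hits: list[MarkerHit]) -> list[LgBucket]:
    """One bucket per linkage group with >=1 marker, markers bp-sorted."""
    buckets: dict[str, LgBucket] = {}
    for marker, aln in sorted(hits, key=lambda h: (h[1].position, h[0].id)):
        buckets.setdefault(marker.linkage_group, LgBucket(marker.linkage_group)).hits.append(
            (marker, aln)
        )
    return list(buckets.values())


def partition_into_runs(buckets: list[LgBucket]) -> list[Run]:
    """Maximal same-LG runs in bp order; adjacent runs differ in LG."""
    merged = sorted(
        (hit for b in buckets for hit in b.hits), key=lambda h: (h[1].position, h[0].id)
    )
    runs: list[Run] = []
    for marker, aln in merged:
        if runs and runs[-1].linkage_group == marker.linkage_group:
            runs[-1].hits.append((marker, aln))
        else:
            runs.append(Run(marker.linkage_group, [(marker, aln)]))
    return runs


def _discard_rank(runs: list[Run], candidates: list[int]) -> int:
    """Pick the run to discard: fewest markers, then fewest bp, then latest."""
    return min(candidates, key=lambda i: (runs[i].n, runs[i].extent, -i))


_EXACT_SEARCH_LIMIT = 12


def _min_discard_keep(scaffold: Scaffold, runs: list[Run]) -> set[int]:
    """Exact minimum-marker-discard subset of runs leaving every adjacent
    surviving pair (after same-LG merging) splittable at a gap.  Feasible
    for the run counts real conflicts produce; a singleton kept set is
    always valid, so a solution exists."""
    import itertools

    from ._split import find_gap_in_interval

    best: tuple[int, int] | None = None
    best_keep: set[int] = set()
    for mask in itertools.product((1, 0), repeat=len(runs)):
        keep = [i for i, m in enumerate(mask) if m]
        if not keep:
            continue
        merged = _merge_adjacent_same_lg([runs[i] for i in keep])
        if any(
            find_gap_in_interval(scaffold, a.bp_last, b.bp_first) is None
            for a, b in zip(merged, merged[1:])
        ):
            continue
        dropped = sum(runs[i].n for i in range(len(runs)) if i not in set(keep))
        key = (dropped, len(runs) - len(keep))
        if best is None or key < best:
            best, best_keep = key, set(keep)
    return best_keep


def _merge_adjacent_same_lg(runs: list[Run]) -> list[Run]:
    out: list[Run] = []
    for run in runs:
        if out and out[-1].linkage_group == run.linkage_group:
            out[-1].hits.extend(run.hits)
            out[-1].hits.sort(key=lambda h: (h[1].position, h[0].id))
        else:
            out.append(Run(run.linkage_group, list(run.hits)))
    return out


def split_inter_lg(
    scaffold: Scaffold,
    runs: list[Run],
    name_pattern: str = "{id}__{n}",
    min_split_support: int = 2,
) -> tuple[list[Scaffold], dict[str, list[MarkerHit]], list[DiscardedHit], list[SplitRecord]]:
    """Split a multi-LG scaffold between marker runs, pruning where needed.

    Returns (fragments, hits per fragment, discarded hits, split records).
    A single-run outcome returns the scaffold unchanged (fragments == [scaffold]).
    """
    runs = [Run(r.linkage_group, list(r.hits)) for r in runs]
    discarded: list[DiscardedHit] = []

    def discard(i: int, reason: str) -> None:
        for marker, aln in runs[i].hits:
            discarded.append((marker, aln, reason))
        del runs[i]

    while len(runs) > 1:
        weak = [i for i, r in enumerate(runs) if r.n < min_split_support]
        if weak:
            discard(_discard_rank(runs, weak), "inter-LG conflict, insufficient support")
            runs = _merge_adjacent_same_lg(runs)
            continue
        gaps: list[int | None] = [
            find_gap_in_interval(scaffold, runs[i].bp_last, runs[i + 1].bp_first)
            for i in range(len(runs) - 1)
        ]
        gapless = [i for i, g in enumerate(gaps) if g is None]
        if not gapless:
            break
        if len(runs) <= _EXACT_SEARCH_LIMIT:
            keep = _min_discard_keep(scaffold, runs)
            for i in sorted(set(range(len(runs))) - keep, reverse=True):
                discard(i, "inter-LG conflict, no gap")
        else:
            involved = sorted({j for i in gapless for j in (i, i + 1)})
            discard(_discard_rank(runs, involved), "inter-LG conflict, no gap")
        runs = _merge_adjacent_same_lg(runs)

    if len(runs) <= 1:
        hits = {scaffold.id: runs[0].hits if runs else []}
        return [scaffold], hits, discarded, []

    gap_indices = [
        find_gap_in_interval(scaffold, runs[i].bp_last, runs[i + 1].bp_first)
        for i in range(len(runs) - 1)
    ]
    fragments, records = split_at_gaps(
        scaffold, gap_indices, name_pattern, reason="inter-LG conflict"
    )
    kept = [hit for r in runs for hit in r.hits]
    hits_by_frag, lost = remap_hits(kept, scaffold, fragments)
    for marker, aln in lost:
        discarded.append((marker, aln, "marker inside consumed gap"))
    return fragments, hits_by_frag, discarded, records


def resolve_inter_lg(
    scaffolds: dict[str, Scaffold],
    hits_by_scaffold: dict[str, list[MarkerHit]],
    name_pattern: str = "{id}__{n}",
    min_split_support: int = 2,
) -> tuple[
    dict[str, Scaffold],
    dict[str, list[MarkerHit]],
    dict[str, list[DiscardedHit]],
    list[SplitRecord],
]:
    """Run stage 1 over the whole assembly (insertion order preserved)."""
    new_scaffolds: dict[str, Scaffold] = {}
    new_hits: dict[str, list[MarkerHit]] = {}
    discards: dict[str, list[DiscardedHit]] = {}
    records: list[SplitRecord] = []
    for sid, scaffold in scaffolds.items():
        hits = hits_by_scaffold.get(sid, [])
        buckets = bucket_markers_by_lg(hits)
        if len(buckets) <= 1:
            new_scaffolds[sid] = scaffold
            if hits:
                new_hits[sid] = hits
            continue
        runs = partition_into_runs(buckets)
        frags, frag_hits, disc, recs = split_inter_lg(
            scaffold, runs, name_pattern, min_split_support
        )
        for frag in frags:
            new_scaffolds[frag.id] = frag
            if frag_hits.get(frag.id):
                new_hits[frag.id] = frag_hits[frag.id]
        if disc:
            discards[sid] = disc
        records.extend(recs)
    return new_scaffolds, new_hits, discards, records
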