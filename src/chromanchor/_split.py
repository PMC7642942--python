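"""Shared scaffold-cutting machinery used by the inter-LG, intra-LG and
rescaffold stages: gap selection inside a marker interval, multi-cut
fragmentation, and remapping of marker alignments onto fragments."""

from __future__ import annotations

from dataclasses import replace

from .datamodel import GAP, MarkerAlignment, MarkerHit, Scaffold, SplitRecord


def find_gap_in_interval(
    scaffold: Scaffold, lo: int, hi: int, allow_virtual: bool = True
) -> int | None:
    """Best gap component strictly between marker positions ``lo`` and ``hi``.

    A gap qualifies when it lies entirely after base ``lo`` and no later than
    base ``hi``.  The largest gap wins; zero-length virtual gaps tie, so ties
    are broken by proximity to the interval midpoint, then leftmost.
    """
    if hi <= lo:
        return None
    mid = (lo + hi) / 2.0
    best: tuple[int, float, int] | None = None  # (-length, |center-mid|, index)
    for i, comp in enumerate(scaffold.components):
        if not comp.is_gap:
            continue
        if comp.kind != GAP and not allow_virtual:
            continue
        if comp.object_beg <= lo or comp.object_end > hi:
            continue
        center = (comp.object_beg + comp.object_end) / 2.0
        key = (-comp.length, abs(center - mid), i)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def split_at_gaps(
    scaffold: Scaffold,
    gap_indices: list[int],
    name_pattern: str,
    reason: str,
) -> tuple[list[Scaffold], list[SplitRecord]]:
    """Cut ``scaffold`` at the given gap components (consuming them) and
    return left-to-right fragments named by ``name_pattern``."""
    records = [
        SplitRecord(
            scaffold_id=scaffold.id,
            origin_id=scaffold.origin_id,
            origin_bp=scaffold.origin_beg + scaffold.components[i].object_beg,
            gap_kind=scaffold.components[i].kind,
            reason=reason,
        )
        for i in sorted(gap_indices)
    ]
    fragments: list[Scaffold] = []
    rest = scaffold
    offset = 0  # components already peeled off `rest`
    for n, gi in enumerate(sorted(gap_indices), start=1):
        left, rest = rest.split_at_component(
            gi - offset,
            name_pattern.format(id=scaffold.id, n=n),
            name_pattern.format(id=scaffold.id, n=n + 1),
        )
        fragments.append(left)
        offset = gi + 1
    fragments.append(rest)
    return fragments, records


def remap_hits(
    hits: list[MarkerHit], parent: Scaffold, fragments: list[Scaffold]
) -> tuple[dict[str, list[MarkerHit]], list[MarkerHit]]:
    """Reassign marker hits on ``parent`` to the fragment containing each
    position.  Hits falling into a consumed gap are returned as lost."""
    spans = []
    for frag in fragments:
        start = frag.origin_beg - parent.origin_beg
        spans.append((start, start + frag.length, frag.id))
    out: dict[str, list[MarkerHit]] = {frag.id: [] for frag in fragments}
    lost: list[MarkerHit] = []
    for marker, aln in hits:
        placed = False
        for start, end, fid in spans:
            if start <= aln.position < end:
                out[fid].append(
                    (marker, replace(aln, scaffold_id=fid, position=aln.position - start))
                )
                placed = True
                break
        if not placed:
            lost.append((marker, aln))
    return out, lost
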