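"""Assemble final chromosome models and emit every output artifact.

Placements are ordered within each linkage group by map node position;
within a single shared node the synteny order applies when available,
otherwise a deterministic fallback (descending scaffold length, then id)
with the orientation flagged unknown.  Adjacent placements are separated by
a fixed-length join gap recorded in AGP as a map-evidence contig gap.

Emitters: AGP v2.1 (chromosomes + unplaced), FASTA (reverse placements
reverse-complemented; non-N base content is conserved), GFF lift-over in
both directions, per-LG before/after marker tables, per-modified-scaffold
split logs, a summary table, the promising-scaffold list, and per-LG
before/after JSON views.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from .datamodel import (
    CONTIG,
    FORWARD,
    GAP,
    REVERSE,
    UNORIENTED,
    AssemblyComponent,
    Chromonome,
    Marker,
    MarkerHit,
    Scaffold,
    ScaffoldPlacement,
    SplitRecord,
)
from .io_formats import reverse_complement, write_agp, write_fasta
from .lg_graph import LinkageGroupGraph

ORIENT_CHAR = {FORWARD: "+", REVERSE: "-", UNORIENTED: "?"}


def _node_group_key(p: ScaffoldPlacement) -> tuple[float, float]:
    return (p.cm_first, p.cm_last)


def _fallback_key(scaffolds: dict[str, Scaffold]):
    def key(p: ScaffoldPlacement):
        return (-scaffolds[p.scaffold_id].length, p.scaffold_id)

    return key


def build_chromonome(
    graphs: dict[str, LinkageGroupGraph],
    scaffolds: dict[str, Scaffold],
    provenance: list[SplitRecord],
    gap_length: int = 100,
) -> Chromonome:
    """Order placements into chromosomes; everything unanchored is unplaced."""
    chromosomes: dict[str, list[tuple[ScaffoldPlacement, int]]] = {}
    placed: set[str] = set()
    for lg in sorted(graphs):
        graph = graphs[lg]
        if not graph.placements:
            continue
        groups: dict[tuple[float, float], list[ScaffoldPlacement]] = {}
        for p in graph.placements:
            groups.setdefault(_node_group_key(p), []).append(p)
        ordered: list[ScaffoldPlacement] = []
        for gkey in sorted(groups):
            group = groups[gkey]
            ranked = sorted(
                (p for p in group if p.synteny_rank is not None),
                key=lambda p: p.synteny_rank,
            )
            rest = sorted(
                (p for p in group if p.synteny_rank is None),
                key=_fallback_key(scaffolds),
            )
            if len(group) > 1:
                for p in rest:
                    if p.evidence == "map" and not p.definitive:
                        p.evidence = "fallback"
            ordered.extend(ranked + rest)
        chromosomes[lg] = [(p, gap_length) for p in ordered]
        placed.update(p.scaffold_id for p in ordered)
    unplaced = [s for sid, s in scaffolds.items() if sid not in placed]
    return Chromonome(chromosomes, dict(scaffolds), unplaced, list(provenance))


def chromosome_layout(
    chromonome: Chromonome, chrom_name=lambda lg: lg
) -> dict[str, list[tuple[ScaffoldPlacement, str, int]]]:
    """Per LG: (placement, chromosome name, start offset) with join gaps."""
    layout: dict[str, list[tuple[ScaffoldPlacement, str, int]]] = {}
    for lg, placements in chromonome.chromosomes.items():
        name = chrom_name(lg)
        offset = 0
        rows = []
        for placement, gap in placements:
            rows.append((placement, name, offset))
            offset += chromonome.scaffolds[placement.scaffold_id].length + gap
        layout[lg] = rows
    return layout


def _oriented_components(scaffold: Scaffold, reverse: bool) -> list[AssemblyComponent]:
    if not reverse:
        return list(scaffold.components)
    flipped = []
    length = scaffold.length
    for comp in reversed(scaffold.components):
        new_beg = length - comp.object_end
        new_end = length - comp.object_beg
        orient = comp.orientation
        if comp.kind == CONTIG:
            orient = {"+": "-", "-": "+"}.get(orient, orient)
        flipped.append(
            AssemblyComponent(
                object_id=comp.object_id,
                object_beg=new_beg,
                object_end=new_end,
                part_number=1,  # renumbered below
                kind=comp.kind,
                component_id=comp.component_id,
                component_beg=comp.component_beg,
                component_end=comp.component_end,
                orientation=orient,
                gap_length=comp.gap_length,
                gap_type=comp.gap_type,
                linkage=comp.linkage,
                evidence=comp.evidence,
            )
        )
    return flipped


def chromonome_scaffolds(
    chromonome: Chromonome, chrom_name=lambda lg: lg, gap_length: int = 100
) -> list[Scaffold]:
    """Materialize each chromosome as a Scaffold of contig/gap components."""
    out = []
    for lg, placements in chromonome.chromosomes.items():
        name = chrom_name(lg)
        comps: list[AssemblyComponent] = []
        pos = 0
        for i, (placement, gap) in enumerate(placements):
            scaf = chromonome.scaffolds[placement.scaffold_id]
            for comp in _oriented_components(scaf, placement.orientation == REVERSE):
                comps.append(
                    AssemblyComponent(
                        object_id=name,
                        object_beg=pos,
                        object_end=pos + comp.length,
                        part_number=len(comps) + 1,
                        kind=comp.kind,
                        component_id=comp.component_id,
                        component_beg=comp.component_beg,
                        component_end=comp.component_end,
                        orientation=comp.orientation,
                        gap_length=comp.gap_length,
                        gap_type=comp.gap_type,
                        linkage=comp.linkage,
                        evidence=comp.evidence,
                    )
                )
                pos += comp.length
            if i < len(placements) - 1:
                comps.append(
                    AssemblyComponent(
                        object_id=name,
                        object_beg=pos,
                        object_end=pos + gap,
                        part_number=len(comps) + 1,
                        kind=GAP,
                        gap_length=gap,
                        gap_type="contig",
                        linkage="yes",
                        evidence="map",
                    )
                )
                pos += gap
        out.append(Scaffold(name, comps, origin_id=name))
    return out


def emit_agp(
    chromonome: Chromonome,
    chrom_path: str,
    unplaced_path: str,
    chrom_name=lambda lg: lg,
) -> None:
    write_agp(chromonome_scaffolds(chromonome, chrom_name), chrom_path)
    write_agp(chromonome.unplaced, unplaced_path)


def fragment_sequence(scaffold: Scaffold, source_seqs: dict[str, str]) -> str:
    if scaffold.origin_id not in source_seqs:
        raise KeyError(
            f"scaffold {scaffold.origin_id!r} present in AGP but absent from FASTA"
        )
    seq = source_seqs[scaffold.origin_id]
    return seq[scaffold.origin_beg : scaffold.origin_beg + scaffold.length]


def emit_fasta(
    chromonome: Chromonome,
    source_seqs: dict[str, str],
    path: str,
    chrom_name=lambda lg: lg,
) -> None:
    """One record per chromosome (named by LG) plus one per unplaced scaffold."""
    records: list[tuple[str, str]] = []
    for lg, placements in chromonome.chromosomes.items():
        parts = []
        for placement, gap in placements:
            scaf = chromonome.scaffolds[placement.scaffold_id]
            seq = fragment_sequence(scaf, source_seqs)
            if placement.orientation == REVERSE:
                seq = reverse_complement(seq)
            parts.append(seq)
        joiner_parts = []
        for i, (placement, gap) in enumerate(placements):
            joiner_parts.append(parts[i])
            if i < len(placements) - 1:
                joiner_parts.append("N" * gap)
        records.append((chrom_name(lg), "".join(joiner_parts)))
    for scaf in chromonome.unplaced:
        records.append((scaf.id, fragment_sequence(scaf, source_seqs)))
    write_fasta(records, path)


# ---------------------------------------------------------------------------
# Annotation lift-over


@dataclass
class _Segment:
    src_seq: str
    src_beg: int
    src_end: int
    dst_seq: str
    dst_beg: int
    reverse: bool


def _liftover_segments(
    chromonome: Chromonome, chrom_name=lambda lg: lg
) -> list[_Segment]:
    segments: list[_Segment] = []
    layout = chromosome_layout(chromonome, chrom_name)
    for rows in layout.values():
        for placement, name, offset in rows:
            scaf = chromonome.scaffolds[placement.scaffold_id]
            segments.append(
                _Segment(
                    scaf.origin_id,
                    scaf.origin_beg,
                    scaf.origin_beg + scaf.length,
                    name,
                    offset,
                    placement.orientation == REVERSE,
                )
            )
    for scaf in chromonome.unplaced:
        segments.append(
            _Segment(
                scaf.origin_id,
                scaf.origin_beg,
                scaf.origin_beg + scaf.length,
                scaf.id,
                0,
                False,
            )
        )
    return segments


def translate_annotations(
    gff_path: str,
    chromonome: Chromonome,
    direction: str,
    out_path: str,
    chrom_name=lambda lg: lg,
) -> list[str]:
    """Lift a GFF/GTF between scaffold and chromonome coordinates.

    ``direction`` is "to_chromonome" or "to_scaffolds".  Features that span
    a split point (no single segment contains them) are dropped and
    reported; the round trip is the identity for surviving features.
    Returns the log of dropped/skipped features."""
    if direction not in ("to_chromonome", "to_scaffolds"):
        raise ValueError(f"bad direction {direction!r}")
    segments = _liftover_segments(chromonome, chrom_name)
    if direction == "to_scaffolds":
        segments = [
            _Segment(s.dst_seq, s.dst_beg, s.dst_beg + (s.src_end - s.src_beg),
                     s.src_seq, s.src_beg, s.reverse)
            for s in segments
        ]
    by_seq: dict[str, list[_Segment]] = {}
    for seg in segments:
        by_seq.setdefault(seg.src_seq, []).append(seg)
    log: list[str] = []
    with open(gff_path) as fh, open(out_path, "w") as out:
        for line in fh:
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                out.write(line)
                continue
            fields = stripped.split("\t")
            if len(fields) < 8:
                out.write(line)
                continue
            seq = fields[0]
            if seq not in by_seq:
                log.append(f"skipped (unknown sequence {seq}): {fields[2]} {fields[3]}")
                continue
            beg, end = int(fields[3]) - 1, int(fields[4])
            seg = next(
                (s for s in by_seq[seq] if s.src_beg <= beg and end <= s.src_end), None
            )
            if seg is None:
                log.append(f"dropped (spans a split point): {seq}:{fields[3]}-{fields[4]}")
                continue
            if seg.reverse:
                length = seg.src_end - seg.src_beg
                nb = seg.dst_beg + (length - (end - seg.src_beg))
                ne = seg.dst_beg + (length - (beg - seg.src_beg))
                strand = {"+": "-", "-": "+"}.get(fields[6], fields[6])
            else:
                nb = seg.dst_beg + (beg - seg.src_beg)
                ne = seg.dst_beg + (end - seg.src_beg)
                strand = fields[6]
            fields[0] = seg.dst_seq
            fields[3] = str(nb + 1)
            fields[4] = str(ne)
            fields[6] = strand
            out.write("\t".join(fields) + "\n")
    return log


# ---------------------------------------------------------------------------
# Logs, summary, promising scaffolds, JSON views


def lg_json_view(
    lg: str,
    state: str,
    nodes: list[float],
    scaffold_rows: list[dict],
    links: list[dict],
) -> dict:
    return {
        "linkage_group": lg,
        "state": state,
        "nodes": [{"cm": cm} for cm in nodes],
        "scaffolds": scaffold_rows,
        "links": links,
    }


def validate_lg_json(obj: dict) -> None:
    """Structural check against the shipped schema (docs/lg_view.schema.json)."""
    for key in ("linkage_group", "state", "nodes", "scaffolds", "links"):
        if key not in obj:
            raise ValueError(f"lg view missing key {key!r}")
    if obj["state"] not in ("before", "after"):
        raise ValueError(f"bad state {obj['state']!r}")
    for node in obj["nodes"]:
        if "cm" not in node:
            raise ValueError("node without cm")
    for row in obj["scaffolds"]:
        for key in ("id", "len", "placement", "orientation", "evidence"):
            if key not in row:
                raise ValueError(f"scaffold row missing {key!r}")
    for link in obj["links"]:
        for key in ("marker", "cm", "bp", "status"):
            if key not in link:
                raise ValueError(f"link missing {key!r}")


def emit_reports(
    out_dir: str,
    markers: dict[str, Marker],
    initial_hits: dict[str, list[MarkerHit]],
    initial_scaffolds: dict[str, Scaffold],
    chromonome: Chromonome,
    discards: dict[str, list[tuple]],
    chrom_name=lambda lg: lg,
) -> dict:
    """Write per-LG before/after tables, per-modified-scaffold logs, the
    summary, the promising-scaffold list and before/after JSON views.
    Returns the summary statistics dict."""
    os.makedirs(out_dir, exist_ok=True)
    lg_of = {m.id: m.linkage_group for m in markers.values()}

    # --- before state: the inputs as read
    before_by_lg: dict[str, list[tuple[str, Marker, int]]] = {}
    for sid, hits in initial_hits.items():
        for marker, aln in hits:
            before_by_lg.setdefault(marker.linkage_group, []).append(
                (sid, marker, aln.position)
            )

    # --- after state
    retained_status: dict[str, tuple[str, int, str]] = {}
    for lg, placements in chromonome.chromosomes.items():
        for placement, _ in placements:
            for marker, aln in placement.retained_markers:
                retained_status[marker.id] = (placement.scaffold_id, aln.position, "retained")
    discard_status: dict[str, tuple[str, int, str]] = {}
    for sid, items in discards.items():
        for marker, aln, reason in items:
            discard_status[marker.id] = (aln.scaffold_id, aln.position, f"discarded: {reason}")

    lgs = sorted(
        set(before_by_lg) | set(chromonome.chromosomes), key=lambda lg: lg
    )
    layout = chromosome_layout(chromonome, chrom_name)
    for lg in lgs:
        rows_before = sorted(
            before_by_lg.get(lg, []), key=lambda r: (r[1].cm, r[0], r[2])
        )
        with open(os.path.join(out_dir, f"{lg}.before.tsv"), "w") as fh:
            fh.write("marker\tcm\tscaffold\tbp\tstatus\n")
            for sid, marker, bp in rows_before:
                fh.write(f"{marker.id}\t{marker.cm}\t{sid}\t{bp}\tinput\n")
        with open(os.path.join(out_dir, f"{lg}.after.tsv"), "w") as fh:
            fh.write("marker\tcm\tscaffold\tbp\tstatus\n")
            for sid, marker, bp in rows_before:
                where = retained_status.get(marker.id) or discard_status.get(marker.id)
                if where is None:
                    fh.write(f"{marker.id}\t{marker.cm}\t{sid}\t{bp}\tunused\n")
                else:
                    fh.write(
                        f"{marker.id}\t{marker.cm}\t{where[0]}\t{where[1]}\t{where[2]}\n"
                    )

        # JSON views
        nodes_before = sorted({m.cm for _, m, _ in rows_before})
        scaf_before = sorted({sid for sid, _, _ in rows_before})
        view_b = lg_json_view(
            lg,
            "before",
            nodes_before,
            [
                {
                    "id": sid,
                    "len": initial_scaffolds[sid].length if sid in initial_scaffolds else None,
                    "placement": None,
                    "orientation": "?",
                    "evidence": "input",
                }
                for sid in scaf_before
            ],
            [
                {"marker": m.id, "cm": m.cm, "bp": bp, "status": "input"}
                for sid, m, bp in rows_before
            ],
        )
        rows_after = []
        links_after = []
        for rank, (placement, name, offset) in enumerate(layout.get(lg, [])):
            scaf = chromonome.scaffolds[placement.scaffold_id]
            rows_after.append(
                {
                    "id": placement.scaffold_id,
                    "len": scaf.length,
                    "placement": rank,
                    "orientation": ORIENT_CHAR[placement.orientation],
                    "evidence": placement.evidence,
                }
            )
            for marker, aln in placement.retained_markers:
                links_after.append(
                    {
                        "marker": marker.id,
                        "cm": marker.cm,
                        "bp": aln.position,
                        "status": "retained",
                    }
                )
        for sid, m, bp in rows_before:
            if m.id in discard_status:
                links_after.append(
                    {"marker": m.id, "cm": m.cm, "bp": bp, "status": discard_status[m.id][2]}
                )
        nodes_after = sorted(
            {p.nodes[i].cm for p, _, _ in layout.get(lg, []) for i in range(len(p.nodes))}
        )
        view_a = lg_json_view(lg, "after", nodes_after, rows_after, links_after)
        for view, tag in ((view_b, "before"), (view_a, "after")):
            validate_lg_json(view)
            with open(os.path.join(out_dir, f"{lg}.{tag}.json"), "w") as fh:
                json.dump(view, fh, indent=1)

    # --- per-modified-scaffold logs
    by_origin: dict[str, list[SplitRecord]] = {}
    for rec in chromonome.provenance:
        by_origin.setdefault(rec.origin_id, []).append(rec)
    for origin, recs in by_origin.items():
        with open(os.path.join(out_dir, f"scaffold_{origin}.log"), "w") as fh:
            fh.write("origin\tsplit_bp\tgap_kind\treason\n")
            for rec in sorted(recs, key=lambda r: r.origin_bp):
                fh.write(f"{origin}\t{rec.origin_bp}\t{rec.gap_kind}\t{rec.reason}\n")

    # --- promising scaffolds: marker-bearing inputs that were not integrated
    placed_origins = {
        chromonome.scaffolds[p.scaffold_id].origin_id
        for placements in chromonome.chromosomes.values()
        for p, _ in placements
    }
    promising = []
    for sid, hits in initial_hits.items():
        if hits and sid not in placed_origins:
            reasons = sorted(
                {reason for _, _, reason in discards.get(sid, [])}
            ) or ["markers present but not anchored"]
            promising.append((sid, len(hits), "; ".join(reasons)))
    with open(os.path.join(out_dir, "promising_scaffolds.tsv"), "w") as fh:
        fh.write("scaffold\tn_markers\treason\n")
        for sid, n, reason in sorted(promising):
            fh.write(f"{sid}\t{n}\t{reason}\n")

    # --- summary
    n_markers_retained = len(retained_status)
    n_markers_discarded = len(discard_status)
    chrom_lengths = {}
    for lg, rows in layout.items():
        if rows:
            placement, name, offset = rows[-1]
            chrom_lengths[name] = offset + chromonome.scaffolds[placement.scaffold_id].length
    summary = {
        "n_chromosomes": len(chrom_lengths),
        "n_scaffolds_integrated": sum(len(v) for v in chromonome.chromosomes.values()),
        "n_scaffolds_unplaced": len(chromonome.unplaced),
        "n_splits": len(chromonome.provenance),
        "n_markers_retained": n_markers_retained,
        "n_markers_discarded": n_markers_discarded,
        "chromosome_lengths": chrom_lengths,
    }
    with open(os.path.join(out_dir, "summary.tsv"), "w") as fh:
        for key, value in summary.items():
            if key == "chromosome_lengths":
                for name, length in value.items():
                    fh.write(f"chromosome_length\t{name}\t{length}\n")
            else:
                fh.write(f"{key}\t{value}\n")
    return summary
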