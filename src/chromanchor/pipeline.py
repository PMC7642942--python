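"""End-to-end orchestration of the integration stages.

The stage order follows the hierarchy of trust — contigs first, then the
linkage map, scaffolding, read depth, and finally conserved synteny:

1. insert virtual gaps from depth of coverage (if supplied);
2. split inter-linkage-group scaffolds at real or virtual gaps;
3. (optional) rescaffold: map-priority splitting inside gapless contigs;
4. model each linkage group as a graph, scaffolds anchored to cM nodes;
5. find consistent marker sets, split intra-LG conflicts, re-orient;
6. (optional) order/orient map-ambiguous scaffolds by conserved synteny;

then strip unused virtual gaps, build the chromonome and emit artifacts.
The pipeline is deterministic: identical inputs yield identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from . import builder, depth_gaps, inter_lg, lg_graph, rescaffold, synteny
from .datamodel import (
    Chromonome,
    FatalInputError,
    Marker,
    MarkerHit,
    Scaffold,
    SplitRecord,
    ValidationReport,
    join_markers,
    validate_inputs,
)
from .io_formats import (
    read_agp,
    read_alignments,
    read_annotation,
    read_depth,
    read_fasta,
    read_map,
    read_orthologs,
)


class ConfigError(ValueError):
    """The run configuration is incomplete or inconsistent."""


@dataclass
class RunConfig:
    agp: str
    map: str
    alignments: str
    out_dir: str
    fasta: str | None = None
    depth: str | None = None
    focal_gff: str | None = None
    external_gff: str | None = None
    orthologs: str | None = None
    rescaffold_enabled: bool = False
    synteny_enabled: bool = False
    depth_window_size: int = depth_gaps.DEFAULT_WINDOW_SIZE
    depth_step: int = depth_gaps.DEFAULT_STEP
    depth_threshold_sd: float = depth_gaps.DEFAULT_THRESHOLD_SD
    gap_length: int = 100
    fragment_name_pattern: str = "{id}__{n}"
    min_mapq: int = 0
    min_split_support: int = 2
    chrom_prefix: str = ""
    synteny_trim_prop: float = synteny.DEFAULT_TRIM_PROP
    synteny_k_sd: float = synteny.DEFAULT_K_SD

    def check(self) -> None:
        for path in (self.agp, self.map, self.alignments):
            if not os.path.exists(path):
                raise ConfigError(f"required input missing: {path}")
        if self.synteny_enabled and not (
            self.focal_gff and self.external_gff and self.orthologs
        ):
            raise ConfigError(
                "synteny requires focal annotations, external annotations "
                "and an ortholog table"
            )
        for path in (self.fasta, self.depth, self.focal_gff, self.external_gff, self.orthologs):
            if path and not os.path.exists(path):
                raise ConfigError(f"input missing: {path}")


@dataclass
class RunResult:
    chromonome: Chromonome
    validation: ValidationReport
    summary: dict
    score_inputs: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _merge_discards(into: dict[str, list], frm: dict[str, list]) -> None:
    for sid, items in frm.items():
        into.setdefault(sid, []).extend(items)


def run(config: RunConfig) -> RunResult:
    config.check()
    log: list[str] = []

    scaffold_list = read_agp(config.agp)
    scaffolds: dict[str, Scaffold] = {}
    for scaf in scaffold_list:
        if scaf.id in scaffolds:
            raise FatalInputError(f"duplicate scaffold id {scaf.id}")
        scaffolds[scaf.id] = scaf
    markers: dict[str, Marker] = {m.id: m for m in read_map(config.map)}
    alignments = read_alignments(config.alignments, config.min_mapq)
    validation = validate_inputs(scaffolds, markers, alignments)
    if not validation.is_clean():
        log.append(
            "validation: "
            f"{len(validation.markers_without_alignment)} unaligned markers, "
            f"{len(validation.alignments_unknown_scaffold)} alignments to unknown scaffolds, "
            f"{len(validation.markers_absent_from_map)} aligned markers absent from map"
        )
    hits = join_markers(markers, alignments, scaffolds)
    initial_hits = {sid: list(h) for sid, h in hits.items()}
    initial_scaffolds = dict(scaffolds)
    discards: dict[str, list] = {}
    split_records: list[SplitRecord] = []

    # stage 1: virtual gaps from depth of coverage
    if config.depth:
        lengths = {sid: s.length for sid, s in scaffolds.items()}
        n_virtual = 0
        for profile in read_depth(config.depth, lengths):
            stats = depth_gaps.window_depth(
                profile, config.depth_window_size, config.depth_step
            )
            n_virtual += depth_gaps.insert_virtual_gaps(
                scaffolds[profile.scaffold_id], stats, config.depth_threshold_sd, profile
            )
        log.append(f"depth: inserted {n_virtual} virtual gaps")

    # stage 2: inter-linkage-group conflicts
    scaffolds, hits, disc, recs = inter_lg.resolve_inter_lg(
        scaffolds, hits, config.fragment_name_pattern, config.min_split_support
    )
    _merge_discards(discards, disc)
    split_records.extend(recs)
    log.append(f"inter-LG: {len(recs)} splits, {sum(len(v) for v in disc.values())} markers discarded")

    # stage 3: optional map-priority rescaffolding
    if config.rescaffold_enabled:
        scaffolds, hits, disc, recs, lines = rescaffold.resolve_rescaffold(
            scaffolds, hits, config.fragment_name_pattern, config.min_split_support
        )
        _merge_discards(discards, disc)
        split_records.extend(recs)
        log.extend(lines)
        log.append(
            f"rescaffold: {len(recs)} splits, "
            f"{sum(len(v) for v in disc.values())} markers discarded"
        )

    # stages 4-5: linkage-group graphs, consistent sets, intra-LG splits
    hits_by_lg: dict[str, dict[str, list[MarkerHit]]] = {}
    for sid, shits in hits.items():
        if not shits:
            continue
        lg = shits[0][0].linkage_group
        hits_by_lg.setdefault(lg, {})[sid] = shits
    graphs: dict[str, lg_graph.LinkageGroupGraph] = {}
    for lg in sorted(hits_by_lg):
        graph = lg_graph.build_lg_graph(lg, hits_by_lg[lg])
        for placement in graph.placements:
            lg_graph.consistent_marker_set(placement)
            for marker, aln, reason in placement.discarded_markers:
                origin = scaffolds[placement.scaffold_id].origin_id
                discards.setdefault(origin, []).append((marker, aln, reason))
        recs, disc = lg_graph.split_intra_lg(
            graph, scaffolds, config.fragment_name_pattern, config.min_split_support
        )
        split_records.extend(recs)
        _merge_discards(discards, disc)  # keyed by origin scaffold id
        lg_graph.finalize_orientation(graph)
        graphs[lg] = graph
    log.append(f"graphs: {len(graphs)} linkage groups")

    # stage 6: conserved synteny for map-ambiguous scaffolds
    if config.synteny_enabled:
        focal_genes = read_annotation(config.focal_gff)
        external_genes = read_annotation(config.external_gff)
        orthologs = read_orthologs(config.orthologs)
        result = synteny.apply_synteny(
            graphs,
            scaffolds,
            focal_genes,
            external_genes,
            orthologs,
            config.gap_length,
            config.synteny_trim_prop,
            config.synteny_k_sd,
        )
        log.extend(result.log)
        log.append(
            f"synteny: ordered {result.scaffolds_ordered} and oriented "
            f"{result.scaffolds_oriented} scaffolds across {result.ordered_nodes} nodes"
        )

    # strip unused virtual gaps, assemble, emit
    scaffolds = depth_gaps.strip_unused_virtual_gaps(scaffolds)
    chromonome = builder.build_chromonome(
        graphs, scaffolds, split_records, config.gap_length
    )

    os.makedirs(config.out_dir, exist_ok=True)
    chrom_name = lambda lg: f"{config.chrom_prefix}{lg}"  # noqa: E731
    builder.emit_agp(
        chromonome,
        os.path.join(config.out_dir, "chromonome.agp"),
        os.path.join(config.out_dir, "unplaced.agp"),
        chrom_name,
    )
    if config.fasta:
        source_seqs = read_fasta(config.fasta)
        builder.emit_fasta(
            chromonome, source_seqs, os.path.join(config.out_dir, "chromonome.fasta"), chrom_name
        )
    if config.focal_gff:
        lift_log = builder.translate_annotations(
            config.focal_gff,
            chromonome,
            "to_chromonome",
            os.path.join(config.out_dir, "annotations.chromonome.gff3"),
            chrom_name,
        )
        log.extend(f"liftover: {line}" for line in lift_log)
    summary = builder.emit_reports(
        config.out_dir,
        markers,
        initial_hits,
        initial_scaffolds,
        chromonome,
        discards,
        chrom_name,
    )
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        for line in log:
            fh.write(line + "\n")
    return RunResult(
        chromonome,
        validation,
        summary,
        score_inputs={"discards": discards},
        log=log,
    )
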