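"""Order and orient map-ambiguous scaffolds with conserved gene synteny.

The genetic map cannot orient a scaffold anchored at a single cM node, nor
order several scaffolds sharing one node.  For those scaffolds — and only
those; synteny evidence is subordinate to map evidence — orthologous gene
order from a related genome is consulted.  Per linkage group the orthologous
external chromosome is identified (plurality vote) and its relative
orientation fixed by regressing external gene positions on the positions the
definitively map-oriented scaffolds project into the provisional chromosome.
Within each ambiguous node, off-chromosome orthologs, positional outliers
(trimmed-mean filter) and order-incongruent genes (longest monotone
subsequence per scaffold) are discarded; the survivors order the scaffolds by
median external position and orient each by regression sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

from .datamodel import FORWARD, REVERSE, UNORIENTED, Scaffold, ScaffoldPlacement
from .io_formats import GeneAnnotation, OrthologPair
from .lg_graph import LinkageGroupGraph, ols_slope

DEFAULT_TRIM_PROP = 0.2
DEFAULT_K_SD = 3.0


@dataclass
class GenePair:
    focal: GeneAnnotation  # coordinates local to the final scaffold fragment
    external: GeneAnnotation

    @property
    def focal_mid(self) -> float:
        return (self.focal.beg + self.focal.end) / 2.0

    @property
    def external_mid(self) -> float:
        return (self.external.beg + self.external.end) / 2.0


@dataclass
class SyntenyContext:
    linkage_group: str
    external_chromosome: str
    reversed: bool

    def transform(self, external_bp: float) -> float:
        return -external_bp if self.reversed else external_bp


@dataclass
class SyntenyResult:
    contexts: dict[str, SyntenyContext] = field(default_factory=dict)
    ordered_nodes: int = 0
    scaffolds_ordered: int = 0
    scaffolds_oriented: int = 0
    log: list[str] = field(default_factory=list)


def genes_on_fragments(
    focal_genes: list[GeneAnnotation],
    orthologs: list[OrthologPair],
    external_genes: list[GeneAnnotation],
    scaffolds: dict[str, Scaffold],
) -> dict[str, list[GenePair]]:
    """Map input-scaffold gene annotations onto final fragments.

    A gene lands on the fragment whose origin slice fully contains it (genes
    straddling a split point are dropped); its coordinates become local to
    the fragment.  Only genes with an ortholog are kept."""
    ext_by_id = {g.gene_id: g for g in external_genes}
    ortho = {p.focal_gene_id: p.external_gene_id for p in orthologs}
    frags_by_origin: dict[str, list[Scaffold]] = {}
    for scaf in scaffolds.values():
        frags_by_origin.setdefault(scaf.origin_id, []).append(scaf)
    out: dict[str, list[GenePair]] = {}
    for gene in focal_genes:
        ext_id = ortho.get(gene.gene_id)
        if ext_id is None or ext_id not in ext_by_id:
            continue
        for frag in frags_by_origin.get(gene.sequence_id, []):
            if frag.origin_beg <= gene.beg and gene.end <= frag.origin_beg + frag.length:
                local = GeneAnnotation(
                    gene.gene_id,
                    frag.id,
                    gene.beg - frag.origin_beg,
                    gene.end - frag.origin_beg,
                    gene.strand,
                )
                out.setdefault(frag.id, []).append(GenePair(local, ext_by_id[ext_id]))
                break
    return out


def orient_external_chromosome(
    graph: LinkageGroupGraph,
    gene_pairs: dict[str, list[GenePair]],
    gap_length: int,
    scaffolds: dict[str, Scaffold],
) -> SyntenyContext | None:
    """Pick the plurality external chromosome for a linkage group and decide
    whether it runs with or against the map, using only definitively
    map-oriented scaffolds projected into the provisional chromosome."""
    lg_pairs = [
        pair
        for placement in graph.placements
        for pair in gene_pairs.get(placement.scaffold_id, [])
    ]
    if not lg_pairs:
        return None
    votes = Counter(pair.external.sequence_id for pair in lg_pairs)
    ext_chrom = max(votes, key=lambda c: (votes[c], c))

    # provisional projection: placements in cM order, fixed inter-scaffold gaps
    ordered = sorted(graph.placements, key=lambda p: (p.cm_first, p.cm_last, p.scaffold_id))
    xs: list[float] = []
    ys: list[float] = []
    offset = 0
    for placement in ordered:
        length = scaffolds[placement.scaffold_id].length
        if placement.definitive:
            pairs = [
                p
                for p in gene_pairs.get(placement.scaffold_id, [])
                if p.external.sequence_id == ext_chrom
            ]
            if len(pairs) >= 2:
                for pair in pairs:
                    local = pair.focal_mid
                    if placement.orientation == REVERSE:
                        local = length - local
                    xs.append(offset + local)
                    ys.append(pair.external_mid)
        offset += length + gap_length
    if len(xs) < 2:
        return None
    slope = ols_slope(xs, ys)
    if slope == 0:
        return None
    return SyntenyContext(graph.linkage_group, ext_chrom, reversed=slope < 0)


def _trimmed_stats(values: list[float], trim_prop: float) -> tuple[float, float]:
    ordered = sorted(values)
    g = int(len(ordered) * trim_prop)
    trimmed = ordered[g : len(ordered) - g] if g else ordered
    mean = sum(trimmed) / len(trimmed)
    var = sum((v - mean) ** 2 for v in trimmed) / len(trimmed)
    return mean, var**0.5


def _longest_monotone_pairs(pairs: list[GenePair], decreasing: bool) -> list[GenePair]:
    ordered = sorted(pairs, key=lambda p: p.focal_mid)
    xs = [p.external_mid for p in ordered]
    n = len(xs)

    def ok(a: float, b: float) -> bool:
        return b <= a if decreasing else a <= b

    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if ok(xs[j], xs[i]) and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    if n == 0:
        return []
    end = max(range(n), key=lambda i: best[i])
    keep = []
    while end != -1:
        keep.append(ordered[end])
        end = prev[end]
    return keep[::-1]


def filter_congruent_genes(
    pairs: list[GenePair],
    context: SyntenyContext,
    trim_prop: float = DEFAULT_TRIM_PROP,
    k_sd: float = DEFAULT_K_SD,
) -> list[GenePair]:
    """Retain the congruently ordered gene set for one scaffold.

    Drops off-chromosome orthologs, then positional outliers beyond
    ``k_sd`` trimmed standard deviations of the trimmed mean external
    position, then order-incongruent genes (the larger of the longest
    non-decreasing / non-increasing subsequences survives — the scaffold's
    own orientation is still unknown)."""
    on_chrom = [p for p in pairs if p.external.sequence_id == context.external_chromosome]
    if len(on_chrom) >= 3:
        mean, sd = _trimmed_stats([p.external_mid for p in on_chrom], trim_prop)
        if sd > 0:
            on_chrom = [p for p in on_chrom if abs(p.external_mid - mean) <= k_sd * sd]
    if not on_chrom:
        return []
    inc = _longest_monotone_pairs(on_chrom, decreasing=False)
    dec = _longest_monotone_pairs(on_chrom, decreasing=True)
    return inc if len(inc) >= len(dec) else dec


def order_and_orient_node(
    placements: list[ScaffoldPlacement],
    retained: dict[str, list[GenePair]],
    context: SyntenyContext,
) -> tuple[int, int]:
    """Order the placements of one ambiguous node by median external gene
    position and orient each map-unoriented scaffold by regression sign.

    Scaffolds without retained genes keep their fallback order, after the
    gene-supported ones.  Returns (n ordered, n oriented).  Map-assigned
    node membership and map orientations are never altered."""
    with_genes = [p for p in placements if retained.get(p.scaffold_id)]
    ordered = 0
    if len(with_genes) >= 2:
        medians = {}
        for p in with_genes:
            exts = sorted(context.transform(g.external_mid) for g in retained[p.scaffold_id])
            medians[p.scaffold_id] = exts[len(exts) // 2]
        for rank, p in enumerate(
            sorted(with_genes, key=lambda p: (medians[p.scaffold_id], p.scaffold_id))
        ):
            p.synteny_rank = rank
            p.evidence = "synteny"
            ordered += 1
    oriented = 0
    for p in placements:
        genes = retained.get(p.scaffold_id, [])
        if p.orientation != UNORIENTED or len(genes) < 2:
            continue
        slope = ols_slope(
            [g.focal_mid for g in genes],
            [context.transform(g.external_mid) for g in genes],
        )
        if slope > 0:
            p.orientation = FORWARD
        elif slope < 0:
            p.orientation = REVERSE
        else:
            continue
        p.evidence = "synteny"
        oriented += 1
    return ordered, oriented


def apply_synteny(
    graphs: dict[str, LinkageGroupGraph],
    scaffolds: dict[str, Scaffold],
    focal_genes: list[GeneAnnotation],
    external_genes: list[GeneAnnotation],
    orthologs: list[OrthologPair],
    gap_length: int = 100,
    trim_prop: float = DEFAULT_TRIM_PROP,
    k_sd: float = DEFAULT_K_SD,
) -> SyntenyResult:
    """Run the synteny stage over every linkage group (ambiguous nodes only)."""
    result = SyntenyResult()
    gene_pairs = genes_on_fragments(focal_genes, orthologs, external_genes, scaffolds)
    for lg, graph in graphs.items():
        context = orient_external_chromosome(graph, gene_pairs, gap_length, scaffolds)
        if context is None:
            result.log.append(f"{lg}: no usable synteny context; skipped")
            continue
        result.contexts[lg] = context
        # ambiguous groups: placements confined to one node, grouped per node
        by_node: dict[int, list[ScaffoldPlacement]] = {}
        for placement in graph.placements:
            if len(placement.nodes) == 1:
                by_node.setdefault(id(placement.nodes[0]), []).append(placement)
        for group in by_node.values():
            needs_order = len(group) >= 2
            needs_orient = any(p.orientation == UNORIENTED for p in group)
            if not (needs_order or needs_orient):
                continue
            retained = {
                p.scaffold_id: filter_congruent_genes(
                    gene_pairs.get(p.scaffold_id, []), context, trim_prop, k_sd
                )
                for p in group
            }
            if sum(len(v) for v in retained.values()) < 2:
                result.log.append(
                    f"{lg}: node at cM {group[0].nodes[0].cm} left unordered "
                    "(<2 congruent genes)"
                )
                continue
            n_ord, n_ori = order_and_orient_node(group, retained, context)
            result.scaffolds_ordered += n_ord
            result.scaffolds_oriented += n_ori
            if n_ord:
                result.ordered_nodes += 1
    return result
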