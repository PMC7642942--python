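"""Core domain model shared by every pipeline stage.

All coordinates in this package are 0-based and half-open.  The 1-based,
inclusive conventions of AGP, SAM and GFF are converted at the I/O boundary
(:mod:`chromanchor.io_formats`), so every in-memory structure speaks a single
coordinate dialect.

The model mirrors how an AGP file describes an assembly: a :class:`Scaffold`
is an ordered list of :class:`AssemblyComponent` rows (contigs and gaps) whose
object spans tile ``[0, length)`` exactly.  *Virtual gaps* are zero-length
placeholder components inserted at depth-of-coverage anomalies; they license a
split inside otherwise gapless sequence and are stripped before output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

CONTIG = "contig"
GAP = "gap"
VIRTUAL_GAP = "virtual_gap"

FORWARD = "forward"
REVERSE = "reverse"
UNORIENTED = "unoriented"


class ModelError(ValueError):
    """A domain invariant was violated."""


class FatalInputError(ValueError):
    """An input is unusable (empty assembly or empty map)."""


@dataclass
class AssemblyComponent:
    """One AGP row: a contig placement or a (possibly virtual) gap.

    ``object_beg``/``object_end`` locate the component on its scaffold;
    ``component_beg``/``component_end`` locate the used slice of the contig
    (contigs only).  ``gap_type``/``linkage``/``evidence`` carry the AGP gap
    columns through round trips.
    """

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    kind: str
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    gap_length: int | None = None
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "paired-ends"

    def __post_init__(self) -> None:
        if self.object_beg < 0 or self.object_end < self.object_beg:
            raise ModelError(
                f"{self.object_id}: bad object span "
                f"[{self.object_beg}, {self.object_end})"
            )
        if self.kind == CONTIG:
            if self.component_id is None:
                raise ModelError(f"{self.object_id}: contig without component_id")
            if self.orientation not in ("+", "-", "?"):
                raise ModelError(
                    f"{self.object_id}/{self.component_id}: "
                    f"bad orientation {self.orientation!r}"
                )
            clen = (self.component_end or 0) - (self.component_beg or 0)
            if clen != self.length or clen <= 0:
                raise ModelError(
                    f"{self.object_id}/{self.component_id}: component span "
                    f"length {clen} != object span length {self.length}"
                )
        elif self.kind == GAP:
            if self.gap_length is None or self.gap_length != self.length or self.gap_length < 1:
                raise ModelError(
                    f"{self.object_id}: gap length {self.gap_length} inconsistent "
                    f"with object span length {self.length}"
                )
        elif self.kind == VIRTUAL_GAP:
            if self.length != 0 or self.gap_length not in (0, None):
                raise ModelError(f"{self.object_id}: virtual gap must have zero length")
            self.gap_length = 0
        else:
            raise ModelError(f"unknown component kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.object_end - self.object_beg

    @property
    def is_gap(self) -> bool:
        return self.kind in (GAP, VIRTUAL_GAP)


@dataclass
class Scaffold:
    """An ordered, validated run of components.

    ``origin_id``/``origin_beg`` track sequence provenance: every scaffold or
    split fragment is a contiguous slice ``[origin_beg, origin_beg + length)``
    of the input scaffold named ``origin_id``, which is all that is needed to
    slice its sequence out of the input FASTA (virtual gaps have zero length,
    so they never perturb this mapping).
    """

    id: str
    components: list[AssemblyComponent]
    origin_id: str | None = None
    origin_beg: int = 0

    def __post_init__(self) -> None:
        if self.origin_id is None:
            self.origin_id = self.id
        self.validate()

    @property
    def length(self) -> int:
        return self.components[-1].object_end if self.components else 0

    def validate(self) -> None:
        pos = 0
        for i, comp in enumerate(self.components):
            if comp.object_beg != pos:
                raise ModelError(
                    f"{self.id}: component {i + 1} starts at {comp.object_beg}, "
                    f"expected {pos} (spans must tile [0, length))"
                )
            if comp.part_number != i + 1:
                raise ModelError(
                    f"{self.id}: component {i + 1} has part_number {comp.part_number}"
                )
            pos = comp.object_end

    def contig_ids(self) -> list[str]:
        return [c.component_id for c in self.components if c.kind == CONTIG]

    def gap_indices(self, virtual: bool = True) -> list[int]:
        kinds = (GAP, VIRTUAL_GAP) if virtual else (GAP,)
        return [i for i, c in enumerate(self.components) if c.kind in kinds]

    def _renumbered(self, comps: list[AssemblyComponent], new_id: str) -> list[AssemblyComponent]:
        out = []
        pos = 0
        for n, c in enumerate(comps, start=1):
            out.append(
                replace(
                    c,
                    object_id=new_id,
                    object_beg=pos,
                    object_end=pos + c.length,
                    part_number=n,
                )
            )
            pos += c.length
        return out

    def split_at_component(
        self, gap_index: int, left_id: str, right_id: str
    ) -> tuple["Scaffold", "Scaffold"]:
        """Cut at a gap component, consuming it, and return the two fragments."""
        gap = self.components[gap_index]
        if not gap.is_gap:
            raise ModelError(f"{self.id}: split point part {gap_index + 1} is not a gap")
        left = Scaffold(
            left_id,
            self._renumbered(self.components[:gap_index], left_id),
            origin_id=self.origin_id,
            origin_beg=self.origin_beg,
        )
        right = Scaffold(
            right_id,
            self._renumbered(self.components[gap_index + 1 :], right_id),
            origin_id=self.origin_id,
            origin_beg=self.origin_beg + gap.object_end,
        )
        return left, right

    def insert_virtual_gap(self, pos: int) -> bool:
        """Insert a zero-length virtual gap at scaffold position ``pos``.

        Returns False (no-op) when ``pos`` is at the scaffold edge, abuts an
        existing gap, or duplicates an existing virtual gap.
        """
        if pos <= 0 or pos >= self.length:
            return False
        for i, comp in enumerate(self.components):
            if comp.object_beg == pos or comp.object_end == pos:
                if comp.is_gap:
                    return False
            if comp.object_beg == pos:
                # boundary between two contigs: place the gap between them
                vgap = AssemblyComponent(
                    object_id=self.id,
                    object_beg=pos,
                    object_end=pos,
                    part_number=comp.part_number,
                    kind=VIRTUAL_GAP,
                    gap_length=0,
                    linkage="no",
                    evidence="na",
                )
                new = self.components[:i] + [vgap] + self.components[i:]
                self.components = self._renumbered(new, self.id)
                self.validate()
                return True
            if comp.object_beg < pos < comp.object_end:
                if comp.is_gap:
                    return False  # never split a real gap
                off = pos - comp.object_beg
                if comp.orientation == "-":
                    # object-left maps to component-right
                    cut = comp.component_end - off
                    left = replace(comp, object_end=pos, component_beg=cut)
                    right = replace(comp, object_beg=pos, component_end=cut)
                else:
                    cut = comp.component_beg + off
                    left = replace(comp, object_end=pos, component_end=cut)
                    right = replace(comp, object_beg=pos, component_beg=cut)
                vgap = AssemblyComponent(
                    object_id=self.id,
                    object_beg=pos,
                    object_end=pos,
                    part_number=comp.part_number,
                    kind=VIRTUAL_GAP,
                    gap_length=0,
                    linkage="no",
                    evidence="na",
                )
                new = self.components[:i] + [left, vgap, right] + self.components[i + 1 :]
                self.components = self._renumbered(new, self.id)
                self.validate()
                return True
        return False

    def strip_virtual_gaps(self) -> "Scaffold":
        """Remove unused virtual gaps, re-merging the contig pieces they split."""
        out: list[AssemblyComponent] = []
        merge_next = False
        for comp in self.components:
            if comp.kind == VIRTUAL_GAP:
                merge_next = True
                continue
            if merge_next and out:
                prev = out[-1]
                if (
                    prev.kind == CONTIG
                    and comp.kind == CONTIG
                    and prev.component_id == comp.component_id
                    and prev.orientation == comp.orientation
                    and (
                        (prev.orientation != "-" and prev.component_end == comp.component_beg)
                        or (prev.orientation == "-" and comp.component_end == prev.component_beg)
                    )
                ):
                    if prev.orientation == "-":
                        cbeg, cend = comp.component_beg, prev.component_end
                    else:
                        cbeg, cend = prev.component_beg, comp.component_end
                    out[-1] = replace(
                        prev,
                        object_end=comp.object_end,
                        component_beg=cbeg,
                        component_end=cend,
                    )
                    merge_next = False
                    continue
            merge_next = False
            out.append(comp)
        return Scaffold(
            self.id,
            self._renumbered(out, self.id),
            origin_id=self.origin_id,
            origin_beg=self.origin_beg,
        )


@dataclass(frozen=True)
class Marker:
    id: str
    linkage_group: str
    cm: float


@dataclass(frozen=True)
class MarkerAlignment:
    marker_id: str
    scaffold_id: str
    position: int  # leftmost aligned base, 0-based
    strand: str
    mapped: bool = True


# A map marker joined to its alignment; the currency of every stage.
MarkerHit = tuple[Marker, MarkerAlignment]


@dataclass(eq=False)
class MapNode:
    """One distinct cM position of one linkage group.

    Identity semantics (no structural equality): nodes and placements
    reference each other."""

    linkage_group: str
    cm: float
    anchors: list["ScaffoldPlacement"] = field(default_factory=list)


@dataclass(eq=False)
class ScaffoldPlacement:
    """A scaffold (fragment) anchored to a run of map nodes.

    Identity semantics (no structural equality): nodes and placements
    reference each other."""

    scaffold_id: str
    nodes: list[MapNode]
    orientation: str = UNORIENTED
    retained_markers: list[MarkerHit] = field(default_factory=list)
    discarded_markers: list[tuple[Marker, MarkerAlignment, str]] = field(default_factory=list)
    definitive: bool = False
    slope: float = 0.0
    evidence: str = "map"
    synteny_rank: int | None = None

    @property
    def cm_first(self) -> float:
        return self.nodes[0].cm

    @property
    def cm_last(self) -> float:
        return self.nodes[-1].cm

    def bp_interval(self) -> tuple[int, int]:
        bps = [aln.position for _, aln in self.retained_markers]
        return (min(bps), max(bps))


@dataclass(frozen=True)
class SplitRecord:
    scaffold_id: str  # the scaffold that was cut (possibly itself a fragment)
    origin_id: str  # input scaffold the cut traces back to
    origin_bp: int  # cut position in input-scaffold coordinates
    gap_kind: str  # "gap" or "virtual_gap"
    reason: str


@dataclass
class Chromonome:
    """Final ordered/oriented placements per linkage group."""

    # lg -> ordered list of (placement, gap length separating it from the next)
    chromosomes: dict[str, list[tuple[ScaffoldPlacement, int]]]
    scaffolds: dict[str, Scaffold]  # every final sequence unit, placed or not
    unplaced: list[Scaffold]
    provenance: list[SplitRecord]

    def placed_ids(self) -> list[str]:
        return [
            p.scaffold_id
            for placements in self.chromosomes.values()
            for p, _ in placements
        ]


@dataclass
class ValidationReport:
    markers_without_alignment: list[str] = field(default_factory=list)
    alignments_unknown_scaffold: list[str] = field(default_factory=list)
    markers_absent_from_map: list[str] = field(default_factory=list)

    def is_clean(self) -> bool:
        return not (
            self.markers_without_alignment
            or self.alignments_unknown_scaffold
            or self.markers_absent_from_map
        )


def validate_inputs(
    scaffolds: dict[str, Scaffold],
    markers: dict[str, Marker],
    alignments: list[MarkerAlignment],
) -> ValidationReport:
    """Cross-check the three mandatory inputs; IDs must match between files."""
    if not scaffolds:
        raise FatalInputError("assembly is empty")
    if not markers:
        raise FatalInputError("genetic map is empty")
    report = ValidationReport()
    aligned = {a.marker_id for a in alignments if a.mapped}
    for mid in markers:
        if mid not in aligned:
            report.markers_without_alignment.append(mid)
    for aln in alignments:
        if aln.mapped and aln.scaffold_id not in scaffolds:
            report.alignments_unknown_scaffold.append(
                f"{aln.marker_id}: unknown scaffold {aln.scaffold_id}"
            )
        if aln.marker_id not in markers:
            report.markers_absent_from_map.append(aln.marker_id)
    return report


def join_markers(
    markers: dict[str, Marker],
    alignments: list[MarkerAlignment],
    scaffolds: dict[str, Scaffold],
) -> dict[str, list[MarkerHit]]:
    """Group usable (mapped, known-scaffold, in-map) hits per scaffold, bp-sorted."""
    by_scaffold: dict[str, list[MarkerHit]] = {}
    for aln in alignments:
        if not aln.mapped or aln.scaffold_id not in scaffolds:
            continue
        marker = markers.get(aln.marker_id)
        if marker is None:
            continue
        by_scaffold.setdefault(aln.scaffold_id, []).append((marker, aln))
    for hits in by_scaffold.values():
        hits.sort(key=lambda h: (h[1].position, h[0].id))
    return by_scaffold
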