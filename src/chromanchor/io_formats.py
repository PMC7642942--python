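"""Readers and writers for every external format the tool touches.

Coordinate conversions happen here and nowhere else: AGP, SAM, GFF and the
samtools-depth table are 1-based inclusive on disk and 0-based half-open in
memory.  Writers and readers are exact inverses on valid models; readers
reject files that violate the named standard.

Formats: AGP v2.1, 3-column map TSV (marker id, linkage group, cM), SAM/BAM
via pysam, samtools-depth 3-column TSV, GFF3/GTF gene annotations, 2-column
ortholog TSV, FASTA via pyfaidx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .datamodel import (
    CONTIG,
    GAP,
    VIRTUAL_GAP,
    AssemblyComponent,
    Marker,
    MarkerAlignment,
    ModelError,
    Scaffold,
)


class ParseError(ValueError):
    """An input file violates its format standard."""


# ---------------------------------------------------------------------------
# AGP v2.1


def read_agp(path: str) -> list[Scaffold]:
    """Parse an AGP v2 file into scaffolds with contiguous components."""
    per_object: dict[str, list[AssemblyComponent]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            obj, beg, end, part, kind = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                obeg, oend, pnum = int(beg) - 1, int(end), int(part)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if kind == "W":
                try:
                    comp = AssemblyComponent(
                        object_id=obj,
                        object_beg=obeg,
                        object_end=oend,
                        part_number=pnum,
                        kind=CONTIG,
                        component_id=fields[5],
                        component_beg=int(fields[6]) - 1,
                        component_end=int(fields[7]),
                        orientation=fields[8],
                    )
                except (ValueError, ModelError) as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
            elif kind in ("N", "U"):
                try:
                    comp = AssemblyComponent(
                        object_id=obj,
                        object_beg=obeg,
                        object_end=oend,
                        part_number=pnum,
                        kind=GAP,
                        gap_length=int(fields[5]),
                        gap_type=fields[6],
                        linkage=fields[7],
                        evidence=fields[8] if len(fields) > 8 else "na",
                    )
                except (ValueError, ModelError) as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
            else:
                raise ParseError(f"{path}:{lineno}: unknown component type {kind!r}")
            if obj not in per_object:
                order.append(obj)
            per_object.setdefault(obj, []).append(comp)

    scaffolds = []
    for obj in order:
        comps = sorted(per_object[obj], key=lambda c: c.part_number)
        try:
            scaffolds.append(Scaffold(obj, comps))
        except ModelError as exc:
            raise ParseError(f"{path}: object {obj}: {exc}") from exc
    return scaffolds


def write_agp(scaffolds: list[Scaffold], path: str) -> None:
    """Write AGP v2.1.  Virtual gaps must have been stripped beforehand."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for scaf in scaffolds:
            for comp in scaf.components:
                if comp.kind == VIRTUAL_GAP:
                    raise ModelError(
                        f"{scaf.id}: residual virtual gap at {comp.object_beg}; "
                        "strip virtual gaps before writing AGP"
                    )
                if comp.kind == CONTIG:
                    row = [
                        scaf.id,
                        str(comp.object_beg + 1),
                        str(comp.object_end),
                        str(comp.part_number),
                        "W",
                        comp.component_id,
                        str(comp.component_beg + 1),
                        str(comp.component_end),
                        comp.orientation,
                    ]
                else:
                    row = [
                        scaf.id,
                        str(comp.object_beg + 1),
                        str(comp.object_end),
                        str(comp.part_number),
                        "N",
                        str(comp.gap_length),
                        comp.gap_type,
                        comp.linkage,
                        comp.evidence,
                    ]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Genetic map TSV: marker id, linkage group, cM


def read_map(path: str) -> list[Marker]:
    markers: list[Marker] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            mid, lg, cm_s = fields[0], fields[1], fields[2]
            if mid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate marker id {mid!r}")
            seen.add(mid)
            try:
                cm = float(cm_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cM {cm_s!r}") from exc
            if not np.isfinite(cm) or cm < 0:
                raise ParseError(f"{path}:{lineno}: cM must be finite and non-negative")
            markers.append(Marker(mid, lg, cm))
    return markers


# ---------------------------------------------------------------------------
# Marker alignments (SAM/BAM)


def read_alignments(path: str, min_mapq: int = 0) -> list[MarkerAlignment]:
    """One record per marker: the primary alignment passing ``min_mapq``.

    Secondary/supplementary records are ignored; unmapped markers are kept
    with ``mapped=False`` so they can be reported.
    """
    out: list[MarkerAlignment] = []
    seen: set[str] = set()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name in seen:
                continue
            seen.add(rec.query_name)
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                out.append(MarkerAlignment(rec.query_name, "", -1, "+", mapped=False))
                continue
            out.append(
                MarkerAlignment(
                    marker_id=rec.query_name,
                    scaffold_id=rec.reference_name,
                    position=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    mapped=True,
                )
            )
    return out


# ---------------------------------------------------------------------------
# samtools-depth table


@dataclass
class DepthProfile:
    """Dense per-bp read depth for one scaffold (absent positions are 0)."""

    scaffold_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.depths < 0):
            raise ModelError(f"{self.scaffold_id}: negative depth")


def read_depth(path: str, scaffold_lengths: dict[str, int]) -> list[DepthProfile]:
    """Read a 3-column (sequence, 1-based position, depth) samtools table."""
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["seq", "pos", "depth"],
            dtype={"seq": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        return []
    profiles = []
    for seq, group in table.groupby("seq", sort=False):
        if seq not in scaffold_lengths:
            raise ParseError(f"{path}: unknown sequence {seq!r}")
        length = scaffold_lengths[seq]
        pos = group["pos"].to_numpy() - 1
        if pos.min() < 0 or pos.max() >= length:
            raise ParseError(
                f"{path}: position {pos.max() + 1} exceeds length of {seq} ({length})"
            )
        depths = np.zeros(length, dtype=np.int64)
        depths[pos] = group["depth"].to_numpy()
        profiles.append(DepthProfile(str(seq), depths))
    return profiles


# ---------------------------------------------------------------------------
# Gene annotations (GFF3 / GTF) and ortholog pairs


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    sequence_id: str
    beg: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.beg:
            raise ModelError(f"{self.gene_id}: empty span")


@dataclass(frozen=True)
class OrthologPair:
    focal_gene_id: str
    external_gene_id: str


def _gene_id_from_attributes(attrs: str) -> str | None:
    attrs = attrs.strip()
    if "=" in attrs and '"' not in attrs:  # GFF3 dialect
        for chunk in attrs.split(";"):
            chunk = chunk.strip()
            if chunk.startswith("ID="):
                return chunk[3:]
            if chunk.startswith("gene_id="):
                return chunk[8:]
    else:  # GTF dialect
        for chunk in attrs.split(";"):
            chunk = chunk.strip()
            if chunk.startswith("gene_id"):
                return chunk.split(None, 1)[1].strip().strip('"')
    return None


def read_annotation(path: str, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneAnnotation]:
    """Extract gene features (with an id attribute) from GFF3 or GTF."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            if fields[2] not in feature_types:
                continue
            gid = _gene_id_from_attributes(fields[8])
            if gid is None:
                raise ParseError(f"{path}:{lineno}: gene feature without an id attribute")
            try:
                beg, end = int(fields[3]) - 1, int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            genes.append(GeneAnnotation(gid, fields[0], beg, end, fields[6]))
    return genes


def read_orthologs(path: str) -> list[OrthologPair]:
    """2-column TSV: focal gene id, external gene id.  Focal ids must be unique."""
    pairs: list[OrthologPair] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if fields[0] in seen:
                raise ParseError(f"{path}:{lineno}: focal gene {fields[0]!r} repeated")
            seen.add(fields[0])
            pairs.append(OrthologPair(fields[0], fields[1]))
    return pairs


# ---------------------------------------------------------------------------
# FASTA

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def read_fasta(path: str) -> dict[str, str]:
    with Fasta(path, as_raw=True, sequence_always_upper=False) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(records: list[tuple[str, str]], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
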