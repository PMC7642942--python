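"""Deterministic synthetic-data generator and ground-truth scorer.

The generator emulates the full input bundle of a map-integration run: true
chromosomes are simulated, partitioned into scaffolds with realistic
assembly gaps, and misassemblies are planted with known junctions —

* ``inter_lg_chimera``: two scaffolds from different chromosomes joined
  across a real gap (the mate-pair/scaffolding error mode);
* ``gapless_inversion``: an internal block reverse-complemented inside
  otherwise contiguous sequence, with a depth-of-coverage anomaly at both
  junctions (the long-read/optical-map error mode);
* ``intra_lg_translocation``: blocks of one scaffold reordered across real
  gaps.

Markers are placed on a fixed bp grid; their cM positions derive from true
chromosome position (``cm_per_mbp``), quantized to a map resolution that
emulates the finite crossover count of a real cross, with a configurable
fraction perturbed by genotyping noise.  A related "external" genome with
orthologous genes in true order supports the synteny stage.  All outputs are
reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .datamodel import CONTIG, GAP, AssemblyComponent, Chromonome, Scaffold

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b


@dataclass
class FixtureConfig:
    """Study conditions for a synthetic integration run."""

    seed: int
    n_chromosomes: int = 4
    chromosome_length: int = 2_000_000
    scaffolds_per_chromosome: int = 6
    small_scaffolds_per_chromosome: int = 2
    small_scaffold_length: int = 15_000
    marker_spacing: int = 10_000
    marker_length: int = 50
    cm_per_mbp: float = 25.0
    cm_resolution: float = 0.5
    genotyping_noise_rate: float = 0.02
    noise_cm_sd: float = 1.0
    n_inter_lg_chimeras: int = 3
    n_gapless_inversions: int = 2
    n_intra_lg_translocations: int = 0
    inversion_block_length: int = 100_000
    junction_clearance: int = 15_000
    gap_spacing: int = 50_000
    gap_len_min: int = 50
    gap_len_max: int = 500
    depth_mean: float = 30.0
    depth_anomaly_multiplier: float = 3.0
    depth_anomaly_halfwidth: int = 5_000
    gene_spacing: int = 6_000
    gene_length: int = 2_000
    gene_offset: int = 12_000

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes,
            self.scaffolds_per_chromosome,
            self.n_inter_lg_chimeras,
            self.n_gapless_inversions,
            self.n_intra_lg_translocations,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class _Segment:
    chrom: int
    t0: int
    t1: int
    orient: str  # '+' or '-'
    a0: int = -1  # assembly start, filled at layout

    @property
    def length(self) -> int:
        return self.t1 - self.t0


@dataclass
class _Plan:
    segments: list[_Segment]
    # joints[i] sits between segments[i] and segments[i+1]:
    # ("gap", length) or ("none", 0) for a gapless junction
    joints: list[tuple[str, int]]
    error: str | None = None


def _quantize(cm: float, resolution: float) -> float:
    return round(round(cm / resolution) * resolution, 6)


def _avoid_markers(pos: int, cfg: FixtureConfig) -> int:
    """Shift a junction off any marker footprint on the bp grid."""
    rem = pos % cfg.marker_spacing
    if rem <= cfg.marker_length:
        pos += cfg.marker_length + 1 - rem
    return pos


def _partition_chromosome(cfg: FixtureConfig, rng: np.random.Generator) -> list[int]:
    n_small = cfg.small_scaffolds_per_chromosome
    n_large = cfg.scaffolds_per_chromosome
    budget = cfg.chromosome_length - n_small * cfg.small_scaffold_length
    weights = rng.uniform(0.6, 1.4, n_large)
    lens = np.floor(weights / weights.sum() * budget).astype(int)
    lens[-1] += budget - lens.sum()
    out = [int(x) for x in lens]
    for _ in range(n_small):
        k = int(rng.integers(1, len(out)))
        out.insert(k, cfg.small_scaffold_length)
    return out


def generate(cfg: FixtureConfig, out_dir: str) -> dict:
    """Write the full input bundle plus a truth manifest; return the manifest."""
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(out_dir, exist_ok=True)

    chrom_names = [f"chr{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    lg_names = [f"LG{i + 1}" for i in range(cfg.n_chromosomes)]
    truth = [
        _BASES[rng.integers(0, 4, size=cfg.chromosome_length)]
        for _ in range(cfg.n_chromosomes)
    ]

    # ---- scaffold spans, then error plans
    plans: list[_Plan] = []
    for ci in range(cfg.n_chromosomes):
        pos = 0
        for length in _partition_chromosome(cfg, rng):
            plans.append(_Plan([_Segment(ci, pos, pos + length, "+")], []))
            pos += length

    def junction_gap() -> int:
        return int(rng.integers(cfg.gap_len_min, cfg.gap_len_max + 1))

    # flanks must hold a couple of cM bins' worth of markers plus clearance
    bin_bp = int(cfg.cm_resolution / cfg.cm_per_mbp * 1e6)
    margin = cfg.junction_clearance + 2 * bin_bp + 2 * cfg.marker_spacing
    invertible = [
        p
        for p in plans
        if p.error is None
        and len(p.segments) == 1
        and p.segments[0].length >= cfg.inversion_block_length + 2 * margin
    ]
    chosen = rng.choice(len(invertible), size=cfg.n_gapless_inversions, replace=False)
    for k in sorted(int(c) for c in chosen):
        plan = invertible[k]
        seg = plan.segments[0]
        j1 = seg.t0 + int(
            rng.integers(margin, seg.length - cfg.inversion_block_length - margin)
        )
        j1 = _avoid_markers(j1, cfg)
        j2 = _avoid_markers(j1 + cfg.inversion_block_length, cfg)
        plan.segments = [
            _Segment(seg.chrom, seg.t0, j1, "+"),
            _Segment(seg.chrom, j1, j2, "-"),
            _Segment(seg.chrom, j2, seg.t1, "+"),
        ]
        plan.joints = [("none", 0), ("none", 0)]
        plan.error = "gapless_inversion"

    translocatable = [
        p
        for p in plans
        if p.error is None
        and len(p.segments) == 1
        and p.segments[0].length >= 9 * cfg.marker_spacing
    ]
    chosen = rng.choice(
        len(translocatable), size=cfg.n_intra_lg_translocations, replace=False
    )
    for k in sorted(int(c) for c in chosen):
        plan = translocatable[k]
        seg = plan.segments[0]
        third = seg.length // 3
        j1 = _avoid_markers(seg.t0 + third, cfg)
        j2 = _avoid_markers(seg.t0 + 2 * third, cfg)
        a, b, c = (
            _Segment(seg.chrom, seg.t0, j1, "+"),
            _Segment(seg.chrom, j1, j2, "+"),
            _Segment(seg.chrom, j2, seg.t1, "+"),
        )
        plan.segments = [a, c, b]  # middle block displaced across real gaps
        plan.joints = [("gap", junction_gap()), ("gap", junction_gap())]
        plan.error = "intra_lg_translocation"

    chimeric = [
        i
        for i, p in enumerate(plans)
        if p.error is None
        and len(p.segments) == 1
        and p.segments[0].length >= 6 * cfg.marker_spacing
    ]
    order = rng.permutation(len(chimeric))
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for oi in order:
        i = chimeric[int(oi)]
        if len(pairs) == cfg.n_inter_lg_chimeras:
            break
        if i in used:
            continue
        partner = next(
            (
                chimeric[int(oj)]
                for oj in order
                if chimeric[int(oj)] not in used
                and plans[chimeric[int(oj)]].segments[0].chrom != plans[i].segments[0].chrom
            ),
            None,
        )
        if partner is None:
            continue
        used.update((i, partner))
        pairs.append((i, partner))
    if len(pairs) < cfg.n_inter_lg_chimeras:
        raise ValueError("not enough scaffolds to plant the requested chimeras")
    removed: set[int] = set()
    for i, j in pairs:
        plans[i].joints = (
            plans[i].joints + [("gap", junction_gap())] + plans[j].joints
        )
        plans[i].segments = plans[i].segments + plans[j].segments
        plans[i].error = "inter_lg_chimera"
        removed.add(j)
    plans = [p for i, p in enumerate(plans) if i not in removed]

    # ---- layout: sequence, gaps, components, junction positions
    scaffolds: list[Scaffold] = []
    seq_records: list[tuple[str, str]] = []
    manifest_scaffolds: dict[str, dict] = {}
    planted_errors: list[dict] = []
    marker_rows: list[dict] = []
    depth_frames: list[pd.DataFrame] = []

    for si, plan in enumerate(plans):
        sid = f"scaffold_{si + 1:03d}"
        apos = 0
        seq_parts: list[np.ndarray] = []
        gap_intervals: list[tuple[int, int]] = []  # assembly coords
        truth_gaps: dict[int, list[tuple[int, int]]] = {}  # per segment index
        junctions: list[int] = []

        for gi, seg in enumerate(plan.segments):
            seg.a0 = apos
            left_joint = plan.joints[gi - 1][0] if gi > 0 else None
            right_joint = plan.joints[gi][0] if gi < len(plan.joints) else None
            lo_clear = cfg.junction_clearance if (
                (seg.orient == "+" and left_joint == "none")
                or (seg.orient == "-" and right_joint == "none")
            ) else 1_000
            hi_clear = cfg.junction_clearance if (
                (seg.orient == "+" and right_joint == "none")
                or (seg.orient == "-" and left_joint == "none")
            ) else 1_000
            sites: list[tuple[int, int]] = []
            t = seg.t0 + lo_clear + int(rng.integers(0, cfg.gap_spacing // 2))
            while t + cfg.gap_len_max < seg.t1 - hi_clear:
                g = junction_gap()
                sites.append((t, t + g))
                t += cfg.gap_spacing + int(
                    rng.integers(-(cfg.gap_spacing // 4), cfg.gap_spacing // 4)
                )
            truth_gaps[gi] = sites

            chunk = truth[seg.chrom][seg.t0 : seg.t1].copy()
            for g0, g1 in sites:
                chunk[g0 - seg.t0 : g1 - seg.t0] = ord("N")
            if seg.orient == "-":
                chunk = _COMP[chunk[::-1]]
                for g0, g1 in sites:
                    gap_intervals.append((apos + seg.t1 - g1, apos + seg.t1 - g0))
            else:
                for g0, g1 in sites:
                    gap_intervals.append((apos + g0 - seg.t0, apos + g1 - seg.t0))
            seq_parts.append(chunk)
            apos += seg.length
            if gi < len(plan.joints):
                kind, glen = plan.joints[gi]
                if kind == "gap":
                    junctions.append(apos)
                    gap_intervals.append((apos, apos + glen))
                    seq_parts.append(np.full(glen, ord("N"), dtype=np.uint8))
                    apos += glen
                else:
                    junctions.append(apos)

        total_len = apos
        seq = np.concatenate(seq_parts)
        assert len(seq) == total_len
        seq_records.append((sid, seq.tobytes().decode("ascii")))

        gap_intervals.sort()
        comps: list[AssemblyComponent] = []
        pos = 0
        ctg = 0
        for g0, g1 in gap_intervals + [(total_len, total_len)]:
            if g0 > pos:
                ctg += 1
                comps.append(
                    AssemblyComponent(
                        sid, pos, g0, len(comps) + 1, CONTIG,
                        component_id=f"{sid}.c{ctg}",
                        component_beg=0, component_end=g0 - pos, orientation="+",
                    )
                )
            if g1 > g0:
                comps.append(
                    AssemblyComponent(
                        sid, g0, g1, len(comps) + 1, GAP,
                        gap_length=g1 - g0, gap_type="scaffold",
                        linkage="yes", evidence="paired-ends",
                    )
                )
            pos = g1
        scaffolds.append(Scaffold(sid, comps))

        manifest_scaffolds[sid] = {
            "length": total_len,
            "segments": [
                {
                    "chrom": chrom_names[seg.chrom],
                    "t0": seg.t0,
                    "t1": seg.t1,
                    "orient": seg.orient,
                    "a0": seg.a0,
                    "a1": seg.a0 + seg.length,
                }
                for seg in plan.segments
            ],
            "gap_starts": [g0 for g0, g1 in gap_intervals],
        }
        if plan.error:
            planted_errors.append(
                {
                    "type": plan.error,
                    "scaffold": sid,
                    "junctions": junctions,
                    "chromosomes": sorted({chrom_names[s.chrom] for s in plan.segments}),
                }
            )

        # ---- markers on this scaffold
        for gi, seg in enumerate(plan.segments):
            start = ((seg.t0 + cfg.marker_spacing - 1) // cfg.marker_spacing) * cfg.marker_spacing
            for t in range(start, seg.t1 - cfg.marker_length, cfg.marker_spacing):
                if any(g0 < t + cfg.marker_length and t < g1 for g0, g1 in truth_gaps[gi]):
                    continue
                if seg.orient == "+":
                    a = seg.a0 + (t - seg.t0)
                    strand = "+"
                else:
                    a = seg.a0 + (seg.t1 - t - cfg.marker_length)
                    strand = "-"
                cm_true = _quantize(t / 1e6 * cfg.cm_per_mbp, cfg.cm_resolution)
                noised = bool(rng.random() < cfg.genotyping_noise_rate)
                if noised:
                    cm_obs = _quantize(
                        max(0.0, cm_true + rng.normal(0.0, cfg.noise_cm_sd)),
                        cfg.cm_resolution,
                    )
                else:
                    cm_obs = cm_true
                marker_rows.append(
                    {
                        "id": f"m_{chrom_names[seg.chrom]}_{t}",
                        "lg": lg_names[seg.chrom],
                        "cm": cm_obs,
                        "cm_true": cm_true,
                        "noised": noised,
                        "scaffold": sid,
                        "position": a,
                        "strand": strand,
                        "chrom": chrom_names[seg.chrom],
                        "t": t,
                    }
                )

        # ---- depth profile
        depths = rng.poisson(cfg.depth_mean, size=total_len).astype(np.int64)
        for g0, g1 in gap_intervals:
            depths[g0:g1] = 0
        if plan.error == "gapless_inversion":
            for j in junctions:
                lo = max(0, j - cfg.depth_anomaly_halfwidth)
                hi = min(total_len, j + cfg.depth_anomaly_halfwidth)
                depths[lo:hi] = (depths[lo:hi] * cfg.depth_anomaly_multiplier).astype(np.int64)
        nz = np.flatnonzero(depths)
        depth_frames.append(
            pd.DataFrame({"seq": sid, "pos": nz + 1, "depth": depths[nz]})
        )

    # ---- genes and orthologs
    focal_rows: list[str] = []
    external_rows: list[str] = []
    ortho_rows: list[str] = []
    seg_index: list[tuple[int, _Segment, str, int]] = []  # (chrom, seg, sid, plan idx)
    for si, plan in enumerate(plans):
        sid = f"scaffold_{si + 1:03d}"
        for gi, seg in enumerate(plan.segments):
            seg_index.append((seg.chrom, seg, sid, gi))
    gene_count = 0
    for ci, chrom in enumerate(chrom_names):
        idx = 0
        for t in range(
            cfg.gene_offset, cfg.chromosome_length - cfg.gene_length, cfg.gene_spacing
        ):
            idx += 1
            xid = f"xg_{chrom}_{idx}"
            external_rows.append(
                f"ext_{chrom}\tsim\tgene\t{t + 1}\t{t + cfg.gene_length}\t.\t+\t."
                f"\tID={xid}\n"
            )
            hit = next(
                (
                    (seg, sid)
                    for c, seg, sid, gi in seg_index
                    if c == ci and seg.t0 <= t and t + cfg.gene_length <= seg.t1
                ),
                None,
            )
            if hit is None:
                continue
            seg, sid = hit
            if seg.orient == "+":
                a0 = seg.a0 + (t - seg.t0)
                strand = "+"
            else:
                a0 = seg.a0 + (seg.t1 - (t + cfg.gene_length))
                strand = "-"
            gid = f"g_{chrom}_{idx}"
            focal_rows.append(
                f"{sid}\tsim\tgene\t{a0 + 1}\t{a0 + cfg.gene_length}\t.\t{strand}\t."
                f"\tID={gid}\n"
            )
            ortho_rows.append(f"{gid}\txg_{chrom}_{idx}\n")
            gene_count += 1

    # ---- write files
    from .io_formats import write_agp, write_fasta

    paths = {
        name: os.path.join(out_dir, fname)
        for name, fname in (
            ("agp", "assembly.agp"),
            ("fasta", "assembly.fasta"),
            ("map", "map.tsv"),
            ("alignments", "markers.sam"),
            ("depth", "depth.tsv"),
            ("focal_gff", "focal.gff3"),
            ("external_gff", "external.gff3"),
            ("orthologs", "orthologs.tsv"),
            ("manifest", "truth.json"),
        )
    }
    write_agp(scaffolds, paths["agp"])
    write_fasta(seq_records, paths["fasta"])
    with open(paths["map"], "w") as fh:
        fh.write("# marker\tlinkage_group\tcm\n")
        for row in marker_rows:
            fh.write(f"{row['id']}\t{row['lg']}\t{row['cm']}\n")
    seq_by_id = dict(seq_records)
    with open(paths["alignments"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for sid, seq in seq_records:
            fh.write(f"@SQ\tSN:{sid}\tLN:{len(seq)}\n")
        for row in marker_rows:
            flag = 16 if row["strand"] == "-" else 0
            mseq = seq_by_id[row["scaffold"]][
                row["position"] : row["position"] + cfg.marker_length
            ]
            fh.write(
                f"{row['id']}\t{flag}\t{row['scaffold']}\t{row['position'] + 1}\t60"
                f"\t{cfg.marker_length}M\t*\t0\t0\t{mseq}\t*\n"
            )
    pd.concat(depth_frames).to_csv(paths["depth"], sep="\t", header=False, index=False)
    with open(paths["focal_gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.writelines(focal_rows)
    with open(paths["external_gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.writelines(external_rows)
    with open(paths["orthologs"], "w") as fh:
        fh.writelines(ortho_rows)

    manifest = {
        "config": asdict(cfg),
        "linkage_groups": dict(zip(chrom_names, lg_names)),
        "scaffolds": manifest_scaffolds,
        "planted_errors": planted_errors,
        "markers": {
            row["id"]: {
                "scaffold": row["scaffold"],
                "position": row["position"],
                "strand": row["strand"],
                "chrom": row["chrom"],
                "truth_position": row["t"],
                "cm_true": row["cm_true"],
                "cm_observed": row["cm"],
                "noised": row["noised"],
            }
            for row in marker_rows
        },
        "n_genes": gene_count,
        "paths": paths,
    }
    with open(paths["manifest"], "w") as fh:
        # basenames on disk so the bundle is relocatable (and byte-identical
        # across output directories); the returned dict keeps absolute paths
        portable = dict(manifest, paths={k: os.path.basename(v) for k, v in paths.items()})
        json.dump(portable, fh, indent=1)
    return manifest


def load_manifest(path: str) -> dict:
    """Read a truth manifest, resolving its relative paths."""
    with open(path) as fh:
        manifest = json.load(fh)
    base = os.path.dirname(os.path.abspath(path))
    manifest["paths"] = {
        k: v if os.path.isabs(v) else os.path.join(base, v)
        for k, v in manifest["paths"].items()
    }
    return manifest


def noise_conflict_closure(manifest: dict) -> set[str]:
    """Marker ids whose discard is attributable to genotyping noise: the
    noised markers plus every marker pair-inverted against one (bp and
    observed-cM orders disagree) or sharing a noised marker's observed cM.
    When a noised marker crosses exactly one true neighbour the consistency
    optimum is a tie, so either member of the pair may be the one dropped."""
    marks = manifest["markers"]
    by_scaffold: dict[str, list[str]] = {}
    for mid, info in marks.items():
        by_scaffold.setdefault(info["scaffold"], []).append(mid)
    closure = {mid for mid, info in marks.items() if info["noised"]}
    for mid in list(closure):
        info = marks[mid]
        for other in by_scaffold[info["scaffold"]]:
            o = marks[other]
            dbp = o["position"] - info["position"]
            dcm = o["cm_observed"] - info["cm_observed"]
            if dbp * dcm < 0 or dcm == 0:
                closure.add(other)
    return closure


# ---------------------------------------------------------------------------
# Scoring against planted truth


def _majority_segment(manifest: dict, scaffold: Scaffold) -> dict | None:
    segs = manifest["scaffolds"].get(scaffold.origin_id, {}).get("segments", [])
    b, e = scaffold.origin_beg, scaffold.origin_beg + scaffold.length
    best, best_ov = None, 0
    for seg in segs:
        ov = min(e, seg["a1"]) - max(b, seg["a0"])
        if ov > best_ov:
            best, best_ov = seg, ov
    return best


def score_against_truth(
    chromonome: Chromonome, manifest: dict, window_size: int = 5_000
) -> dict:
    """Compare a finished run against the generator's planted truth.

    Split recall/precision use a +/-1-gap-position tolerance for junctions
    at real gaps and a +/-1-window tolerance for depth-derived (virtual-gap)
    junctions; orientation accuracy covers orientable placements only; order
    accuracy is the fraction of adjacent true scaffold pairs left adjacent
    in the output.
    """
    junctions: list[tuple[str, int, str]] = []
    for err in manifest["planted_errors"]:
        for j in err["junctions"]:
            junctions.append((err["scaffold"], j, err["type"]))

    def tolerance_ok(origin: str, split_bp: int, junction_bp: int, kind: str) -> bool:
        """+/-1 window for depth-derived cuts; +/-1 gap position for gap cuts
        (the cut sits at the junction gap, at a neighbouring gap, or at the
        gap immediately bracketing a gapless junction)."""
        if abs(split_bp - junction_bp) <= window_size:
            return True
        gaps = sorted(manifest["scaffolds"][origin]["gap_starts"])
        if not gaps:
            return False
        si = min(range(len(gaps)), key=lambda i: abs(gaps[i] - split_bp))
        if abs(gaps[si] - split_bp) > window_size:
            return False  # split is not at/near any real gap
        ji = min(range(len(gaps)), key=lambda i: abs(gaps[i] - junction_bp))
        if abs(gaps[ji] - junction_bp) <= window_size:
            return abs(si - ji) <= 1  # junction itself sits at a gap
        lo, hi = min(split_bp, junction_bp), max(split_bp, junction_bp)
        return not any(lo + window_size < g < hi - window_size for g in gaps)

    matched_junctions: set[int] = set()
    matched_splits = 0
    for rec in chromonome.provenance:
        candidates = [
            (abs(rec.origin_bp - j_bp), k)
            for k, (origin, j_bp, kind) in enumerate(junctions)
            if origin == rec.origin_id
            and k not in matched_junctions
            and tolerance_ok(origin, rec.origin_bp, j_bp, kind)
        ]
        if candidates:
            matched_junctions.add(min(candidates)[1])
            matched_splits += 1
    n_splits = len(chromonome.provenance)
    split_recall = len(matched_junctions) / len(junctions) if junctions else 1.0
    split_precision = matched_splits / n_splits if n_splits else 1.0

    ori_total = ori_correct = 0
    lg_by_chrom = manifest["linkage_groups"]
    placements_by_lg: dict[str, list] = {}
    for lg, placements in chromonome.chromosomes.items():
        placements_by_lg[lg] = [p for p, _ in placements]
        for p in placements_by_lg[lg]:
            seg = _majority_segment(manifest, chromonome.scaffolds[p.scaffold_id])
            if seg is None or p.orientation == "unoriented":
                continue
            expected = "forward" if seg["orient"] == "+" else "reverse"
            ori_total += 1
            if p.orientation == expected:
                ori_correct += 1
    orientation_accuracy = ori_correct / ori_total if ori_total else 1.0

    adj_total = adj_kept = 0
    for lg, placements in placements_by_lg.items():
        keyed = []
        for rank, p in enumerate(placements):
            scaf = chromonome.scaffolds[p.scaffold_id]
            seg = _majority_segment(manifest, scaf)
            if seg is None:
                continue
            if seg["orient"] == "+":
                tpos = seg["t0"] + max(0, scaf.origin_beg - seg["a0"])
            else:
                tpos = seg["t0"] + max(
                    0, seg["a1"] - (scaf.origin_beg + scaf.length)
                )
            if lg_by_chrom.get(seg["chrom"]) == lg:
                keyed.append((tpos, rank))
        keyed.sort()
        for (t1, r1), (t2, r2) in zip(keyed, keyed[1:]):
            adj_total += 1
            if abs(r1 - r2) == 1:
                adj_kept += 1
    order_accuracy = adj_kept / adj_total if adj_total else 1.0

    placed_len = sum(
        chromonome.scaffolds[p.scaffold_id].length
        for ps in chromonome.chromosomes.values()
        for p, _ in ps
    )
    total_len = placed_len + sum(s.length for s in chromonome.unplaced)
    return {
        "split_recall": split_recall,
        "split_precision": split_precision,
        "orientation_accuracy": orientation_accuracy,
        "order_accuracy": order_accuracy,
        "n_planted_junctions": len(junctions),
        "n_splits": n_splits,
        "n_scaffolds_integrated": sum(
            len(v) for v in chromonome.chromosomes.values()
        ),
        "fraction_length_integrated": placed_len / total_len if total_len else 0.0,
    }
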