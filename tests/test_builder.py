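"""Chromonome assembly and output emission: placement order, AGP/FASTA
consistency, annotation lift-over and report bookkeeping."""

import json
import os

import pytest

from chromanchor import builder
from chromanchor.datamodel import FORWARD, GAP, REVERSE, UNORIENTED
from chromanchor.io_formats import read_agp, read_fasta, reverse_complement
from chromanchor.lg_graph import build_lg_graph, finalize_orientation

from conftest import make_hits, make_scaffold


def _simple_chromonome(orientations=("forward", "forward", "forward")):
    hits = {
        "s1": make_hits("s1", ("m1", "LG1", 0.0, 10), ("m2", "LG1", 0.5, 90)),
        "s2": make_hits("s2", ("m3", "LG1", 5.0, 10), ("m4", "LG1", 5.5, 190)),
        "s3": make_hits("s3", ("m5", "LG1", 10.0, 10), ("m6", "LG1", 10.5, 290)),
    }
    graph = build_lg_graph("LG1", hits)
    finalize_orientation(graph)
    for p, orient in zip(sorted(graph.placements, key=lambda p: p.scaffold_id), orientations):
        p.orientation = orient
    scaffolds = {
        "s1": make_scaffold("c:100", "s1"),
        "s2": make_scaffold("c:200", "s2"),
        "s3": make_scaffold("c:300", "s3"),
    }
    return builder.build_chromonome({"LG1": graph}, scaffolds, [], gap_length=100), scaffolds


class TestBuildChromonome:
    def test_three_single_node_scaffolds_in_cm_order(self):
        chromonome, _ = _simple_chromonome()
        (placements,) = chromonome.chromosomes.values()
        assert [p.scaffold_id for p, _ in placements] == ["s1", "s2", "s3"]
        (chrom,) = builder.chromonome_scaffolds(chromonome, gap_length=100)
        assert chrom.length == 100 + 100 + 200 + 100 + 300
        gaps = [c for c in chrom.components if c.kind == GAP]
        assert len(gaps) == 2 and all(g.evidence == "map" for g in gaps)

    def test_shared_node_fallback_order_and_unknown_orientation(self):
        hits = {
            "sA": make_hits("sA", ("m1", "LG1", 3.0, 10)),
            "sB": make_hits("sB", ("m2", "LG1", 3.0, 10)),
        }
        graph = build_lg_graph("LG1", hits)
        finalize_orientation(graph)
        scaffolds = {"sA": make_scaffold("c:100", "sA"), "sB": make_scaffold("c:900", "sB")}
        chromonome = builder.build_chromonome({"LG1": graph}, scaffolds, [])
        (placements,) = chromonome.chromosomes.values()
        assert [p.scaffold_id for p, _ in placements] == ["sB", "sA"]  # longer first
        assert all(p.orientation == UNORIENTED for p, _ in placements)
        assert all(p.evidence == "fallback" for p, _ in placements)

    def test_empty_graph_emits_no_chromosome(self):
        chromonome = builder.build_chromonome(
            {"LG1": build_lg_graph("LG1", {})}, {"s1": make_scaffold("c:10")}, []
        )
        assert chromonome.chromosomes == {}
        assert [s.id for s in chromonome.unplaced] == ["s1"]


class TestEmitFasta:
    def test_forward_and_reverse_sequence(self, tmp_path):
        chromonome, _ = _simple_chromonome(("forward", "reverse", "forward"))
        seqs = {"s1": "A" * 100, "s2": "ACGT" * 50, "s3": "G" * 300}
        path = tmp_path / "out.fasta"
        builder.emit_fasta(chromonome, seqs, str(path))
        (record,) = read_fasta(str(path)).values()
        expected = "A" * 100 + "N" * 100 + reverse_complement("ACGT" * 50) + "N" * 100 + "G" * 300
        assert record == expected

    def test_missing_source_sequence_is_fatal_with_id(self, tmp_path):
        chromonome, _ = _simple_chromonome()
        with pytest.raises(KeyError, match="s2"):
            builder.emit_fasta(chromonome, {"s1": "A" * 100, "s3": "G" * 300},
                               str(tmp_path / "x.fasta"))


class TestAgpFastaAgreement:
    def test_agp_reassembly_reproduces_fasta_bytes(self, small_run, tmp_path):
        """Reading the output AGP back and assembling it against the input
        FASTA must reproduce the emitted chromosome sequences exactly."""
        manifest, result, out_dir = small_run
        source = read_fasta(manifest["paths"]["fasta"])
        emitted = read_fasta(os.path.join(out_dir, "chromonome.fasta"))
        # map final fragment ids to origin slices for component lookup
        frags = result.chromonome.scaffolds
        for chrom_scaffold in read_agp(os.path.join(out_dir, "chromonome.agp")):
            parts = []
            for comp in chrom_scaffold.components:
                if comp.kind == GAP:
                    parts.append("N" * comp.gap_length)
                    continue
                # component ids are contig ids of final fragments
                frag = next(
                    f for f in frags.values() if comp.component_id in f.contig_ids()
                )
                fcomp = next(
                    c for c in frag.components if c.component_id == comp.component_id
                    and (c.component_beg, c.component_end)
                    == (comp.component_beg, comp.component_end)
                )
                seq = source[frag.origin_id][
                    frag.origin_beg + fcomp.object_beg : frag.origin_beg + fcomp.object_end
                ]
                if comp.orientation != fcomp.orientation:
                    seq = reverse_complement(seq)
                parts.append(seq)
            assert "".join(parts) == emitted[chrom_scaffold.id]

    def test_non_n_base_count_conserved(self, small_run):
        manifest, result, out_dir = small_run
        source = read_fasta(manifest["paths"]["fasta"])
        emitted = read_fasta(os.path.join(out_dir, "chromonome.fasta"))
        count = lambda seqs: sum(len(s) - s.upper().count("N") for s in seqs.values())
        assert count(emitted) == count(source)


class TestTranslateAnnotations:
    def test_forward_offset_reverse_mirror_and_round_trip(self, tmp_path):
        chromonome, _ = _simple_chromonome(("forward", "reverse", "forward"))
        gff = tmp_path / "in.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "s1\tsrc\tgene\t11\t60\t.\t+\t.\tID=g1\n"
            "s2\tsrc\tgene\t1\t40\t.\t+\t.\tID=g2\n"
        )
        out1 = tmp_path / "chrom.gff3"
        builder.translate_annotations(str(gff), chromonome, "to_chromonome", str(out1))
        rows = [l.split("\t") for l in out1.read_text().splitlines() if not l.startswith("#")]
        # s1 placed at offset 0: coordinates unchanged
        assert (rows[0][0], rows[0][3], rows[0][4], rows[0][6]) == ("LG1", "11", "60", "+")
        # s2 (len 200) reverse-placed at offset 200: [0,40) -> [360,400), strand flipped
        assert (rows[1][3], rows[1][4], rows[1][6]) == ("361", "400", "-")
        out2 = tmp_path / "back.gff3"
        builder.translate_annotations(str(out1), chromonome, "to_scaffolds", str(out2))
        assert out2.read_text() == gff.read_text()

    def test_feature_spanning_split_dropped_and_logged(self, small_run, tmp_path):
        manifest, result, out_dir = small_run
        split = result.chromonome.provenance[0]
        gff = tmp_path / "span.gff3"
        gff.write_text(
            f"{split.origin_id}\tsrc\tgene\t{split.origin_bp - 99}\t{split.origin_bp + 100}"
            "\t.\t+\t.\tID=gX\n"
        )
        out = tmp_path / "out.gff3"
        log = builder.translate_annotations(str(gff), result.chromonome,
                                            "to_chromonome", str(out))
        assert out.read_text() == ""
        assert any("split point" in line for line in log)


class TestReports:
    def test_every_discarded_marker_logged_once_with_reason(self, small_run):
        manifest, result, out_dir = small_run
        discards = result.score_inputs["discards"]
        discarded_ids = {m.id for items in discards.values() for m, _, _ in items}
        seen = {}
        for name in os.listdir(out_dir):
            if name.endswith(".after.tsv"):
                for line in open(os.path.join(out_dir, name)).readlines()[1:]:
                    marker, _, _, _, status = line.rstrip("\n").split("\t")
                    if status.startswith("discarded"):
                        seen[marker] = seen.get(marker, 0) + 1
                        assert ": " in status  # carries a reason
        assert set(seen) == discarded_ids
        assert all(v == 1 for v in seen.values())

    def test_unmodified_scaffolds_have_no_split_log(self, small_run):
        manifest, result, out_dir = small_run
        modified = {r.origin_id for r in result.chromonome.provenance}
        logs = {n[len("scaffold_"):-len(".log")] for n in os.listdir(out_dir)
                if n.startswith("scaffold_") and n.endswith(".log")}
        assert logs == modified

    def test_json_views_validate_against_schema(self, small_run):
        manifest, result, out_dir = small_run
        n = 0
        for name in os.listdir(out_dir):
            if name.endswith(".json"):
                view = json.load(open(os.path.join(out_dir, name)))
                builder.validate_lg_json(view)  # raises on shape violations
                n += 1
        assert n >= 4  # before+after per linkage group

    def test_summary_counts_match_output_agp(self, small_run):
        manifest, result, out_dir = small_run
        chrom_scaffolds = read_agp(os.path.join(out_dir, "chromonome.agp"))
        unplaced = read_agp(os.path.join(out_dir, "unplaced.agp"))
        assert result.summary["n_chromosomes"] == len(chrom_scaffolds)
        assert result.summary["n_scaffolds_unplaced"] == len(unplaced)
        for chrom in chrom_scaffolds:
            assert result.summary["chromosome_lengths"][chrom.id] == chrom.length

    def test_promising_scaffolds_have_markers_but_no_placement(self, small_run):
        manifest, result, out_dir = small_run
        placed_origins = {
            result.chromonome.scaffolds[p].origin_id
            for p in result.chromonome.placed_ids()
        }
        rows = open(os.path.join(out_dir, "promising_scaffolds.tsv")).readlines()[1:]
        for row in rows:
            sid, n, reason = row.rstrip("\n").split("\t")
            assert sid not in placed_origins
            assert int(n) >= 1 and reason
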