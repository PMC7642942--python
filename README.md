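# chromanchor

Integrate a scaffold-level genome assembly with a marker-dense genetic map —
plus optional read-depth and conserved-synteny evidence — into chromosome
models ("chromonomes"), detecting and splitting chimeric scaffolds along the
way and logging every decision.

## Who this is for

Genome projects routinely end with thousands of scaffolds whose long-range
arrangement is unknown, and some of those scaffolds are chimeric: mate-pair
scaffolding joins unrelated loci, and long-read or optical-map assemblies
contain inverted or translocated blocks with no gap at the joint. A genetic
map is an independent witness of genome structure: markers genotyped in a
cross bind scaffolds into linkage groups (chromosome models) and order them
by recombination distance (centiMorgans, cM). `chromanchor` automates the
reconciliation for anyone holding an assembly (AGP + FASTA), a map (marker,
linkage group, cM), and marker alignments (SAM/BAM).

## The algorithm in brief

Evidence is applied in a fixed hierarchy of trust: contigs, then linkage
group assignment, marker order, scaffold gap structure, read depth, and
finally conserved gene synteny. Concretely:

1. **Virtual gaps** — with per-base depth `d_i`, a sliding window's mean is
   scored `z = (x̄_w − μ)/σ` against the scaffold's window-mean statistics;
   each maximal block with `|z| ≥ 3` receives a zero-length *virtual gap* at
   its deviation-weighted centroid, licensing cuts inside gapless sequence.
2. **Inter-LG splitting** — a scaffold whose markers hit ≥ 2 linkage groups
   is cut at the largest gap between adjacent same-LG marker runs;
   unsplittable runs are pruned by exact minimum-marker-discard search.
3. **Rescaffolding** (optional, `--rescaffold`) — map nodes own the
   sequence their markers span; nodes are re-sorted by mean bp, overlaps
   pruned, and the scaffold is cut wherever the physical node progression
   breaks cM adjacency (the gapless-inversion/translocation fix).
4. **Linkage-group graph** — one node per cM position; scaffolds anchor to
   nodes, consecutive anchored nodes collapse into a placement, and within
   each placement the maximum-cardinality marker subset with monotone cM
   (longest-monotone-subsequence DP) is retained.
5. **Intra-LG splitting and orientation** — multi-placement scaffolds are
   cut between marker groups; orientation is the sign of the OLS slope of
   bp on cM (≥ 2 cM positions required).
6. **Conserved synteny** (optional, `--synteny`) — scaffolds the map cannot
   order or orient are arranged by orthologous gene order on the related
   genome's plurality chromosome; synteny never overrides a map decision.

Outputs: chromosome + unplaced AGP v2.1, FASTA, lifted GFF, per-LG
before/after marker tables and JSON views, per-split logs, a summary, and a
"promising scaffolds" list. The pipeline is fully deterministic.

## Worked example

Generate a synthetic bundle — 4 chromosomes × 2 Mbp with 3 inter-LG
chimeras and 2 gapless inversions planted — then integrate it:

```sh
chromanchor fixtures generate --seed 7 --out-dir demo/bundle
# wrote 29 scaffolds, 793 markers, 5 planted errors to demo/bundle

chromanchor integrate \
    --agp demo/bundle/assembly.agp --map demo/bundle/map.tsv \
    --alignments demo/bundle/markers.sam --fasta demo/bundle/assembly.fasta \
    --depth demo/bundle/depth.tsv --rescaffold --out-dir demo/run
```

The run log (stderr) narrates the stages:

```
depth: inserted 25 virtual gaps
inter-LG: 3 splits, 0 markers discarded
rescaffold: 4 splits, 22 markers discarded
graphs: 4 linkage groups
```

and the summary (stdout) reports the finished chromonome:

```json
{
 "n_chromosomes": 4,
 "n_scaffolds_integrated": 36,
 "n_scaffolds_unplaced": 0,
 "n_splits": 7,
 "n_markers_retained": 771,
 "n_markers_discarded": 22,
 "chromosome_lengths": {"LG1": 2000900, "LG2": 1990740,
                        "LG3": 2010830, "LG4": 2000700}
}
```

Reading: the 3 chimeras were each split once at the joining gap and the 2
inversions twice each at their depth-flagged junctions (3 + 4 = 7 splits,
29 scaffolds → 36 placed fragments); 771 of 793 markers survived the
consistency filters. Because this bundle is synthetic, the result can be
scored against the planted truth:

```sh
chromanchor fixtures score --manifest demo/bundle/truth.json --run-dir demo/score
```

```json
{
 "split_recall": 1.0, "split_precision": 1.0,
 "orientation_accuracy": 1.0, "order_accuracy": 1.0,
 "n_planted_junctions": 7, "n_splits": 7,
 "n_scaffolds_integrated": 36, "fraction_length_integrated": 1.0
}
```

— every planted junction was found (within one depth window for gapless
junctions), no spurious splits were made, and every orientable fragment,
including the inverted middle blocks, came out correctly oriented.

The library mirrors the CLI: `chromanchor.run(RunConfig(...))` returns the
`Chromonome` object, and `chromanchor.fixtures.generate` /
`score_against_truth` drive the same synthetic study. See
`docs/methods.md` for the model, parameter meanings and limitations.

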