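# Methods

`chromanchor` integrates a scaffold-level genome assembly with a
marker-dense genetic map — plus optional read-depth and conserved-synteny
evidence — into chromosome models ("chromonomes"), detecting and splitting
chimeric scaffolds and logging every decision. This note describes the
model, its assumptions, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was open.

## The hierarchy of trust

Every stage resolves conflicts by ranking evidence:

1. **contigs** — contiguous assembled sequence is never contradicted by a
   single marker;
2. **linkage-group assignment** — statistically the most robust map
   property; a scaffold whose markers hit two linkage groups is presumed
   chimeric;
3. **marker order within a linkage group** — trusted over scaffolding, but
   individual markers are not: genotyping error moves single markers;
4. **scaffolding** (the gap structure), which supplies legal cut points;
5. **read depth**, which licenses cut points inside gapless sequence;
6. **conserved synteny**, used only where the map is silent.

The pipeline realizes this as six ordered stages: virtual-gap insertion
(depth), inter-LG splitting, optional map-priority rescaffolding, the
linkage-group graph with consistent marker subsets, intra-LG splitting and
re-orientation, and finally synteny ordering of map-ambiguous scaffolds.
The pipeline contains no random state; identical inputs give byte-identical
outputs.

## Coordinates and the assembly model

All internal coordinates are 0-based, half-open; AGP, SAM, GFF and the
samtools depth table are converted at the I/O boundary only. A scaffold is
an ordered list of AGP components (contigs and gaps) tiling `[0, length)`;
this invariant is validated after every mutation. Splits consume the gap
they cut at; contig content (ids and component spans) is conserved by every
operation, and zero-length *virtual gaps* never change sequence
coordinates, so each output fragment is a contiguous slice of exactly one
input scaffold. That slice (`origin_id`, `origin_beg`) is the provenance
used for sequence extraction, annotation lift-over and truth scoring.

Multiply-aligned markers: only the primary SAM record is used; secondary
and supplementary records are ignored, and a marker's position is the
leftmost aligned base regardless of strand. `min_mapq` defaults to 0 (no
filter).

## Inter-linkage-group conflicts

A scaffold's markers are bucketed by linkage group and partitioned into
maximal bp-contiguous same-LG runs. Between every adjacent pair of
surviving runs the scaffold is cut at the best gap strictly between the
bounding markers: largest gap first, ties broken by proximity to the
interval midpoint, then leftmost (ties matter mainly among zero-length
virtual gaps). When an adjacency has no gap, marker sets must be pruned.
For up to 12 runs the pruned set is chosen by exact search — the fewest
markers whose removal leaves every surviving adjacency splittable (greedy
smallest-set pruning is not optimal: with gapless singleton runs
`LG1|LG2|LG1` it discards two markers where removing the middle run costs
one); beyond 12 runs a greedy smallest-set rule takes over. Fragments are
renamed `{id}__{n}` (configurable).

**Minimum split support.** A run (or, later, a placement or node span)
consisting of fewer than `min_split_support` markers (default 2) never
forces a split; it is discarded instead. This is the "uncorroborated
single marker" principle of the trust hierarchy: one noise-shifted marker
landing beyond a scaffold's map range must not amputate a terminal
fragment.

## The linkage-group graph

Each distinct cM value in a linkage group is a node. A scaffold is anchored
at every node holding at least one of its markers; maximal runs of
consecutive anchored nodes collapse into one *placement* (definitively
orientable when it spans two or more nodes), and non-adjacent anchors
produce multiple placements — the signature of an intra-LG misassembly.

**Provisional orientation** is the sign of the ordinary-least-squares slope
of marker bp on cM over all the scaffold's markers; fewer than two distinct
cM positions, or an exactly zero slope, leaves the scaffold unoriented (no
epsilon is applied; the slope is a rational computation on exact inputs).

**Consistent marker subsets.** Within each placement the
maximum-cardinality subset of markers whose cM sequence is non-decreasing
(forward) or non-increasing (reverse) in bp order is retained, computed by
longest-monotone-subsequence dynamic programming; equal cM values belong to
one node and never conflict. Among equal-cardinality optima the
lexicographically earliest by bp is kept; unoriented placements are
evaluated in both directions and the larger set wins (ties: forward). The
rest are logged as order conflicts. Note an identifiability limit: when a
noised marker crosses exactly one true neighbour, the two optimal subsets
tie and no order-based method can tell which member of the inverted pair
was perturbed.

**Intra-LG splitting.** A scaffold holding several placements is cut at the
best gap (real or virtual) in the interval between the retained marker
groups of each adjacent placement pair; if an adjacency has no gap the
smallest conflicting placement (fewest retained markers, then fewest bp,
then highest cM) is discarded and the search repeats, terminating with a
clean multi-way split or a single placement. Orientation is then
recomputed on retained markers only.

## Depth of coverage and virtual gaps

A window (default 5 kbp) slides along each scaffold at a configurable step
(default 1 kbp); each window's mean depth is z-scored against the mean and
standard deviation of all window means of that scaffold (sd = 0 yields
z = 0 everywhere). Maximal blocks of overlapping windows with |z| at or
beyond the threshold (default 3) mark anomalous regions, and one
zero-length virtual gap is inserted per block at the |depth − mean|-
weighted centroid of its per-base depth (a symmetric anomaly's centroid
pins the breakpoint to within tens of bases, far below window
granularity; without a profile the block center is used); insertion is
skipped where the position falls inside or immediately abuts a real gap. Tiling (step =
window) is available but localizes breakpoints only to window granularity,
which can leave junctions closely bracketed by markers unsplittable.
Virtual gaps not consumed by a split are stripped before output and the
contig pieces they separated are re-merged, so insert-then-strip is the
identity.

## Map-priority rescaffolding

An inversion or translocation *inside* a contig leaves no multi-placement
signature: the basal algorithm would simply discard the minority markers.
Rescaffold mode (off by default, `--rescaffold`) instead makes each map
node the owner of the sequence its markers span: markers are bucketed per
node, nodes re-sorted by mean bp, and physically overlapping adjacent
nodes pruned — removing the marker farthest from its own node mean first;
distance ties prefer the removal that most reduces the pair's overlap
(that being the objective of pruning), then marker id. Spans below the
support floor that collide with a corroborated span are dropped whole.

The bp-sorted spans are then grouped into maximal runs whose node ranks
(recomputed from surviving spans after every discard) step by exactly one
in a constant direction. Two parsimony rules precede cutting: a span below
the support floor is sacrificed whenever that alone reduces the number of
run breaks (one stray marker never fabricates a misassembly), and runs
below the floor are dropped entirely. The scaffold is cut at the best gap
between each adjacent run pair — real gaps rank above virtual ones per the
trust hierarchy — and pairs without any gap are merged and logged.
Fragments re-enter the basal pipeline, which re-sorts them to cM order and
re-orients each by regression, so an inverted internal block emerges as a
reverse-oriented middle fragment.

## Conserved synteny

Only scaffolds the map leaves ambiguous (anchored at a single node, or
sharing a node with others) are touched; map decisions are never
overridden. Per linkage group the external chromosome is the plurality
vote of the orthologs of the group's genes, and its relative orientation
is the regression sign of external gene position on the position each gene
projects to in the provisional chromosome, using definitively map-oriented
scaffolds only. Within an ambiguous node, ortholog pairs are filtered:
off-chromosome pairs are dropped; external positions farther than `k_sd`
(default 3) trimmed standard deviations from the trimmed mean (default
trim 0.2 per tail) are dropped; and per scaffold the larger of the longest
non-decreasing/non-increasing external-position subsequences survives (the
monotonicity filter is per scaffold because a scaffold is contiguous
physical sequence, while cross-scaffold order is the unknown being
estimated). Scaffolds are then ordered by median retained external
position and each map-unoriented scaffold oriented by regression sign
(two or more genes required). Nodes with fewer than two congruent genes
are left in fallback order and logged.

## Chromonome assembly and outputs

Placements are ordered by node span (first, then last cM); within a shared
single node, by synteny rank when available, else by descending scaffold
length then id, with orientation flagged `?` and evidence `fallback`.
Adjacent placements are joined by a fixed gap (default 100 bp; AGP gap
type `contig`, linkage `yes`, evidence `map`). Outputs: chromosome and
unplaced AGP v2.1; FASTA (reverse placements reverse-complemented; non-N
base count is conserved, and re-assembling the output AGP against the
input FASTA reproduces the emitted sequence byte-for-byte); GFF lift-over
in both directions (features spanning a split point are dropped and
logged; the round trip is the identity for survivors); per-LG before/after
marker tables and JSON views (schema in `docs/lg_view.schema.json`); a log
per modified scaffold with each split position and reason; a summary; and
the promising-scaffold list — marker-bearing scaffolds that were not
integrated, with the reasons their markers were set aside (criteria are
ours: the concept names scaffolds a better map could rescue).

## The synthetic study conditions

The generator (`chromanchor fixtures generate`, `chromanchor.fixtures`)
simulates true chromosomes, partitions them into scaffolds, overlays
assembly gaps (every ~50 kbp, 50–500 bp, consuming the sequence they
replace), and plants misassemblies with recorded junctions: inter-LG
chimeras (two scaffolds from different chromosomes joined across a real
gap), gapless inversions (an internal block reverse-complemented inside
contiguous sequence, with a depth anomaly of 3x the mean over ±5 kbp at
both junctions), and intra-LG translocations (blocks reordered across real
gaps). Markers sit on a 10 kbp grid; cM = true position × 25 cM/Mbp,
quantized to 0.5 cM — so map nodes hold ~2 markers and scaffolds span many
nodes, emulating the finite resolution of a few-hundred-progeny cross — and
2% of markers get Gaussian cM noise (sd 1 cM, re-quantized). Genes every
6 kbp (dense enough that the ~15 kbp single-node scaffolds carry the two
or more orthologs the synteny stage needs) are annotated on both the focal
scaffolds and an external genome that equals the true order. Depth is
Poisson (mean 30x), zero in gaps. Defaults: 4 chromosomes × 2 Mbp, 6
large + 2 small scaffolds each, 3 chimeras + 2 inversions. All outputs are
deterministic in the seed.

What the generator does **not** emulate: repetitive sequence and
mapping ambiguity, segregation-distorted or clustered markers, map errors
beyond independent per-marker noise, gap-length misestimates, true
biological rearrangement between focal and external genome, and read-level
artifacts. Passing tests therefore demonstrate algorithmic correctness
under the stated error models, not performance on any real assembly.

`score_against_truth` reports: split recall and precision under a
±1-gap-position tolerance (a cut matches a junction if within one window
for depth-derived cuts, at the junction gap or an immediate neighbour for
gap junctions, or at the real gap immediately bracketing a gapless
junction — the topology is right and the localization bounded by the local
gap structure); orientation accuracy over orientable placements against
segment provenance; and order accuracy as the fraction of adjacent true
pairs left adjacent in the output.

## Test problem sizes

The acceptance suite runs the full default conditions once for planted-
error recovery and once (error-free) for the null case; conservation and
monotonicity properties run on 100 and 12 scaled-down bundles
(2 chromosomes × 120–400 kbp), chosen because those laws are
scale-invariant; the consistency filters are checked against
exhaustive-subset enumeration on 1,000 seeded instances of up to 12
markers/genes. `scripts/acceptance.py --seed N --out results.json`
recomputes the headline metrics from scratch at the default scale.

## Known limitations

* Node collapsing assumes exact cM equality; maps with near-duplicate cM
  values (floating-point noise from map software) should be rounded
  upstream or nodes will not merge.
* The rescaffold stage resolves structure only down to the map's node
  resolution; junctions inside a single node span cannot be localized
  better than the flanking markers allow.
* Exact inter-LG pruning is exponential in the number of runs and falls
  back to a greedy rule above 12 runs.
* Synteny ordering trusts a single external genome; a true rearrangement
  between the two species is indistinguishable from an assembly error at
  ambiguous nodes (the subordination rule limits the blast radius to
  scaffolds the map cannot place).
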