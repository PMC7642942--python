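import pytest

from chromanchor.datamodel import (
    CONTIG,
    GAP,
    AssemblyComponent,
    Marker,
    MarkerAlignment,
    Scaffold,
)
from chromanchor.fixtures import FixtureConfig


def make_scaffold(spec: str, sid: str = "s1") -> Scaffold:
    """Build a scaffold from a compact spec like "c:100 g:50 c:200".

    ``c:<len>[:-]`` is a contig (optionally reverse-oriented), ``g:<len>``
    a gap.  Contigs are named <sid>.c1, <sid>.c2, ...
    """
    comps = []
    pos = 0
    ctg = 0
    for tok in spec.split():
        parts = tok.split(":")
        kind, length = parts[0], int(parts[1])
        if kind == "c":
            ctg += 1
            comps.append(
                AssemblyComponent(
                    sid, pos, pos + length, len(comps) + 1, CONTIG,
                    component_id=f"{sid}.c{ctg}", component_beg=0,
                    component_end=length,
                    orientation="-" if len(parts) > 2 and parts[2] == "-" else "+",
                )
            )
        elif kind == "g":
            comps.append(
                AssemblyComponent(
                    sid, pos, pos + length, len(comps) + 1, GAP, gap_length=length
                )
            )
        else:
            raise ValueError(tok)
        pos += length
    return Scaffold(sid, comps)


def make_hits(sid: str, *markers: tuple[str, str, float, int]):
    """(id, lg, cm, bp) tuples -> list of (Marker, MarkerAlignment)."""
    return [
        (Marker(mid, lg, cm), MarkerAlignment(mid, sid, bp, "+"))
        for mid, lg, cm, bp in markers
    ]


def small_fixture_config(seed: int, **overrides) -> FixtureConfig:
    """Scaled-down study conditions for fast whole-pipeline tests."""
    defaults = dict(
        n_chromosomes=2,
        chromosome_length=200_000,
        scaffolds_per_chromosome=3,
        small_scaffolds_per_chromosome=1,
        marker_spacing=5_000,
        cm_per_mbp=100.0,
        gap_spacing=20_000,
        n_inter_lg_chimeras=1,
        n_gapless_inversions=0,
        inversion_block_length=40_000,
        junction_clearance=8_000,
        gene_spacing=4_000,
        gene_length=1_000,
    )
    defaults.update(overrides)
    return FixtureConfig(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One generated small fixture bundle shared across read-only tests."""
    from chromanchor import fixtures

    out = tmp_path_factory.mktemp("bundle")
    manifest = fixtures.generate(small_fixture_config(seed=101), str(out))
    return manifest


def run_config_for(manifest, out_dir, **overrides):
    from chromanchor.pipeline import RunConfig

    paths = manifest["paths"]
    kw = dict(
        agp=paths["agp"],
        map=paths["map"],
        alignments=paths["alignments"],
        out_dir=str(out_dir),
        fasta=paths["fasta"],
        depth=paths["depth"],
        focal_gff=paths["focal_gff"],
        external_gff=paths["external_gff"],
        orthologs=paths["orthologs"],
        rescaffold_enabled=True,
        synteny_enabled=True,
    )
    kw.update(overrides)
    return RunConfig(**kw)


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """A finished pipeline run on the shared small bundle."""
    from chromanchor import pipeline

    out = tmp_path_factory.mktemp("run")
    result = pipeline.run(run_config_for(small_bundle, out))
    return small_bundle, result, out
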