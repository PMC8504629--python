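"""Shared fixtures: one default synthetic world + one pipeline run per session."""

from __future__ import annotations

from pathlib import Path

import pytest

from smorf_caller import FilterConfig, TranscriptModel, make_world, run_pipeline

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def world(tmp_path_factory) -> dict:
    """The default synthetic world (seed 1, default generator parameters)."""
    out = tmp_path_factory.mktemp("world")
    manifest = make_world(out, seed=DEFAULT_SEED)
    return {
        "dir": Path(out),
        "genome": Path(out) / "genome.fa",
        "gtf": Path(out) / "annot.gtf",
        "ribo": Path(out) / "ribo.bam",
        "rna": Path(out) / "rna.bam",
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def pipeline_run(world, tmp_path_factory):
    """Full pipeline run on the default world, with outputs on disk."""
    out = tmp_path_factory.mktemp("pipeline_out")
    records, report = run_pipeline(
        world["genome"],
        world["gtf"],
        world["ribo"],
        world["rna"],
        config=FilterConfig(),
        out_dir=out,
    )
    return {"records": records, "report": report, "out": Path(out)}


def single_exon_tx(
    length: int,
    strand: str = "+",
    chrom: str = "chrT",
    cds: tuple[int, int] | None = None,
    biotype: str = "protein_coding",
    tid: str = "t1",
) -> TranscriptModel:
    """A single-exon transcript at genomic origin 0.

    On the + strand, transcript coordinates equal genomic coordinates, which
    keeps hand-written expectations readable; ``cds`` is given in transcript
    coordinates and converted for the strand.
    """
    cds_genomic = None
    if cds is not None:
        if strand == "+":
            cds_genomic = [cds]
        else:
            cds_genomic = [(length - cds[1], length - cds[0])]
    return TranscriptModel(
        transcript_id=tid,
        gene_id=f"g_{tid}",
        chrom=chrom,
        strand=strand,
        exons=[(0, length)],
        cds=cds_genomic or [],
        biotype=biotype,
    )
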