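"""End-to-end smORF calling: scan -> calibrate -> score -> filter -> classify.

The filter cascade is an AND of independent per-ORF gates, applied in order:
host-transcript RNA expression, RPF codon coverage, ORFScore, and RRS (the
RRS gate is skipped when no downstream region exists).  Survivors are
classified, internal ORFs discarded, and isoform duplicates / nested ORFs
collapsed into a unique set.  A run report records per-stage counts and all
effective parameters so a run can be reproduced from the report alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import annotation_io, metrics, orf_classifier, orf_scanner, psite_calibration
from .annotation_io import GenomeSequence, TranscriptModel
from .orf_classifier import ClassifiedOrf, OrfClass

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds and scan parameters for a pipeline run."""

    min_codons: int = 5
    max_codons: int = 100
    start_codons: tuple[str, ...] = ("ATG",)
    min_rna_fpkm: float = 1.0
    min_coverage: float = 0.5
    min_orf_score: float = 6.0
    min_rrs: float = 5.0
    downstream_window: int = 150
    read_length_min: int = 25
    read_length_max: int = 34
    mapq_min: int = 10
    metagene_min_reads: int = 100
    metagene_min_frame0: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "start_codons" in data:
            data["start_codons"] = tuple(data["start_codons"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_codons"] = list(d["start_codons"])
        return d


@dataclass
class RunReport:
    """Per-stage counts and effective parameters of one pipeline run."""

    config: dict
    counts: dict
    offsets: dict
    libraries: dict
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(asdict(self), out, indent=1, sort_keys=True)


_CONVENTION_NOTES = [
    "P-sites assigned as 5' end + fixed per-read-length offset from a "
    "start-codon metagene",
    "RRS downstream region for upstream ORFs is truncated at the annotated "
    "CDS start; CDS-overlapping uORFs have no release region and skip the "
    "RRS gate",
    "read uniqueness enforced by mapping-quality threshold",
]


def _coding_transcripts(transcripts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    coding = []
    for tx in transcripts:
        if tx.biotype != "protein_coding" or not tx.cds:
            continue
        cds_len = sum(e - s for s, e in tx.cds)
        if cds_len % 3 != 0:
            log.warning(
                "transcript %s CDS length %d not divisible by 3; excluded "
                "from calibration",
                tx.transcript_id,
                cds_len,
            )
            continue
        coding.append(tx)
    return coding


def run_pipeline(
    genome_fa: str | Path,
    gtf: str | Path,
    ribo_bam: str | Path,
    rna_bam: str | Path,
    config: Optional[FilterConfig] = None,
    out_dir: Optional[str | Path] = None,
    conservation: Optional[dict[str, float]] = None,
) -> tuple[list[ClassifiedOrf], RunReport]:
    """Run the full smORF-calling pipeline.

    Returns the unique filtered smORF records and a :class:`RunReport`.
    When ``out_dir`` is given, writes smorfs.bed (BED12+), metrics.tsv,
    class_composition.tsv, offsets.tsv and run_report.json there.
    ``conservation`` optionally maps ORF ids to pass-through conservation
    scores merged into the output.
    """
    config = config or FilterConfig()

    log.info("stage read_inputs: loading genome and annotation")
    genome = GenomeSequence.from_fasta(genome_fa)
    transcripts = annotation_io.read_gtf(gtf)
    transcripts = annotation_io.drop_missing_chroms(transcripts, genome)
    transcripts.sort(key=lambda t: t.transcript_id)
    if not transcripts:
        raise RuntimeError("stage read_inputs failed: no usable transcripts")

    log.info("stage calibrate: estimating P-site offsets")
    coding = _coding_transcripts(transcripts)
    offsets = psite_calibration.metagene_offsets(
        ribo_bam,
        coding,
        lengths=range(config.read_length_min, config.read_length_max + 1),
        mapq_min=config.mapq_min,
        min_reads=config.metagene_min_reads,
        min_frame0=config.metagene_min_frame0,
    )
    if offsets.offsets:
        track = psite_calibration.build_psite_track(ribo_bam, offsets, config.mapq_min)
    else:
        # no read length passed the periodicity check (e.g. empty RPF
        # library): every ORF will fail the coverage gate downstream
        log.warning("stage calibrate: no usable read length; P-site track is empty")
        track = psite_calibration.PSiteTrack()

    log.info("stage quantify: RNA library")
    rna = psite_calibration.ReadCounter(rna_bam, config.mapq_min)
    rna_lib = rna.library_size
    if rna_lib == 0:
        raise RuntimeError("stage quantify failed: empty RNA library")

    tx_fpkm: dict[str, float] = {}
    for tx in transcripts:
        count = rna.count(tx.chrom, tx.exons)
        tx_fpkm[tx.transcript_id] = metrics.fpkm(count, tx.spliced_length, rna_lib)

    counts = {
        "n_transcripts": len(transcripts),
        "n_scanned": 0,
        "fail_rna_fpkm": 0,
        "fail_coverage": 0,
        "fail_orf_score": 0,
        "fail_rrs": 0,
        "internal_discarded": 0,
        "passed": 0,
    }

    log.info("stage scan_score_filter: %d transcripts", len(transcripts))
    start_codons = frozenset(c.upper() for c in config.start_codons)
    survivors: list[ClassifiedOrf] = []
    for tx in transcripts:
        seq = annotation_io.spliced_sequence(tx, genome)
        orfs = orf_scanner.scan_transcript(
            tx,
            seq,
            min_codons=config.min_codons,
            max_codons=config.max_codons,
            start_codons=start_codons,
        )
        counts["n_scanned"] += len(orfs)
        expressed = tx_fpkm[tx.transcript_id] >= config.min_rna_fpkm
        for orf in orfs:
            if not expressed:
                counts["fail_rna_fpkm"] += 1
                continue
            m = metrics.compute_orf_metrics(
                orf, tx, track, rna, track.n_accepted, config.downstream_window
            )
            if m.coverage < config.min_coverage:
                counts["fail_coverage"] += 1
                continue
            if m.orf_score < config.min_orf_score:
                counts["fail_orf_score"] += 1
                continue
            if m.rrs is not None and m.rrs < config.min_rrs:
                counts["fail_rrs"] += 1
                continue
            orf_class = orf_classifier.classify(orf, tx)
            if orf_class is OrfClass.INTERNAL:
                counts["internal_discarded"] += 1
                continue
            counts["passed"] += 1
            survivors.append(
                ClassifiedOrf(
                    orf=orf,
                    orf_class=orf_class,
                    host_transcripts=[tx.transcript_id],
                    gene_ids=[tx.gene_id],
                    metrics=m,
                    peptide=orf_scanner.translate(seq[orf.tx_start : orf.tx_end]),
                )
            )

    log.info("stage collapse: %d pre-collapse records", len(survivors))
    records = orf_classifier.collapse_unique(survivors)
    counts["n_unique"] = len(records)

    if conservation:
        for rec in records:
            rec.conservation_score = conservation.get(rec.orf.orf_id)

    report = RunReport(
        config=config.to_dict(),
        counts=counts,
        offsets={
            str(length): {
                "p_site_offset": offsets.offsets[length],
                **offsets.stats.get(length, {}),
            }
            for length in sorted(offsets.offsets)
        },
        libraries={
            "rpf_accepted": track.n_accepted,
            "rpf_dropped": track.n_dropped,
            "rna_accepted": rna_lib,
        },
        notes=list(_CONVENTION_NOTES),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        annotation_io.write_bed12_plus(records, out_dir / "smorfs.bed")
        metrics_table(records).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        class_composition(records).to_csv(
            out_dir / "class_composition.tsv", sep="\t", index=False
        )
        offsets.to_tsv(out_dir / "offsets.tsv")
        report.to_json(out_dir / "run_report.json")

    rna.close()
    return records, report


def metrics_table(records: Sequence[ClassifiedOrf]) -> pd.DataFrame:
    """Per-ORF metrics keyed by ORF id."""
    rows = []
    for rec in records:
        m = rec.metrics
        rows.append(
            {
                "orf_id": rec.orf.orf_id,
                "orf_class": rec.orf_class.value,
                "host_transcripts": ",".join(rec.host_transcripts),
                "length_codons": rec.orf.length_codons,
                "orf_score": m.orf_score if m else None,
                "coverage": m.coverage if m else None,
                "rrs": m.rrs if m else None,
                "rpf_fpkm": m.rpf_fpkm if m else None,
                "rna_fpkm": m.rna_fpkm if m else None,
                "te": m.te if m else None,
                "peptide": rec.peptide,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "orf_id",
            "orf_class",
            "host_transcripts",
            "length_codons",
            "orf_score",
            "coverage",
            "rrs",
            "rpf_fpkm",
            "rna_fpkm",
            "te",
            "peptide",
        ],
    )


def class_composition(records: Sequence[ClassifiedOrf]) -> pd.DataFrame:
    """Class counts and fractions over a set of records."""
    if not records:
        return pd.DataFrame(columns=["orf_class", "count", "fraction"])
    counts = (
        pd.Series([r.orf_class.value for r in records])
        .value_counts()
        .rename_axis("orf_class")
        .reset_index(name="count")
        .sort_values(["count", "orf_class"], ascending=[False, True])
        .reset_index(drop=True)
    )
    counts["fraction"] = counts["count"] / counts["count"].sum()
    return counts
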