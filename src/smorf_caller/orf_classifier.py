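"""Positional classification of small ORFs relative to the annotated CDS.

Classes are assigned in transcript coordinates (5'->3' on the spliced mRNA),
which makes the scheme strand-agnostic: the annotated CDS spans
[cds_start, cds_end) with the stop codon included, and an ORF [s, e) is
placed relative to those two boundaries.  ORFs fully inside the CDS in a
different frame receive the sentinel ``internal`` class and are never
emitted downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .annotation_io import TranscriptModel
from .orf_scanner import PutativeOrf

log = logging.getLogger(__name__)


class OrfClass(Enum):
    CANONICAL = "canonical"
    CANONICAL_EXTENDED = "canonical_extended"
    CANONICAL_TRUNCATED = "canonical_truncated"
    NUORF = "nuORF"
    OUORF = "ouORF"
    NDORF = "ndORF"
    ODORF = "odORF"
    NCORF = "ncORF"
    INTERNAL = "internal"  # sentinel, discarded


# when isoforms disagree, the retained label follows this precedence
CLASS_PRECEDENCE = [
    OrfClass.CANONICAL,
    OrfClass.CANONICAL_EXTENDED,
    OrfClass.CANONICAL_TRUNCATED,
    OrfClass.OUORF,
    OrfClass.NUORF,
    OrfClass.ODORF,
    OrfClass.NDORF,
    OrfClass.NCORF,
]
_RANK = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}

NONCODING_BIOTYPES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "processed_transcript",
        "pseudogene",
        "processed_pseudogene",
        "unprocessed_pseudogene",
        "transcribed_processed_pseudogene",
        "transcribed_unprocessed_pseudogene",
        "polymorphic_pseudogene",
    }
)


def is_noncoding_biotype(biotype: str) -> bool:
    return biotype in NONCODING_BIOTYPES or "pseudogene" in biotype


def classify(
    orf: PutativeOrf,
    tx: TranscriptModel,
    noncoding_biotypes: frozenset[str] = NONCODING_BIOTYPES,
) -> OrfClass:
    """Assign the positional class of ``orf`` on its host transcript.

    A transcript without an annotated CDS hosts ncORFs.  An ORF sharing the
    annotated stop codon is canonical (same start), canonical_extended
    (upstream start) or canonical_truncated (downstream in-frame start);
    otherwise the ORF is placed upstream/downstream of the CDS with the
    "o" prefix marking overlap of a CDS boundary.
    """
    cds = tx.cds_transcript_interval()
    if cds is None:
        if tx.biotype and tx.biotype not in noncoding_biotypes and not is_noncoding_biotype(tx.biotype):
            log.warning(
                "transcript %s (biotype %s) has no CDS; ORF classified ncORF",
                tx.transcript_id,
                tx.biotype,
            )
        return OrfClass.NCORF
    if tx.biotype and is_noncoding_biotype(tx.biotype):
        log.warning(
            "transcript %s has a CDS but non-coding biotype %s; classified by CDS",
            tx.transcript_id,
            tx.biotype,
        )
    s, e = orf.tx_start, orf.tx_end
    cs, ce = cds
    if e == ce:
        if s == cs:
            return OrfClass.CANONICAL
        return OrfClass.CANONICAL_EXTENDED if s < cs else OrfClass.CANONICAL_TRUNCATED
    if e <= cs:
        return OrfClass.NUORF
    if s < cs:  # e > cs and different stop: overlaps the CDS start
        return OrfClass.OUORF
    if s >= ce:
        return OrfClass.NDORF
    if e > ce:  # starts inside the CDS, ends downstream
        return OrfClass.ODORF
    return OrfClass.INTERNAL


@dataclass
class ClassifiedOrf:
    """A unique smORF record: ORF + class + metrics + peptide."""

    orf: PutativeOrf
    orf_class: OrfClass
    host_transcripts: list[str]
    gene_ids: list[str]
    metrics: Optional[object] = None  # OrfMetrics, attached by the pipeline
    peptide: str = ""
    conservation_score: Optional[float] = None


def _reading_positions(orf: PutativeOrf) -> list[int]:
    pos = [p for s, e in orf.genomic_blocks for p in range(s, e)]
    return pos if orf.strand == "+" else pos[::-1]


def _nested_same_frame(inner: PutativeOrf, outer: PutativeOrf) -> bool:
    """True when inner's blocks are a strict subset of outer's, in frame."""
    if inner.chrom != outer.chrom or inner.strand != outer.strand:
        return False
    outer_pos = _reading_positions(outer)
    inner_pos = _reading_positions(inner)
    if len(inner_pos) >= len(outer_pos):
        return False
    index = {g: i for i, g in enumerate(outer_pos)}
    first = index.get(inner_pos[0])
    if first is None or first % 3 != 0:
        return False
    # inner must be a contiguous run of outer's reading frame
    return inner_pos == outer_pos[first : first + len(inner_pos)]


def collapse_unique(
    classified: Iterable[ClassifiedOrf],
) -> list[ClassifiedOrf]:
    """Merge isoform duplicates and remove nested same-frame ORFs.

    ORFs with identical genomic blocks (found on several isoforms) are
    merged into one record listing all host transcripts; the retained class
    label and metrics follow :data:`CLASS_PRECEDENCE`.  An ORF whose blocks
    are a strict same-frame subset of another retained ORF's blocks is
    removed.  The result is independent of input order.
    """
    by_key: dict[tuple, list[ClassifiedOrf]] = {}
    for rec in classified:
        by_key.setdefault(rec.orf.block_key, []).append(rec)

    merged: list[ClassifiedOrf] = []
    for key in sorted(by_key, key=lambda k: (k[0], k[2][0][0], k[2][-1][1], k[1])):
        group = sorted(
            by_key[key],
            key=lambda r: (_RANK.get(r.orf_class, 99), sorted(r.host_transcripts)),
        )
        base = group[0]
        hosts = sorted({h for r in group for h in r.host_transcripts})
        genes = sorted({g for r in group for g in r.gene_ids})
        merged.append(
            ClassifiedOrf(
                orf=base.orf,
                orf_class=base.orf_class,
                host_transcripts=hosts,
                gene_ids=genes,
                metrics=base.metrics,
                peptide=base.peptide,
                conservation_score=base.conservation_score,
            )
        )

    keep = []
    for rec in merged:
        nested = any(
            other is not rec and _nested_same_frame(rec.orf, other.orf)
            for other in merged
        )
        if not nested:
            keep.append(rec)
    return keep
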