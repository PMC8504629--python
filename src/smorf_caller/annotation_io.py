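"""Genome FASTA and GTF input, transcript models, and BED12+ output.

All coordinates are held internally as 0-based half-open genomic intervals;
transcript coordinates are 0-based offsets into the spliced (5'->3') sequence.
GTF's 1-based closed convention is converted on read, BED's on write.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

Interval = tuple[int, int]

# columns 13..25 of the extended BED output, in order
EXTRA_COLUMNS = [
    "orf_class",
    "host_transcripts",
    "gene_ids",
    "length_codons",
    "frame_counts",
    "orf_score",
    "rrs",
    "coverage",
    "rpf_fpkm",
    "rna_fpkm",
    "te",
    "conservation_score",
    "peptide",
]

_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tthickStart\tthickEnd\titemRgb\t"
    "blockCount\tblockSizes\tblockStarts\t" + "\t".join(EXTRA_COLUMNS)
)


@dataclass
class TranscriptModel:
    """An exon-structured transcript with optional CDS.

    ``exons`` and ``cds`` are ascending, non-overlapping genomic intervals.
    The CDS interval list, when taken from a GTF, includes the stop codon
    (``stop_codon`` features are merged into it on read) so that a scanned
    ORF that coincides with the annotation spans exactly the same interval.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    biotype: str = ""
    _pos_cache: Optional[list[int]] = field(default=None, repr=False, compare=False)
    _tx_cache: Optional[dict[int, int]] = field(default=None, repr=False, compare=False)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    def reading_order_positions(self) -> list[int]:
        """Genomic positions of every spliced base in 5'->3' transcript order."""
        if self._pos_cache is None:
            pos = [p for s, e in self.exons for p in range(s, e)]
            self._pos_cache = pos if self.strand == "+" else pos[::-1]
        return self._pos_cache

    def to_transcript(self, genomic_pos: int) -> Optional[int]:
        """Transcript coordinate of a genomic position, or None if intronic."""
        if self._tx_cache is None:
            self._tx_cache = {g: t for t, g in enumerate(self.reading_order_positions())}
        return self._tx_cache.get(genomic_pos)

    def to_genomic_blocks(self, tx_interval: Interval) -> list[Interval]:
        """Project a transcript-coordinate interval to ascending genomic blocks."""
        a, b = tx_interval
        if a < 0 or b > self.spliced_length or a >= b:
            raise ValueError(
                f"interval [{a},{b}) outside spliced transcript "
                f"{self.transcript_id} (length {self.spliced_length})"
            )
        positions = sorted(self.reading_order_positions()[a:b])
        blocks: list[Interval] = []
        start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                blocks.append((start, prev + 1))
                start = p
            prev = p
        blocks.append((start, prev + 1))
        return blocks

    def cds_transcript_interval(self) -> Optional[Interval]:
        """CDS (stop codon included) as a transcript-coordinate interval."""
        if not self.cds:
            return None
        coords = []
        for s, e in self.cds:
            for g in (s, e - 1):
                t = self.to_transcript(g)
                if t is None:
                    raise ValueError(
                        f"CDS position {g} of {self.transcript_id} is not exonic"
                    )
                coords.append(t)
        return min(coords), max(coords) + 1


class GenomeSequence(dict):
    """Per-chromosome nucleotide strings, uppercase ACGTN."""

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        genome = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            genome[rec.id] = str(rec.seq).upper()
        return genome

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(f"interval [{start},{end}) outside {chrom} (len {len(seq)})")
        return seq[start:end]


_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = dict(_ATTR_QUOTED.findall(text))
    if not attrs:  # key=value dialect
        for part in text.strip().strip(";").split(";"):
            part = part.strip()
            if not part:
                continue
            if "=" in part:
                k, _, v = part.partition("=")
            else:
                k, _, v = part.partition(" ")
            attrs[k.strip()] = v.strip().strip('"')
    return attrs


def _merge_touching(intervals: list[Interval]) -> list[Interval]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gtf(
    path: str | Path,
    biotypes: Optional[set[str]] = None,
) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Exon and CDS records are grouped by ``transcript_id``; ``stop_codon``
    features are merged into the CDS so the stored CDS interval covers the
    full ORF including its stop.  Coordinates come out 0-based half-open.
    Transcripts lacking exon records are dropped with a warning, as are
    records with an unknown strand symbol.  ``biotypes``, when given,
    restricts the returned transcripts to those biotypes.
    """
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, dict] = {}
    seen: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"unparseable GTF line {lineno}: expected 9 fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_text = fields[:9]
            if feature not in ("transcript", "exon", "CDS", "stop_codon"):
                continue
            try:
                iv = (int(start) - 1, int(end))  # 1-based closed -> 0-based half-open
            except ValueError as exc:
                raise ValueError(f"unparseable GTF line {lineno}: {exc}") from None
            attrs = _parse_attributes(attr_text)
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if strand not in ("+", "-"):
                log.warning("line %d: unknown strand %r, record skipped", lineno, strand)
                continue
            seen.add(tid)
            if tid not in meta:
                biotype = (
                    attrs.get("transcript_biotype")
                    or attrs.get("gene_biotype")
                    or attrs.get("transcript_type")
                    or attrs.get("gene_type")
                    or ""
                )
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", ""),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": biotype,
                }
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feature in ("CDS", "stop_codon"):
                cds.setdefault(tid, []).append(iv)

    models = []
    for tid in sorted(seen):
        if tid not in exons:
            log.warning("transcript %s has no exon records and was dropped", tid)
            continue
        m = meta[tid]
        if biotypes is not None and m["biotype"] not in biotypes:
            continue
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=sorted(exons[tid]),
                cds=_merge_touching(cds.get(tid, [])),
                biotype=m["biotype"],
            )
        )
    return models


def drop_missing_chroms(
    transcripts: Iterable[TranscriptModel], genome: GenomeSequence
) -> list[TranscriptModel]:
    """Drop transcripts on contigs absent from the genome, with a warning."""
    kept = []
    for tx in transcripts:
        if tx.chrom not in genome:
            log.warning(
                "transcript %s on contig %s absent from genome; dropped",
                tx.transcript_id,
                tx.chrom,
            )
            continue
        kept.append(tx)
    return kept


def spliced_sequence(tx: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation."""
    parts = [genome.fetch(tx.chrom, s, e) for s, e in tx.exons]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _fmt(value, nd: int = 4) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.{nd}g}"
    return str(value)


def write_bed12_plus(records: Sequence, path: str | Path) -> None:
    """Write classified ORFs as a BED12+ table loadable in a genome browser.

    Columns 1-12 are standard BED12; columns 13-25 carry the class label,
    host transcripts, metrics and the peptide sequence (final column).
    """
    with open(path, "w") as out:
        out.write(_BED_HEADER + "\n")
        for rec in records:
            orf = rec.orf
            blocks = list(orf.genomic_blocks)
            if not blocks:
                raise ValueError(f"record {rec} lacks genomic blocks")
            start = blocks[0][0]
            end = blocks[-1][1]
            name = f"{orf.chrom}:{start}-{end}:{orf.strand}"
            m = rec.metrics
            score = 0
            if m is not None and m.orf_score is not None:
                score = int(max(0, min(1000, round(m.orf_score * 100))))
            row = [
                orf.chrom,
                str(start),
                str(end),
                name,
                str(score),
                orf.strand,
                str(start),
                str(end),
                "0",
                str(len(blocks)),
                ",".join(str(e - s) for s, e in blocks),
                ",".join(str(s - start) for s, _e in blocks),
                rec.orf_class.value,
                ",".join(rec.host_transcripts),
                ",".join(rec.gene_ids),
                str(orf.length_codons),
                ";".join(str(int(round(c))) for c in (m.frame_counts if m else (0, 0, 0))),
                _fmt(m.orf_score if m else None),
                _fmt(m.rrs if m else None),
                _fmt(m.coverage if m else None),
                _fmt(m.rpf_fpkm if m else None),
                _fmt(m.rna_fpkm if m else None),
                _fmt(m.te if m else None),
                _fmt(rec.conservation_score),
                rec.peptide or "",
            ]
            out.write("\t".join(row) + "\n")


def read_bed12_plus(path: str | Path) -> list[dict]:
    """Parse a BED12+ file written by :func:`write_bed12_plus`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].split(",") if x]
            offsets = [int(x) for x in f[11].split(",") if x]
            blocks = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "name": f[3],
                "score": int(f[4]),
                "strand": f[5],
                "blocks": blocks,
            }
            for key, value in zip(EXTRA_COLUMNS, f[12:]):
                row[key] = value
            rows.append(row)
    return rows


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write chromosome sequences as wrapped FASTA."""
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
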