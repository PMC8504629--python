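"""Enumeration of putative small ORFs on spliced transcript sequences.

A putative ORF is a maximal open reading frame: it runs from the first
permitted start codon after the previous in-frame stop to the next in-frame
stop codon.  In-frame start codons downstream of the chosen start (before the
same stop) are recorded as alternative starts but never emitted as separate
ORFs, so no two emitted ORFs on one transcript share a (frame, stop) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import FrozenSet, Optional

from Bio.Data.CodonTable import standard_dna_table

from .annotation_io import Interval, TranscriptModel

log = logging.getLogger(__name__)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
DEFAULT_START_CODONS = frozenset({"ATG"})
_CODON_TO_AA = dict(standard_dna_table.forward_table)

DEFAULT_MIN_CODONS = 5
DEFAULT_MAX_CODONS = 100
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class PutativeOrf:
    """A start..stop interval in transcript coordinates with genomic blocks.

    ``tx_end`` points one past the stop codon; ``length_codons`` counts sense
    codons only (the stop codon is excluded).
    """

    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    genomic_blocks: tuple[Interval, ...]
    alt_starts: tuple[int, ...] = field(default=())

    @property
    def length_nt(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def length_codons(self) -> int:
        return (self.tx_end - self.tx_start) // 3 - 1

    @property
    def orf_id(self) -> str:
        start = self.genomic_blocks[0][0]
        end = self.genomic_blocks[-1][1]
        return f"{self.chrom}:{start}-{end}:{self.strand}"

    @property
    def block_key(self) -> tuple:
        return (self.chrom, self.strand, self.genomic_blocks)


def translate(seq: str) -> str:
    """Translate a nucleotide sequence with the standard genetic code.

    A trailing stop codon is allowed and rendered as nothing; an internal
    stop raises ``ValueError``; codons containing non-ACGT characters
    translate to ``X``.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    peptide = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at position {3 * i}")
        peptide.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(peptide)


def scan_transcript(
    tx: TranscriptModel,
    seq: str,
    min_codons: int = DEFAULT_MIN_CODONS,
    max_codons: int = DEFAULT_MAX_CODONS,
    start_codons: FrozenSet[str] = DEFAULT_START_CODONS,
) -> list[PutativeOrf]:
    """Scan the spliced sequence of ``tx`` in all three frames for smORFs.

    Returns every maximal ORF whose sense-codon count lies in
    [min_codons, max_codons].  ORFs without an in-frame stop before the
    transcript end are excluded.  Transcripts with more than 10% ambiguous
    bases are skipped with a warning.
    """
    seq = seq.upper()
    if len(seq) >= 3 and seq.count("N") / len(seq) > MAX_N_FRACTION:
        log.warning(
            "transcript %s skipped: >10%% ambiguous bases", tx.transcript_id
        )
        return []
    orfs: list[PutativeOrf] = []
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if starts:
                    s, e = starts[0], i + 3
                    length = (e - s) // 3 - 1
                    if min_codons <= length <= max_codons:
                        orfs.append(
                            PutativeOrf(
                                transcript_id=tx.transcript_id,
                                chrom=tx.chrom,
                                strand=tx.strand,
                                tx_start=s,
                                tx_end=e,
                                genomic_blocks=tuple(tx.to_genomic_blocks((s, e))),
                                alt_starts=tuple(starts[1:]),
                            )
                        )
                    starts = []
            elif codon in start_codons:
                starts.append(i)
    orfs.sort(key=lambda o: (o.tx_start, o.tx_end))
    return orfs


def project_to_genome(tx: TranscriptModel, tx_interval: Interval) -> list[Interval]:
    """Project a transcript-coordinate interval through the exon structure.

    Blocks ascend genomically and their total length equals the interval
    length regardless of strand.
    """
    return tx.to_genomic_blocks(tx_interval)
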