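"""P-site offset calibration and strand-aware P-site count tracks.

Ribosome-protected fragments are assigned a P-site at a fixed per-read-length
offset from the read 5' end (the dominant Ribo-Seq convention).  Offsets are
estimated from a metagene of read 5' ends around annotated start codons:
initiating ribosomes accumulate over the start codon, so the upstream peak of
the 5'-end histogram sits exactly one offset before the start.  Read lengths
whose offset places fewer than half of the P-sites in frame 0 over annotated
CDSs are rejected.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .annotation_io import Interval, TranscriptModel

log = logging.getLogger(__name__)

DEFAULT_READ_LENGTHS = range(25, 35)
DEFAULT_MAPQ_MIN = 10
DEFAULT_METAGENE_WINDOW = (-40, 20)
DEFAULT_MIN_READS = 100
DEFAULT_MIN_FRAME0 = 0.5


@dataclass
class OffsetTable:
    """Per-read-length 5'-end P-site offsets with calibration statistics."""

    offsets: dict[int, int]
    stats: dict[int, dict] = field(default_factory=dict)

    @property
    def accepted_lengths(self) -> set[int]:
        return set(self.offsets)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("read_length\tp_site_offset\tn_reads\tframe0_fraction\n")
            for length in sorted(self.offsets):
                st = self.stats.get(length, {})
                out.write(
                    f"{length}\t{self.offsets[length]}\t"
                    f"{st.get('n_reads', 'NA')}\t{st.get('frame0_fraction', 'NA')}\n"
                )


@dataclass
class PSiteTrack:
    """Sparse per-(chrom, strand) genomic P-site counts."""

    counts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    n_accepted: int = 0
    n_dropped: int = 0

    def add(self, chrom: str, strand: str, pos: int) -> None:
        self.counts.setdefault((chrom, strand), Counter())[pos] += 1
        self.n_accepted += 1

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand), {}).get(pos, 0)

    def region_sum(self, chrom: str, strand: str, blocks: Iterable[Interval]) -> int:
        track = self.counts.get((chrom, strand))
        if not track:
            return 0
        return sum(track.get(p, 0) for s, e in blocks for p in range(s, e))

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())


def _passes(read: pysam.AlignedSegment, mapq_min: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_qcfail
        and read.mapping_quality >= mapq_min
    )


def _read_length(read: pysam.AlignedSegment) -> Optional[int]:
    length = read.infer_read_length()
    if length is None and read.query_sequence:
        length = len(read.query_sequence)
    return length


def metagene_offsets(
    bam_path: str | Path,
    transcripts: Sequence[TranscriptModel],
    lengths: Iterable[int] = DEFAULT_READ_LENGTHS,
    window: tuple[int, int] = DEFAULT_METAGENE_WINDOW,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    min_reads: int = DEFAULT_MIN_READS,
    min_frame0: float = DEFAULT_MIN_FRAME0,
) -> OffsetTable:
    """Estimate per-read-length P-site offsets from a start-codon metagene.

    For each read length the histogram of 5'-end positions relative to
    annotated start codons (transcript coordinates, window [-40, +20]) is
    accumulated over all coding transcripts; the offset is the negated
    position of the upstream peak.  Lengths with fewer than ``min_reads``
    usable reads, or whose offset leaves less than ``min_frame0`` of P-sites
    in frame 0, are rejected with a warning.
    """
    lengths = set(lengths)
    hists: dict[int, Counter] = {L: Counter() for L in lengths}
    lo, hi = window
    with pysam.AlignmentFile(str(bam_path)) as bam:
        chroms = set(bam.references)
        for tx in transcripts:
            cds = tx.cds_transcript_interval()
            if cds is None or tx.chrom not in chroms:
                continue
            cs = cds[0]
            span = tx.span
            for read in bam.fetch(tx.chrom, span[0], span[1]):
                if not _passes(read, mapq_min):
                    continue
                length = _read_length(read)
                if length not in lengths:
                    continue
                if read.is_reverse != (tx.strand == "-"):
                    continue
                g5 = read.reference_end - 1 if read.is_reverse else read.reference_start
                t5 = tx.to_transcript(g5)
                if t5 is None:
                    continue
                rel = t5 - cs
                if lo <= rel <= hi:
                    hists[length][rel] += 1

    offsets: dict[int, int] = {}
    stats: dict[int, dict] = {}
    for length in sorted(lengths):
        hist = hists[length]
        n = sum(hist.values())
        if n < min_reads:
            log.warning(
                "read length %d rejected: %d usable reads (< %d)", length, n, min_reads
            )
            continue
        upstream = {rel: c for rel, c in hist.items() if rel < 0}
        if not upstream:
            log.warning("read length %d rejected: no upstream 5'-end signal", length)
            continue
        # tie-break toward the position closest to the start codon
        peak = max(sorted(upstream), key=lambda r: (upstream[r], r))
        offset = -peak
        frame0 = sum(c for rel, c in hist.items() if (rel + offset) % 3 == 0) / n
        if frame0 < min_frame0:
            log.warning(
                "read length %d rejected: frame-0 fraction %.2f < %.2f",
                length,
                frame0,
                min_frame0,
            )
            continue
        offsets[length] = offset
        stats[length] = {"n_reads": n, "frame0_fraction": round(frame0, 4)}
    return OffsetTable(offsets=offsets, stats=stats)


def build_psite_track(
    bam_path: str | Path,
    offsets: OffsetTable,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> PSiteTrack:
    """Convert accepted RPF alignments into a strand-aware P-site track.

    Each accepted read contributes one count at its offset P-site; the
    offset is applied along the aligned reference positions, so junction
    (N-CIGAR) reads land on the correct exonic base.  Reads of rejected
    lengths, secondary/supplementary alignments and low-MAPQ reads are
    dropped and counted.
    """
    track = PSiteTrack()
    n_mapped = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            n_mapped += 1
            if not _passes(read, mapq_min):
                track.n_dropped += 1
                continue
            length = _read_length(read)
            offset = offsets.offsets.get(length)
            if offset is None:
                track.n_dropped += 1
                continue
            refpos = read.get_reference_positions()
            if len(refpos) <= offset:
                track.n_dropped += 1
                continue
            if read.is_reverse:
                strand, pos = "-", refpos[-1 - offset]
            else:
                strand, pos = "+", refpos[offset]
            track.add(read.reference_name, strand, pos)
    if n_mapped == 0:
        raise ValueError(f"{bam_path}: no mapped reads")
    if track.n_dropped:
        log.info("P-site track: %d reads dropped", track.n_dropped)
    return track


class ReadCounter:
    """Counts alignments overlapping genomic regions (RNA-Seq quantification).

    RNA reads are never offset: a read counts toward a feature when its
    alignment overlaps any of the feature's blocks, irrespective of strand
    (unstranded library convention).
    """

    def __init__(self, bam_path: str | Path, mapq_min: int = DEFAULT_MAPQ_MIN):
        self.path = str(bam_path)
        self.mapq_min = mapq_min
        self._bam = pysam.AlignmentFile(self.path)
        self._library_size: Optional[int] = None

    @property
    def library_size(self) -> int:
        if self._library_size is None:
            n = 0
            with pysam.AlignmentFile(self.path) as bam:
                for read in bam.fetch(until_eof=True):
                    if not read.is_unmapped and _passes(read, self.mapq_min):
                        n += 1
            self._library_size = n
        return self._library_size

    def count(self, chrom: str, blocks: Iterable[Interval]) -> int:
        if chrom not in self._bam.references:
            return 0
        names = set()
        for s, e in blocks:
            for read in self._bam.fetch(chrom, s, e):
                if _passes(read, self.mapq_min):
                    names.add(read.query_name)
        return len(names)

    def close(self) -> None:
        self._bam.close()

    def __enter__(self) -> "ReadCounter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
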