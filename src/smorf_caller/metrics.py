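"""Per-ORF translation-evidence metrics.

ORFScore measures the bias of P-site counts toward an ORF's first reading
frame: with frame totals (F1, F2, F3) and mean F-bar it is
``log2(1 + sum_i (Fi - Fbar)^2 / Fbar)``, negated when frame 1 is not the
maximal frame.  The first and last sense codon are excluded (initiation and
termination peaks distort the frame distribution) and per-codon counts are
capped at the 97.5th percentile of codon totals within the ORF.

The ribosome release score (RRS) contrasts RPF density inside the ORF with
the region downstream of its stop codon, normalised by the same RNA-Seq
ratio; a pseudocount of 1 on every raw count keeps it finite on sparse data.
Translation efficiency (TE) is the ratio of RPF to RNA FPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotation_io import TranscriptModel
from .orf_scanner import PutativeOrf
from .psite_calibration import PSiteTrack, ReadCounter

CAP_QUANTILE = 97.5
DEFAULT_DOWNSTREAM_WINDOW = 150


@dataclass
class OrfMetrics:
    """Translation-evidence metrics for one ORF."""

    frame_counts: tuple[float, float, float]
    orf_score: float
    coverage: float
    rrs: Optional[float]
    rpf_fpkm: float
    rna_fpkm: float
    te: Optional[float]


def _reading_positions(orf: PutativeOrf) -> list[int]:
    pos = [p for s, e in orf.genomic_blocks for p in range(s, e)]
    return pos if orf.strand == "+" else pos[::-1]


def codon_frame_matrix(orf: PutativeOrf, track: PSiteTrack) -> np.ndarray:
    """P-site counts per (sense codon, frame), shape (length_codons, 3)."""
    positions = _reading_positions(orf)[: 3 * orf.length_codons]
    sub = track.counts.get((orf.chrom, orf.strand), {})
    counts = np.fromiter(
        (sub.get(p, 0) for p in positions), dtype=float, count=len(positions)
    )
    return counts.reshape(-1, 3)


def frame_counts(
    orf: PutativeOrf, track: PSiteTrack, cap_quantile: float = CAP_QUANTILE
) -> tuple[float, float, float]:
    """Frame totals over interior codons, with per-codon capping."""
    matrix = codon_frame_matrix(orf, track)
    if matrix.shape[0] < 3:
        raise ValueError(f"ORF {orf.orf_id} too short for frame statistics")
    interior = matrix[1:-1].copy()
    totals = interior.sum(axis=1)
    if totals.size and totals.max() > 0:
        cap = np.percentile(totals, cap_quantile)
        over = totals > cap
        if cap > 0 and over.any():
            interior[over] *= (cap / totals[over])[:, None]
    f1, f2, f3 = interior.sum(axis=0)
    return float(f1), float(f2), float(f3)


def orf_score(frame_totals: Sequence[float]) -> float:
    """Log2 chi-square-style frame-bias statistic, sign-negated off-frame.

    All-zero counts give 0; frame totals must be non-negative.
    """
    f1, f2, f3 = frame_totals
    if f1 < 0 or f2 < 0 or f3 < 0:
        raise ValueError("frame counts must be non-negative")
    mean = (f1 + f2 + f3) / 3.0
    if mean == 0:
        return 0.0
    chi = sum((f - mean) ** 2 / mean for f in (f1, f2, f3))
    score = math.log2(1.0 + chi)
    if f2 > f1 or f3 > f1:
        score = -score
    return score


def codon_coverage(orf: PutativeOrf, track: PSiteTrack) -> float:
    """Fraction of interior codons with at least one frame-0 P-site."""
    if orf.length_codons <= 0:
        raise ValueError(f"ORF {orf.orf_id} has no sense codons")
    matrix = codon_frame_matrix(orf, track)
    if matrix.shape[0] < 3:
        raise ValueError(f"ORF {orf.orf_id} too short for coverage")
    inner = matrix[1:-1, 0]
    return float(np.mean(inner > 0))


def downstream_region(
    orf: PutativeOrf,
    tx: TranscriptModel,
    window: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> Optional[tuple[int, int]]:
    """Transcript interval downstream of the ORF stop used for the RRS.

    For ORFs lying upstream of an annotated CDS with a different stop codon,
    the region is truncated at the CDS start (the main ORF is itself
    translated and would mask ribosome release); when that leaves nothing
    (CDS-overlapping uORFs) the RRS is reported missing.
    """
    start = orf.tx_end
    end = min(tx.spliced_length, start + window)
    cds = tx.cds_transcript_interval()
    if cds is not None:
        cs, ce = cds
        if orf.tx_start < cs and orf.tx_end != ce:
            end = min(end, cs)
    if end <= start:
        return None
    return start, end


def rrs(
    orf: PutativeOrf,
    track_rpf: PSiteTrack,
    rna: ReadCounter,
    tx: TranscriptModel,
    window: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> Optional[float]:
    """Ribosome release score; None when no downstream region exists."""
    region = downstream_region(orf, tx, window)
    if region is None:
        return None
    dn_blocks = tx.to_genomic_blocks(region)
    orf_len = orf.length_nt
    dn_len = region[1] - region[0]

    rpf_orf = track_rpf.region_sum(orf.chrom, orf.strand, orf.genomic_blocks) + 1
    rpf_dn = track_rpf.region_sum(orf.chrom, orf.strand, dn_blocks) + 1
    rna_orf = rna.count(orf.chrom, orf.genomic_blocks) + 1
    rna_dn = rna.count(orf.chrom, dn_blocks) + 1

    rpf_ratio = (rpf_orf / orf_len) / (rpf_dn / dn_len)
    rna_ratio = (rna_orf / orf_len) / (rna_dn / dn_len)
    return rpf_ratio / rna_ratio


def fpkm(count: int, feature_len: int, library_size: int) -> float:
    """Fragments per kilobase of feature per million mapped reads."""
    if feature_len <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count * 1e9 / (feature_len * library_size)


def translation_efficiency(rpf_fpkm: float, rna_fpkm: float) -> Optional[float]:
    """RPF FPKM over RNA FPKM; undefined (None) when RNA FPKM is zero."""
    if rna_fpkm < 0:
        raise ValueError("RNA FPKM must be non-negative")
    if rna_fpkm == 0:
        return None
    return rpf_fpkm / rna_fpkm


def compute_orf_metrics(
    orf: PutativeOrf,
    tx: TranscriptModel,
    track: PSiteTrack,
    rna: ReadCounter,
    rpf_library_size: int,
    window: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> OrfMetrics:
    """All translation-evidence metrics for one ORF on one host transcript."""
    fc = frame_counts(orf, track)
    rpf_count = track.region_sum(orf.chrom, orf.strand, orf.genomic_blocks)
    rna_count = rna.count(orf.chrom, orf.genomic_blocks)
    rpf_f = fpkm(rpf_count, orf.length_nt, max(rpf_library_size, 1))
    rna_f = fpkm(rna_count, orf.length_nt, max(rna.library_size, 1))
    return OrfMetrics(
        frame_counts=fc,
        orf_score=orf_score(fc),
        coverage=codon_coverage(orf, track),
        rrs=rrs(orf, track, rna, tx, window),
        rpf_fpkm=rpf_f,
        rna_fpkm=rna_f,
        te=translation_efficiency(rpf_f, rna_f),
    )
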