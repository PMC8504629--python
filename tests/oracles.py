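"""Independent brute-force oracles used to validate the implementation.

These deliberately use different algorithms from the package: exhaustive
substring enumeration for ORF scanning, per-base coordinate walking for
genomic projection, and a flat explicit case analysis for classification.
"""

from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}


def orf_scan_oracle(
    seq: str,
    min_codons: int = 5,
    max_codons: int = 100,
    start_codons: frozenset = frozenset({"ATG"}),
) -> set[tuple[int, int]]:
    """Every maximal (first-start, first-stop) ORF via substring enumeration.

    For each start-codon occurrence, walk to the first in-frame stop; group
    candidates by their stop and keep the earliest start; filter by length.
    Returns a set of (tx_start, tx_end) pairs.
    """
    seq = seq.upper()
    candidates = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] not in start_codons:
            continue
        j = i
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in STOPS:
                if j > i:  # a start immediately followed by... j==i impossible
                    candidates.append((i, j + 3))
                break
            j += 3
    first_start_per_stop: dict[int, int] = {}
    for s, e in candidates:
        if e not in first_start_per_stop or s < first_start_per_stop[e]:
            first_start_per_stop[e] = s
    result = set()
    for e, s in first_start_per_stop.items():
        n_codons = (e - s) // 3 - 1
        if min_codons <= n_codons <= max_codons:
            result.add((s, e))
    return result


def projection_oracle(
    exons: list[tuple[int, int]], strand: str, a: int, b: int
) -> list[tuple[int, int]]:
    """Project [a, b) transcript coords to genomic blocks, base by base."""
    bases = [p for s, e in exons for p in range(s, e)]
    if strand == "-":
        bases = bases[::-1]
    picked = sorted(bases[a:b])
    blocks: list[tuple[int, int]] = []
    for p in picked:
        if blocks and p == blocks[-1][1]:
            blocks[-1] = (blocks[-1][0], p + 1)
        else:
            blocks.append((p, p + 1))
    return blocks


def classify_oracle(
    s: int, e: int, cds: tuple[int, int] | None, has_cds: bool = True
) -> str:
    """Explicit flat case analysis of ORF [s, e) against CDS [cs, ce).

    The CDS interval includes the stop codon.  Returns the class label
    string, with "internal" marking ORFs to be discarded.
    """
    if cds is None or not has_cds:
        return "ncORF"
    cs, ce = cds
    same_stop = e == ce
    if same_stop and s == cs:
        return "canonical"
    if same_stop and s < cs:
        return "canonical_extended"
    if same_stop and s > cs:
        return "canonical_truncated"
    entirely_upstream = e <= cs
    entirely_downstream = s >= ce
    if entirely_upstream:
        return "nuORF"
    if entirely_downstream:
        return "ndORF"
    starts_upstream = s < cs
    ends_downstream = e > ce
    starts_inside = cs <= s < ce
    if starts_upstream:
        return "ouORF"
    if starts_inside and ends_downstream:
        return "odORF"
    return "internal"
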