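"""Self-contained synthetic test world for the smORF pipeline.

:func:`make_world` writes a toy genome FASTA, a GTF annotation, coordinate-
sorted + indexed ribosome-profiling and RNA-Seq BAM files, and a ground-truth
JSON manifest.  The world plants translated smORFs of every positional class
(canonical, canonical_extended, canonical_truncated, nuORF, ouORF, ndORF,
odORF, ncORF), isoform pairs sharing one ORF, a nested same-frame ORF trap,
and untranslated decoy ORFs (silent, stop-codon read-through, non-periodic,
and non-expressed hosts).

RPF reads are simulated only on translated features: P-sites are drawn
per codon (Poisson, rate ``depth x abundance x te``), placed in frame 0 with
probability ``fidelity`` (else shifted +1/+2 nt), terminated at the stop
codon, and emitted as reads whose 5' end sits one per-length offset upstream
of the P-site.  Initiating ribosomes accumulate over the start codon
(``init_peak``-fold rate), which is what makes metagene offset calibration
identifiable.  RNA reads are uniform over the spliced transcript,
proportional to abundance.  All randomness flows from one seeded generator,
so re-running with the same seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam
from Bio.Seq import Seq

from .annotation_io import write_fasta

STOPS = ("TAA", "TAG", "TGA")
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE = [c for c in _ALL_CODONS if c not in STOPS]
SENSE_NO_ATG = [c for c in SENSE if c != "ATG"]

ALL_CLASSES = (
    "canonical",
    "canonical_extended",
    "canonical_truncated",
    "nuORF",
    "ouORF",
    "ndORF",
    "odORF",
    "ncORF",
)

DEFAULT_OFFSETS = {28: 12, 30: 13}
RNA_READ_LEN = 50
INTRON_LEN = 150
SPACER = 800


@dataclass
class _Feature:
    """A translated stretch: P-sites over ``n_codons`` codons from ``tx_start``."""

    tx_start: int
    n_codons: int
    mode: str  # "periodic" | "nonperiodic"
    te_mult: float = 1.0


@dataclass
class _Planted:
    tx_start: int
    tx_end: int
    label: str
    translated: bool
    expected_unique: bool = True
    decoy_type: Optional[str] = None
    te_mult: float = 1.0


@dataclass
class _TxPlan:
    tid: str
    gene: str
    biotype: str
    strand: str
    spliced: str
    exon_lengths: list[int]  # transcript order
    cds_tx: Optional[tuple[int, int]]  # stop codon included
    planted: list[_Planted]
    features: list[_Feature]
    abundance: float
    group: Optional[str] = None
    exon_layout: Optional[list[tuple[int, int]]] = None  # (rel offset, length)
    exons: list[tuple[int, int]] = field(default_factory=list)
    chrom: str = ""
    positions: list[int] = field(default_factory=list)


class FixtureManifest:
    """Ground truth for a generated world; the oracle for pipeline tests."""

    def __init__(self, data: dict):
        self.data = data

    def save(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(self.data, out, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "FixtureManifest":
        with open(path) as fh:
            return cls(json.load(fh))

    @property
    def orfs(self) -> list[dict]:
        return self.data["orfs"]

    @property
    def transcripts(self) -> list[dict]:
        return self.data["transcripts"]

    @property
    def params(self) -> dict:
        return self.data["params"]

    def expected_ids(self) -> set[str]:
        """ORF ids of planted translated smORFs expected in pipeline output."""
        return {
            o["orf_id"]
            for o in self.orfs
            if o["translated"] and o["expected_unique"]
        }

    def decoy_ids(self) -> set[str]:
        return {o["orf_id"] for o in self.orfs if not o["translated"]}


# ---------------------------------------------------------------------------
# sequence construction helpers


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _filler(rng: np.random.Generator, n: int) -> str:
    """Random sequence free of ATG (keeps UTRs free of unplanned starts)."""
    s = _rand_bases(rng, n)
    while "ATG" in s:
        s = s.replace("ATG", "ATC", 1)
    return s


def _codons(rng: np.random.Generator, n: int, pool: Sequence[str] = SENSE) -> str:
    return "".join(pool[i] for i in rng.integers(0, len(pool), n))


def _orf_nt(rng: np.random.Generator, n_sense: int, pool: Sequence[str] = SENSE) -> str:
    """ATG + (n_sense - 1) sense codons + stop; 3*(n_sense+1) nt."""
    return "ATG" + _codons(rng, n_sense - 1, pool) + STOPS[rng.integers(0, 3)]


def _check_planted(seq: str, s: int, e: int) -> bool:
    """Verify a planted ORF is exactly what a first-ATG scanner would emit."""
    if (e - s) % 3 != 0 or seq[s : s + 3] != "ATG" or seq[e - 3 : e] not in STOPS:
        return False
    for i in range(s, e - 3, 3):
        if seq[i : i + 3] in STOPS:
            return False
    p = s - 3
    while p >= 0:
        codon = seq[p : p + 3]
        if codon in STOPS:
            break
        if codon == "ATG":
            return False
        p -= 3
    return True


def _validated(plan: _TxPlan) -> _TxPlan:
    for orf in plan.planted:
        if not _check_planted(plan.spliced, orf.tx_start, orf.tx_end):
            raise RuntimeError(
                f"fixture construction violated ORF invariants in {plan.tid}"
            )
    return plan


# ---------------------------------------------------------------------------
# per-class transcript builders


def _build_canonical(rng) -> _TxPlan:
    u5, orf, u3 = _filler(rng, 70), _orf_nt(rng, 60), _filler(rng, 200)
    s, e = 70, 70 + len(orf)
    return _validated(
        _TxPlan(
            tid="tx_canonical",
            gene="g_canonical",
            biotype="protein_coding",
            strand="+",
            spliced=u5 + orf + u3,
            exon_lengths=[150, 70 + len(orf) + 200 - 150],
            cds_tx=(s, e),
            planted=[_Planted(s, e, "canonical", True, te_mult=2.0)],
            features=[_Feature(s, 60, "periodic", 2.0)],
            abundance=1.0,
        )
    )


def _build_extended(rng) -> _TxPlan:
    u5 = _filler(rng, 40)
    ext = "ATG" + _codons(rng, 7)
    cds = "ATG" + _codons(rng, 49) + STOPS[rng.integers(0, 3)]
    u3 = _filler(rng, 200)
    s = 40
    cs = 40 + len(ext)
    e = cs + len(cds)
    return _validated(
        _TxPlan(
            tid="tx_extended",
            gene="g_extended",
            biotype="protein_coding",
            strand="-",
            spliced=u5 + ext + cds + u3,
            exon_lengths=[120, 40 + len(ext) + len(cds) + 200 - 120],
            cds_tx=(cs, e),
            planted=[_Planted(s, e, "canonical_extended", True)],
            features=[_Feature(s, (e - s) // 3 - 1, "periodic")],
            abundance=2.0,
        )
    )


def _build_truncated(rng) -> _TxPlan:
    # annotated start is a non-AUG (CTG) codon; the scanner starts at the
    # first in-frame ATG ten codons in, sharing the annotated stop
    u5 = _filler(rng, 60)
    cds = "CTG" + _codons(rng, 9, SENSE_NO_ATG) + "ATG" + _codons(rng, 49)
    cds += STOPS[rng.integers(0, 3)]
    u3 = _filler(rng, 180)
    cs, ce = 60, 60 + len(cds)
    s = cs + 30
    return _validated(
        _TxPlan(
            tid="tx_truncated",
            gene="g_truncated",
            biotype="protein_coding",
            strand="+",
            spliced=u5 + cds + u3,
            exon_lengths=[60 + len(cds) + 180],
            cds_tx=(cs, ce),
            planted=[_Planted(s, ce, "canonical_truncated", True)],
            features=[_Feature(s, (ce - s) // 3 - 1, "periodic")],
            abundance=1.0,
        )
    )


def _build_nuorf(rng) -> _TxPlan:
    u5a = _filler(rng, 30)
    uorf = _orf_nt(rng, 24)
    gap = _filler(rng, 40)
    cds = "ATG" + _codons(rng, 129) + STOPS[rng.integers(0, 3)]
    u3 = _filler(rng, 200)
    s = 30
    e = s + len(uorf)
    cs = e + 40
    ce = cs + len(cds)
    return _validated(
        _TxPlan(
            tid="tx_nuorf",
            gene="g_nuorf",
            biotype="protein_coding",
            strand="+",
            spliced=u5a + uorf + gap + cds + u3,
            exon_lengths=[250, ce + 200 - 250],
            cds_tx=(cs, ce),
            planted=[_Planted(s, e, "nuORF", True, te_mult=2.0)],
            features=[_Feature(s, 24, "periodic", 2.0), _Feature(cs, 130, "periodic")],
            abundance=1.0,
        )
    )


def _build_ouorf(rng) -> _TxPlan:
    # an upstream ORF whose stop codon lies a few codons inside the main CDS
    for _ in range(200):
        cds = "ATG" + _codons(rng, 129) + STOPS[rng.integers(0, 3)]
        hit = None
        for delta in (1, 2):
            for j in range(8):
                q = delta + 3 * j
                if cds[q : q + 3] in STOPS:
                    hit = (delta, q)
                    break
            if hit:
                break
        if hit is None:
            continue
        _delta, q = hit
        e_rel = q + 3  # ouORF end, relative to CDS start
        n_codons = 25 + e_rel // 3
        up_nt = 3 * (n_codons + 1) - e_rel
        for _ in range(50):
            upstream = "ATG" + _rand_bases(rng, up_nt - 3)
            ou = upstream + cds[:e_rel]
            if any(ou[3 * k : 3 * k + 3] in STOPS for k in range(n_codons)):
                continue
            if "ATG" in upstream[1:]:  # keep the planted start the first ATG
                continue
            u5 = _filler(rng, 50)
            u3 = _filler(rng, 200)
            spliced = u5 + upstream + cds + u3
            s = 50
            cs = 50 + up_nt
            ce = cs + len(cds)
            e = s + 3 * (n_codons + 1)
            plan = _TxPlan(
                tid="tx_ouorf",
                gene="g_ouorf",
                biotype="protein_coding",
                strand="-",
                spliced=spliced,
                exon_lengths=[200, len(spliced) - 200],
                cds_tx=(cs, ce),
                planted=[_Planted(s, e, "ouORF", True)],
                features=[
                    _Feature(s, n_codons, "periodic"),
                    _Feature(cs, 130, "periodic"),
                ],
                abundance=2.0,
            )
            if _check_planted(spliced, s, e) and _check_planted(spliced, cs, ce):
                return plan
    raise RuntimeError("could not construct ouORF fixture")


def _build_ndorf(rng) -> _TxPlan:
    u5 = _filler(rng, 60)
    cds = "ATG" + _codons(rng, 129) + STOPS[rng.integers(0, 3)]
    u3a = _filler(rng, 40)
    dorf = _orf_nt(rng, 30)
    u3b = _filler(rng, 170)
    cs, ce = 60, 60 + len(cds)
    s = ce + 40
    e = s + len(dorf)
    return _validated(
        _TxPlan(
            tid="tx_ndorf",
            gene="g_ndorf",
            biotype="protein_coding",
            strand="+",
            spliced=u5 + cds + u3a + dorf + u3b,
            exon_lengths=[300, e + 170 - 300],
            cds_tx=(cs, ce),
            planted=[_Planted(s, e, "ndORF", True, te_mult=0.5)],
            features=[_Feature(s, 30, "periodic", 0.5), _Feature(cs, 130, "periodic")],
            abundance=2.0,
        )
    )


def _build_odorf(rng) -> _TxPlan:
    # an ORF starting at an ATG inside the CDS (different frame) whose stop
    # lies in the 3' UTR
    for _ in range(500):
        cds = "ATG" + _codons(rng, 129) + STOPS[rng.integers(0, 3)]
        ce_rel = len(cds)
        hit = None
        for delta in (1, 2):
            q = delta
            while q + 3 <= ce_rel:
                if ce_rel - 27 <= q <= ce_rel - 3 and cds[q : q + 3] == "ATG":
                    ok = True
                    r = q + 3
                    while r + 3 <= ce_rel:
                        if cds[r : r + 3] in STOPS:
                            ok = False
                            break
                        r += 3
                    if ok:
                        hit = q
                        break
                q += 3
            if hit is not None:
                break
        if hit is None:
            continue
        q = hit
        overlap_nt = ce_rel - q
        n_codons = overlap_nt // 3 + 25
        od_nt = 3 * (n_codons + 1)
        tail_nt = od_nt - overlap_nt
        for _ in range(50):
            tail = _rand_bases(rng, tail_nt - 3) + STOPS[rng.integers(0, 3)]
            od = cds[q:] + tail
            if any(od[3 * k : 3 * k + 3] in STOPS for k in range(n_codons)):
                continue
            u5 = _filler(rng, 60)
            u3 = _filler(rng, 160)
            spliced = u5 + cds + tail + u3
            cs, ce = 60, 60 + ce_rel
            s = 60 + q
            e = s + od_nt
            if not (_check_planted(spliced, s, e) and _check_planted(spliced, cs, ce)):
                continue
            return _TxPlan(
                tid="tx_odorf",
                gene="g_odorf",
                biotype="protein_coding",
                strand="-",
                spliced=spliced,
                exon_lengths=[len(spliced)],
                cds_tx=(cs, ce),
                planted=[_Planted(s, e, "odORF", True)],
                features=[
                    _Feature(s, n_codons, "periodic"),
                    _Feature(cs, 130, "periodic"),
                ],
                abundance=1.0,
            )
    raise RuntimeError("could not construct odORF fixture")


def _build_nc_lnc(rng) -> _TxPlan:
    f1, orf, f2 = _filler(rng, 60), _orf_nt(rng, 40), _filler(rng, 180)
    s, e = 60, 60 + len(orf)
    return _validated(
        _TxPlan(
            tid="tx_nclnc",
            gene="g_nclnc",
            biotype="lncRNA",
            strand="+",
            spliced=f1 + orf + f2,
            exon_lengths=[100, 60 + len(orf) + 180 - 100],
            cds_tx=None,
            planted=[_Planted(s, e, "ncORF", True)],
            features=[_Feature(s, 40, "periodic")],
            abundance=1.0,
        )
    )


def _build_nc_pseudo(rng) -> _TxPlan:
    f1, orf, f2 = _filler(rng, 50), _orf_nt(rng, 35), _filler(rng, 170)
    s, e = 50, 50 + len(orf)
    return _validated(
        _TxPlan(
            tid="tx_ncpseudo",
            gene="g_ncpseudo",
            biotype="processed_pseudogene",
            strand="-",
            spliced=f1 + orf + f2,
            exon_lengths=[50 + len(orf) + 170],
            cds_tx=None,
            planted=[_Planted(s, e, "ncORF", True)],
            features=[_Feature(s, 35, "periodic")],
            abundance=2.0,
        )
    )


def _build_isoform_pair(rng) -> list[_TxPlan]:
    """Two lncRNA isoforms sharing exon 1 and the ORF it contains."""
    exon1 = _filler(rng, 40) + _orf_nt(rng, 30) + _filler(rng, 117)
    s, e = 40, 40 + 93
    a = _TxPlan(
        tid="tx_isoA",
        gene="g_iso",
        biotype="lncRNA",
        strand="+",
        spliced=exon1 + _filler(rng, 200),
        exon_lengths=[250, 200],
        cds_tx=None,
        planted=[_Planted(s, e, "ncORF", True)],
        features=[_Feature(s, 30, "periodic")],
        abundance=1.0,
        group="iso",
        exon_layout=[(0, 250), (400, 200)],
    )
    b = _TxPlan(
        tid="tx_isoB",
        gene="g_iso",
        biotype="lncRNA",
        strand="+",
        spliced=exon1 + _filler(rng, 150),
        exon_lengths=[250, 150],
        cds_tx=None,
        planted=[_Planted(s, e, "ncORF", True, expected_unique=False,
                          decoy_type="isoform_duplicate")],
        features=[],
        abundance=1.0,
        group="iso",
        exon_layout=[(0, 250), (700, 150)],
    )
    _validated(a)
    _validated(b)
    return [a, b]


def _build_nested_pair(rng) -> list[_TxPlan]:
    """A 5'-truncated isoform whose scanned ORF is a same-frame nested
    subset of the full isoform's ORF (must be collapsed away)."""
    for _ in range(100):
        inner_atg_codon = 12
        body = (
            _codons(rng, inner_atg_codon - 1, SENSE_NO_ATG)
            + "ATG"
            + _codons(rng, 39 - inner_atg_codon)
        )
        orf = "ATG" + body + STOPS[rng.integers(0, 3)]  # 40 sense codons
        spliced_c = _filler(rng, 50) + orf + _filler(rng, 180)
        trunc = 60
        spliced_d = spliced_c[trunc:]
        s_outer, e_outer = 50, 50 + len(orf)
        s_inner = 50 + 3 * inner_atg_codon - trunc
        e_inner = e_outer - trunc
        if not _check_planted(spliced_c, s_outer, e_outer):
            continue
        if not _check_planted(spliced_d, s_inner, e_inner):
            continue
        c = _TxPlan(
            tid="tx_nestC",
            gene="g_nest",
            biotype="lncRNA",
            strand="-",
            spliced=spliced_c,
            exon_lengths=[len(spliced_c)],
            cds_tx=None,
            planted=[_Planted(s_outer, e_outer, "ncORF", True)],
            features=[_Feature(s_outer, 40, "periodic")],
            abundance=1.0,
            group="nest",
            exon_layout=[(0, len(spliced_c))],
        )
        d = _TxPlan(
            tid="tx_nestD",
            gene="g_nest",
            biotype="lncRNA",
            strand="-",
            spliced=spliced_d,
            exon_lengths=[len(spliced_d)],
            cds_tx=None,
            planted=[_Planted(s_inner, e_inner, "ncORF", True,
                              expected_unique=False, decoy_type="nested_duplicate")],
            features=[],
            abundance=1.0,
            group="nest",
            # minus strand: trimming the transcript 5' end trims the
            # genomic high end, so the shared exon keeps the same origin
            exon_layout=[(0, len(spliced_d))],
        )
        return [c, d]
    raise RuntimeError("could not construct nested-ORF fixture")


def _build_silent_decoy(rng, idx: int, abundance: float, strand: str) -> _TxPlan:
    l1, l2 = 20 + idx * 3, 26 + idx * 2
    f1 = _filler(rng, 40)
    o1 = _orf_nt(rng, l1)
    f2 = _filler(rng, 30)
    o2 = _orf_nt(rng, l2)
    f3 = _filler(rng, 330)
    s1 = 40
    e1 = s1 + len(o1)
    s2 = e1 + 30
    e2 = s2 + len(o2)
    return _validated(
        _TxPlan(
            tid=f"tx_silent{idx}",
            gene=f"g_silent{idx}",
            biotype="lncRNA",
            strand=strand,
            spliced=f1 + o1 + f2 + o2 + f3,
            exon_lengths=[e2 + 330],
            cds_tx=None,
            planted=[
                _Planted(s1, e1, "ncORF", False, decoy_type="silent"),
                _Planted(s2, e2, "ncORF", False, decoy_type="silent"),
            ],
            features=[],
            abundance=abundance,
        )
    )


def _build_readthrough_decoy(rng) -> _TxPlan:
    f1, orf, f2 = _filler(rng, 50), _orf_nt(rng, 30), _filler(rng, 200)
    s, e = 50, 50 + len(orf)
    return _validated(
        _TxPlan(
            tid="tx_readthrough",
            gene="g_readthrough",
            biotype="lncRNA",
            strand="+",
            spliced=f1 + orf + f2,
            cds_tx=None,
            exon_lengths=[50 + len(orf) + 200],
            planted=[_Planted(s, e, "ncORF", False, decoy_type="readthrough")],
            # ribosome signal runs through the stop for 40 further codons
            features=[_Feature(s, 30 + 1 + 40, "periodic")],
            abundance=1.0,
        )
    )


def _build_nonperiodic_decoy(rng) -> _TxPlan:
    f1, orf, f2 = _filler(rng, 50), _orf_nt(rng, 30), _filler(rng, 170)
    s, e = 50, 50 + len(orf)
    return _validated(
        _TxPlan(
            tid="tx_nonperiodic",
            gene="g_nonperiodic",
            biotype="lncRNA",
            strand="-",
            spliced=f1 + orf + f2,
            cds_tx=None,
            exon_lengths=[50 + len(orf) + 170],
            planted=[_Planted(s, e, "ncORF", False, decoy_type="nonperiodic")],
            features=[_Feature(s, 30, "nonperiodic")],
            abundance=1.0,
        )
    )


def _build_unexpressed_decoy(rng) -> _TxPlan:
    f1, orf, f2 = _filler(rng, 40), _orf_nt(rng, 25), _filler(rng, 160)
    s, e = 40, 40 + len(orf)
    return _validated(
        _TxPlan(
            tid="tx_unexpressed",
            gene="g_unexpressed",
            biotype="lncRNA",
            strand="+",
            spliced=f1 + orf + f2,
            cds_tx=None,
            exon_lengths=[40 + len(orf) + 160],
            planted=[_Planted(s, e, "ncORF", False, decoy_type="unexpressed")],
            features=[],
            abundance=0.0,
        )
    )


_CLASS_BUILDERS = {
    "canonical": [_build_canonical],
    "canonical_extended": [_build_extended],
    "canonical_truncated": [_build_truncated],
    "nuORF": [_build_nuorf],
    "ouORF": [_build_ouorf],
    "ndORF": [_build_ndorf],
    "odORF": [_build_odorf],
    "ncORF": [_build_nc_lnc, _build_nc_pseudo],
}


# ---------------------------------------------------------------------------
# layout / projection


def _project(positions: list[int], a: int, b: int) -> list[tuple[int, int]]:
    ps = sorted(positions[a:b])
    blocks = []
    start = prev = ps[0]
    for p in ps[1:]:
        if p != prev + 1:
            blocks.append((start, prev + 1))
            start = p
        prev = p
    blocks.append((start, prev + 1))
    return blocks


def _layout(plans: list[_TxPlan], min_chrom_len: int = 0) -> dict[str, int]:
    """Assign genomic exon coordinates; returns chromosome lengths."""
    cursors = {"chr1": 1000, "chr2": 1000}
    chrom_cycle = ["chr1", "chr2"]
    groups: list[list[_TxPlan]] = []
    seen_groups: dict[str, list[_TxPlan]] = {}
    for plan in plans:
        if plan.group is None:
            groups.append([plan])
        elif plan.group not in seen_groups:
            seen_groups[plan.group] = [plan]
            groups.append(seen_groups[plan.group])
        else:
            seen_groups[plan.group].append(plan)

    for gi, group in enumerate(groups):
        chrom = chrom_cycle[gi % 2]
        origin = cursors[chrom]
        span_end = origin
        for plan in group:
            plan.chrom = chrom
            if plan.exon_layout is not None:
                plan.exons = [(origin + off, origin + off + ln) for off, ln in plan.exon_layout]
            else:
                lengths = (
                    plan.exon_lengths
                    if plan.strand == "+"
                    else list(reversed(plan.exon_lengths))
                )
                exons = []
                cur = origin
                for ln in lengths:
                    exons.append((cur, cur + ln))
                    cur += ln + INTRON_LEN
                plan.exons = exons
            assert sum(e - s for s, e in plan.exons) == len(plan.spliced)
            span_end = max(span_end, plan.exons[-1][1])
        cursors[chrom] = span_end + SPACER
    return {
        c: max(cursors[c] + 1000, min_chrom_len)
        for c in chrom_cycle
        if cursors[c] > 1000
    }


def _fill_genome(
    plans: list[_TxPlan], chrom_lengths: dict[str, int], rng: np.random.Generator
) -> dict[str, str]:
    genome = {c: list(_rand_bases(rng, n)) for c, n in chrom_lengths.items()}
    for plan in plans:
        chunk_src = (
            plan.spliced
            if plan.strand == "+"
            else str(Seq(plan.spliced).reverse_complement())
        )
        cur = 0
        for s, e in plan.exons:
            genome[plan.chrom][s:e] = chunk_src[cur : cur + (e - s)]
            cur += e - s
    return {c: "".join(chars) for c, chars in genome.items()}


def _write_gtf(plans: list[_TxPlan], path: Path) -> None:
    with open(path, "w") as out:
        for plan in plans:
            attrs = (
                f'gene_id "{plan.gene}"; transcript_id "{plan.tid}"; '
                f'gene_biotype "{plan.biotype}"; transcript_biotype "{plan.biotype}";'
            )
            span = (plan.exons[0][0], plan.exons[-1][1])

            def line(feature, s, e):
                return (
                    f"{plan.chrom}\tfixture\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{plan.strand}\t0\t{attrs}\n"
                )

            out.write(line("transcript", span[0], span[1]))
            for s, e in plan.exons:
                out.write(line("exon", s, e))
            if plan.cds_tx is not None:
                cs, ce = plan.cds_tx
                for s, e in _project(plan.positions, cs, ce - 3):
                    out.write(line("CDS", s, e))
                for s, e in _project(plan.positions, ce - 3, ce):
                    out.write(line("stop_codon", s, e))


def _simulate_reads(
    plans: list[_TxPlan],
    rng: np.random.Generator,
    depth: float,
    fidelity: float,
    init_peak: float,
    offsets: dict[int, int],
    rna_coverage: float,
) -> tuple[list, list]:
    """Returns (rpf, rna) read tuples: (plan, tx_five_prime, length, reverse)."""
    lengths = sorted(offsets)
    rpf, rna = [], []
    for plan in plans:
        txlen = len(plan.spliced)
        for feat in plan.features:
            rate = depth * plan.abundance * feat.te_mult
            for k in range(feat.n_codons):
                lam = rate * (init_peak if (k == 0 and feat.mode == "periodic") else 1.0)
                for _ in range(rng.poisson(lam)):
                    length = lengths[rng.integers(0, len(lengths))]
                    if feat.mode == "nonperiodic":
                        shift = int(rng.integers(0, 3))
                    else:
                        shift = 0 if rng.random() < fidelity else int(rng.integers(1, 3))
                    five = feat.tx_start + 3 * k + shift - offsets[length]
                    if five < 0 or five + length > txlen:
                        continue
                    rpf.append((plan, five, length, plan.strand == "-"))
        if plan.abundance > 0:
            n_rna = rng.poisson(rna_coverage * txlen * plan.abundance / RNA_READ_LEN)
            starts = rng.integers(0, txlen - RNA_READ_LEN + 1, n_rna)
            for st in starts:
                reverse = bool(rng.random() < 0.5)
                rna.append((plan, int(st), RNA_READ_LEN, reverse))
    return rpf, rna


def _write_bam(
    reads: list,
    genome: dict[str, str],
    chrom_lengths: dict[str, int],
    path: Path,
    prefix: str,
) -> None:
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
    }
    tid_of = {c: i for i, c in enumerate(chroms)}

    records = []
    for i, (plan, five, length, reverse) in enumerate(reads):
        positions = sorted(plan.positions[five : five + length])
        blocks = _project(plan.positions, five, five + length)
        cigar = []
        for bi, (s, e) in enumerate(blocks):
            if bi:
                cigar.append((3, s - blocks[bi - 1][1]))  # N
            cigar.append((0, e - s))  # M
        seq = "".join(genome[plan.chrom][s:e] for s, e in blocks)
        records.append(
            (tid_of[plan.chrom], positions[0], tuple(cigar), seq, reverse, i)
        )
    records.sort(key=lambda r: (r[0], r[1], r[5]))

    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for tid, pos, cigar, seq, reverse, i in records:
            aln = pysam.AlignedSegment(bam.header)
            aln.query_name = f"{prefix}{i}"
            aln.query_sequence = seq
            aln.flag = 16 if reverse else 0
            aln.reference_id = tid
            aln.reference_start = pos
            aln.mapping_quality = 42
            aln.cigartuples = list(cigar)
            aln.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            bam.write(aln)
    pysam.index(str(path))


def make_world(
    out_dir: str | Path,
    seed: int = 1,
    classes: Sequence[str] = ALL_CLASSES,
    depth: float = 4.0,
    fidelity: float = 0.85,
    init_peak: float = 5.0,
    offsets: Optional[dict[int, int]] = None,
    rna_coverage: float = 10.0,
    n_silent_decoys: int = 4,
    readthrough_decoy: bool = True,
    nonperiodic_decoy: bool = True,
    unexpressed_decoy: bool = True,
    isoform_pair: bool = True,
    nested_pair: bool = True,
    min_chrom_len: int = 100_000,
) -> FixtureManifest:
    """Generate a complete synthetic test world under ``out_dir``.

    Writes genome.fa, annot.gtf, ribo.bam(+.bai), rna.bam(+.bai) and
    manifest.json; returns the loaded :class:`FixtureManifest`.  ``depth``
    is the mean number of P-site reads per codon for an abundance-1,
    TE-1 feature; ``fidelity`` is the frame-0 probability of each P-site.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    offsets = dict(offsets or DEFAULT_OFFSETS)
    rng = np.random.default_rng(seed)

    unknown = [c for c in classes if c not in ALL_CLASSES]
    if unknown:
        raise ValueError(f"unknown smORF class requested: {unknown[0]}")

    def build(builder, *args):
        # a draw can violate the first-ATG/no-internal-stop invariants
        # (e.g. an in-frame ATG upstream of a planted dORF inside the CDS);
        # validation rejects it and a fresh draw is taken
        for _ in range(100):
            try:
                return builder(rng, *args)
            except RuntimeError:
                continue
        raise RuntimeError(f"fixture builder {builder.__name__} failed to converge")

    plans: list[_TxPlan] = []
    for cls in ALL_CLASSES:  # fixed order for determinism
        if cls in classes:
            for builder in _CLASS_BUILDERS[cls]:
                plans.append(build(builder))
    if isoform_pair:
        plans.extend(build(_build_isoform_pair))
    if nested_pair:
        plans.extend(build(_build_nested_pair))
    for i in range(n_silent_decoys):
        abundance = [0.5, 1.0, 2.0, 1.0][i % 4]
        plans.append(build(_build_silent_decoy, i, abundance, "+-"[i % 2]))
    if readthrough_decoy:
        plans.append(build(_build_readthrough_decoy))
    if nonperiodic_decoy:
        plans.append(build(_build_nonperiodic_decoy))
    if unexpressed_decoy:
        plans.append(build(_build_unexpressed_decoy))

    for cls in classes:
        if not any(p.label == cls for plan in plans for p in plan.planted):
            raise ValueError(f"no fixture transcript plants class {cls}")

    chrom_lengths = _layout(plans, min_chrom_len)
    genome = _fill_genome(plans, chrom_lengths, rng)
    for plan in plans:
        pos = [p for s, e in plan.exons for p in range(s, e)]
        plan.positions = pos if plan.strand == "+" else pos[::-1]

    write_fasta(genome, out_dir / "genome.fa")
    _write_gtf(plans, out_dir / "annot.gtf")

    rpf, rna = _simulate_reads(
        plans, rng, depth, fidelity, init_peak, offsets, rna_coverage
    )
    _write_bam(rpf, genome, chrom_lengths, out_dir / "ribo.bam", "rpf")
    _write_bam(rna, genome, chrom_lengths, out_dir / "rna.bam", "rna")

    # manifest: merge planted ORFs that share genomic blocks across isoforms
    orf_entries: dict[str, dict] = {}
    for plan in plans:
        for p in plan.planted:
            blocks = _project(plan.positions, p.tx_start, p.tx_end)
            orf_id = f"{plan.chrom}:{blocks[0][0]}-{blocks[-1][1]}:{plan.strand}"
            nt = plan.spliced[p.tx_start : p.tx_end]
            key = f"{orf_id}|{p.decoy_type or ''}" if p.decoy_type in (
                "nested_duplicate",
            ) else orf_id
            entry = orf_entries.get(key)
            if entry is None:
                orf_entries[key] = {
                    "orf_id": orf_id,
                    "hosts": [plan.tid],
                    "chrom": plan.chrom,
                    "strand": plan.strand,
                    "blocks": [list(b) for b in blocks],
                    "tx_start": p.tx_start,
                    "tx_end": p.tx_end,
                    "n_codons": (p.tx_end - p.tx_start) // 3 - 1,
                    "class": p.label,
                    "translated": p.translated,
                    "expected_unique": p.expected_unique,
                    "decoy_type": p.decoy_type,
                    "te_mult": p.te_mult,
                    "peptide": str(Seq(nt[:-3]).translate()),
                }
            else:
                entry["hosts"].append(plan.tid)
                entry["expected_unique"] = entry["expected_unique"] or p.expected_unique

    orfs = sorted(orf_entries.values(), key=lambda o: o["orf_id"])
    manifest = FixtureManifest(
        {
            "seed": seed,
            "params": {
                "depth": depth,
                "fidelity": fidelity,
                "init_peak": init_peak,
                "rna_coverage": rna_coverage,
                "rna_read_len": RNA_READ_LEN,
                "offsets": {str(k): v for k, v in offsets.items()},
            },
            "chromosomes": chrom_lengths,
            "transcripts": [
                {
                    "id": plan.tid,
                    "gene": plan.gene,
                    "chrom": plan.chrom,
                    "strand": plan.strand,
                    "biotype": plan.biotype,
                    "exons": [list(e) for e in plan.exons],
                    "spliced_length": len(plan.spliced),
                    "spliced_sequence": plan.spliced,
                    "abundance": plan.abundance,
                    "cds_tx": list(plan.cds_tx) if plan.cds_tx else None,
                }
                for plan in plans
            ],
            "orfs": orfs,
            "n_unique_translated": sum(
                1 for o in orfs if o["translated"] and o["expected_unique"]
            ),
            "n_transcripts": len(plans),
        }
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
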