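"""Tests for ORFScore, coverage, RRS, FPKM and translation efficiency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smorf_caller import fpkm, orf_score, rrs, translation_efficiency
from smorf_caller.metrics import codon_coverage, downstream_region, frame_counts
from smorf_caller.orf_scanner import PutativeOrf
from smorf_caller.psite_calibration import PSiteTrack

from conftest import single_exon_tx


def _orf(tx, s, e):
    return PutativeOrf(
        transcript_id=tx.transcript_id,
        chrom=tx.chrom,
        strand=tx.strand,
        tx_start=s,
        tx_end=e,
        genomic_blocks=tuple(tx.to_genomic_blocks((s, e))),
    )


def _track(pairs, chrom="chrT", strand="+"):
    t = PSiteTrack()
    for pos, n in pairs:
        for _ in range(n):
            t.add(chrom, strand, pos)
    return t


class TestOrfScore:
    def test_single_frame_closed_form(self):
        assert orf_score((30, 0, 0)) == pytest.approx(math.log2(61))

    def test_uniform_counts_give_zero(self):
        assert orf_score((10, 10, 10)) == 0.0
        assert orf_score((0, 0, 0)) == 0.0

    def test_wrong_frame_negation(self):
        assert orf_score((0, 30, 0)) == pytest.approx(-math.log2(61))
        assert orf_score((0, 0, 30)) == pytest.approx(-math.log2(61))

    def test_closed_form_family(self):
        for n in range(1, 101):
            assert orf_score((n, 0, 0)) == pytest.approx(math.log2(1 + 2 * n))

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            orf_score((-1, 0, 0))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
        st.integers(2, 5),
    )
    def test_frame23_symmetry_and_scaling(self, f1, f2, f3, k):
        assert orf_score((f1, f2, f3)) == pytest.approx(orf_score((f1, f3, f2)))
        base = orf_score((f1, f2, f3))
        scaled = orf_score((k * f1, k * f2, k * f3))
        if base != 0:
            assert abs(scaled) > abs(base)
            assert math.copysign(1, scaled) == math.copysign(1, base)


class TestCoverageAndFrameCounts:
    def test_half_covered_interior(self):
        tx = single_exon_tx(60, biotype="lncRNA")
        orf = _orf(tx, 0, 33)  # 10 sense codons, 8 interior
        hits = [(3 * c, 1) for c in (1, 2, 5, 6)]
        track = _track(hits)
        assert codon_coverage(orf, track) == pytest.approx(4 / 8)

    def test_empty_track_gives_zero(self):
        tx = single_exon_tx(60, biotype="lncRNA")
        assert codon_coverage(_orf(tx, 0, 33), PSiteTrack()) == 0.0

    def test_frame_counts_exclude_terminal_codons(self):
        tx = single_exon_tx(60, biotype="lncRNA")
        orf = _orf(tx, 0, 33)
        track = _track([(0, 100), (3, 2), (4, 1), (24, 3), (27, 50)])
        f1, f2, f3 = frame_counts(orf, track)
        # codon 0 (pos 0) and the last sense codon (pos 27) are excluded
        assert (f1, f2, f3) == (5.0, 1.0, 0.0)

    def test_capping_tempers_single_codon_spikes(self):
        tx = single_exon_tx(600, biotype="lncRNA")
        orf = _orf(tx, 0, 300)
        track = _track([(3 * c, 1) for c in range(1, 99)] + [(150, 1000)])
        f1, _, _ = frame_counts(orf, track)
        assert f1 < 200  # the 1000-count spike is capped

    def test_fixture_coverage_matches_poisson_expectation(self, world, pipeline_run):
        """Planted ORF coverage approximates 1 - exp(-lambda) for the
        generator's per-codon frame-0 P-site rate."""
        manifest = world["manifest"]
        params = manifest.params
        tx_abund = {t["id"]: t["abundance"] for t in manifest.transcripts}
        records = {r.orf.orf_id: r for r in pipeline_run["records"]}
        for orf in manifest.orfs:
            if not (orf["translated"] and orf["expected_unique"]):
                continue
            rec = records[orf["orf_id"]]
            lam = (
                params["depth"]
                * orf["te_mult"]
                * max(tx_abund[h] for h in orf["hosts"])
                * params["fidelity"]
            )
            expected = 1 - math.exp(-lam)
            assert rec.metrics.coverage == pytest.approx(expected, abs=0.1)


class TestRrs:
    class _StubRna:
        """Duck-typed RNA counter returning region length-proportional counts."""

        def __init__(self, per_nt=0.0):
            self.per_nt = per_nt

        def count(self, chrom, blocks):
            return int(round(sum(e - s for s, e in blocks) * self.per_nt))

    def test_uniform_signal_gives_one(self):
        tx = single_exon_tx(600, biotype="lncRNA")
        orf = _orf(tx, 150, 300)
        track = _track([(p, 1) for p in range(150, 450)])  # ORF + downstream
        value = rrs(orf, track, self._StubRna(1.0), tx)
        assert value == pytest.approx(1.0, rel=0.05)

    def test_release_at_stop_gives_high_score(self):
        tx = single_exon_tx(600, biotype="lncRNA")
        orf = _orf(tx, 150, 300)
        track = _track([(p, 1) for p in range(150, 300)])  # ORF only
        value = rrs(orf, track, self._StubRna(1.0), tx)
        assert value > 50

    def test_zero_downstream_signal_is_finite(self):
        tx = single_exon_tx(600, biotype="lncRNA")
        orf = _orf(tx, 150, 300)
        track = _track([(p, 2) for p in range(150, 300)])
        value = rrs(orf, track, self._StubRna(0.0), tx)
        assert value is not None and math.isfinite(value)

    def test_uorf_region_truncated_at_cds_start(self):
        tx = single_exon_tx(600, cds=(300, 450))
        uorf = _orf(tx, 30, 90)
        assert downstream_region(uorf, tx) == (90, 240)
        overlapping = _orf(tx, 270, 330)  # stop inside the CDS
        assert downstream_region(overlapping, tx) is None

    def test_canonical_region_is_three_prime_window(self):
        tx = single_exon_tx(600, cds=(300, 450))
        canonical = _orf(tx, 300, 450)
        assert downstream_region(canonical, tx) == (450, 600)


class TestExpressionMetrics:
    def test_fpkm_examples(self):
        assert fpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert fpkm(0, 1000, 10**6) == 0.0
        with pytest.raises(ValueError):
            fpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            fpkm(1, 100, 0)

    def test_te_examples(self):
        assert translation_efficiency(10, 5) == pytest.approx(2.0)
        assert translation_efficiency(0, 5) == 0.0
        assert translation_efficiency(3, 0) is None

    def test_fixture_fpkm_tracks_abundance(self, world):
        """RNA FPKM of the abundance-ladder transcripts (0.5x, 1x, 2x) is
        rank-ordered with the planted abundances."""
        from scipy.stats import spearmanr

        from smorf_caller.psite_calibration import ReadCounter

        manifest = world["manifest"]
        ladder = [
            t
            for t in manifest.transcripts
            if t["id"] in ("tx_silent0", "tx_silent1", "tx_silent2")
        ]
        rc = ReadCounter(world["rna"])
        fpkms, abunds = [], []
        for t in ladder:
            count = rc.count(t["chrom"], [tuple(e) for e in t["exons"]])
            fpkms.append(fpkm(count, t["spliced_length"], rc.library_size))
            abunds.append(t["abundance"])
        rc.close()
        rho = spearmanr(fpkms, abunds).statistic
        assert rho == pytest.approx(1.0)

    def test_fixture_te_multipliers_rank_recovered(self, world, pipeline_run):
        """Planted TE multipliers {0.5, 1, 2} come out in the right order."""
        manifest = world["manifest"]
        records = {r.orf.orf_id: r for r in pipeline_run["records"]}
        ladder = {
            orf["te_mult"]: records[orf["orf_id"]].metrics.te
            for orf in manifest.orfs
            if orf["translated"]
            and orf["expected_unique"]
            and orf["hosts"][0] in ("tx_ndorf", "tx_nclnc", "tx_nuorf")
            and orf["class"] in ("ndORF", "ncORF", "nuORF")
        }
        assert set(ladder) == {0.5, 1.0, 2.0}
        assert ladder[0.5] < ladder[1.0] < ladder[2.0]
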