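"""Tests for positional classification and unique-set collapsing."""

import numpy as np
import pytest

from smorf_caller import OrfClass, classify, collapse_unique
from smorf_caller.orf_classifier import ClassifiedOrf
from smorf_caller.orf_scanner import PutativeOrf

from conftest import single_exon_tx
from oracles import classify_oracle

TX_LEN = 500
CDS = (50, 350)


def _orf(s, e, tx, tid=None):
    return PutativeOrf(
        transcript_id=tid or tx.transcript_id,
        chrom=tx.chrom,
        strand=tx.strand,
        tx_start=s,
        tx_end=e,
        genomic_blocks=tuple(tx.to_genomic_blocks((s, e))),
    )


class TestClassify:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((50, 350), OrfClass.CANONICAL),
            ((20, 350), OrfClass.CANONICAL_EXTENDED),
            ((80, 350), OrfClass.CANONICAL_TRUNCATED),
            ((5, 35), OrfClass.NUORF),
            ((5, 65), OrfClass.OUORF),
            ((360, 420), OrfClass.NDORF),
            ((340, 420), OrfClass.ODORF),
            ((100, 160), OrfClass.INTERNAL),
        ],
    )
    def test_coding_transcript_cases(self, interval, expected):
        tx = single_exon_tx(TX_LEN, cds=CDS)
        assert classify(_orf(*interval, tx), tx) is expected

    def test_noncoding_transcript_gives_ncorf(self):
        tx = single_exon_tx(TX_LEN, biotype="lncRNA")
        assert classify(_orf(10, 40, tx), tx) is OrfClass.NCORF

    def test_minus_strand_uses_transcript_coordinates(self):
        tx = single_exon_tx(TX_LEN, strand="-", cds=CDS)
        assert classify(_orf(5, 35, tx), tx) is OrfClass.NUORF
        assert classify(_orf(50, 350, tx), tx) is OrfClass.CANONICAL

    def test_cds_with_noncoding_biotype_classified_by_cds(self, caplog):
        tx = single_exon_tx(TX_LEN, cds=CDS, biotype="lncRNA")
        with caplog.at_level("WARNING"):
            assert classify(_orf(50, 350, tx), tx) is OrfClass.CANONICAL
        assert "non-coding biotype" in caplog.text

    def test_matches_case_analysis_oracle(self):
        """Sliding a 30-nt ORF and random (ORF, CDS) placements against the
        independent explicit case analysis."""
        rng = np.random.default_rng(0)
        tx = single_exon_tx(TX_LEN, cds=CDS)
        checked = 0
        for s in range(0, TX_LEN - 30, 1):  # exhaustive slide of a 30-nt ORF
            got = classify(_orf(s, s + 30, tx), tx)
            assert got.value == classify_oracle(s, s + 30, CDS)
            checked += 1
        for _ in range(1000):  # random ORF/CDS geometries
            cs = int(rng.integers(30, 300))
            ce = cs + 3 * int(rng.integers(5, 60))
            length = 3 * int(rng.integers(2, 80))
            s = int(rng.integers(0, TX_LEN - length))
            e = s + length
            tx_r = single_exon_tx(TX_LEN, cds=(cs, ce))
            assert classify(_orf(s, e, tx_r), tx_r).value == classify_oracle(s, e, (cs, ce))
            checked += 1
        assert checked >= 1000


class TestCollapseUnique:
    def _rec(self, tx, s, e, cls, tid=None):
        tid = tid or tx.transcript_id
        return ClassifiedOrf(
            orf=_orf(s, e, tx, tid=tid),
            orf_class=cls,
            host_transcripts=[tid],
            gene_ids=[f"g_{tid}"],
            peptide="M" * ((e - s) // 3 - 1),
        )

    def test_isoform_duplicates_merge_hosts(self):
        tx = single_exon_tx(TX_LEN, biotype="lncRNA")
        a = self._rec(tx, 10, 40, OrfClass.NUORF, tid="iso1")
        b = self._rec(tx, 10, 40, OrfClass.NUORF, tid="iso2")
        out = collapse_unique([a, b])
        assert len(out) == 1
        assert out[0].host_transcripts == ["iso1", "iso2"]

    def test_class_precedence_on_merge(self):
        tx = single_exon_tx(TX_LEN)
        a = self._rec(tx, 10, 40, OrfClass.NUORF, tid="iso1")
        b = self._rec(tx, 10, 40, OrfClass.CANONICAL, tid="iso2")
        assert collapse_unique([a, b])[0].orf_class is OrfClass.CANONICAL

    def test_nested_same_frame_removed(self):
        tx = single_exon_tx(TX_LEN, biotype="lncRNA")
        outer = self._rec(tx, 10, 70, OrfClass.NCORF, tid="A")
        inner = self._rec(tx, 22, 70, OrfClass.NCORF, tid="B")  # same frame suffix
        out = collapse_unique([outer, inner])
        assert [r.orf.tx_start for r in out] == [10]

    def test_nested_different_frame_kept(self):
        tx = single_exon_tx(TX_LEN, biotype="lncRNA")
        outer = self._rec(tx, 10, 70, OrfClass.NCORF, tid="A")
        inner = self._rec(tx, 23, 59, OrfClass.NCORF, tid="B")  # +1 frame
        assert len(collapse_unique([outer, inner])) == 2

    def test_order_independence(self):
        tx = single_exon_tx(TX_LEN)
        recs = [
            self._rec(tx, 10, 40, OrfClass.NUORF, tid="i1"),
            self._rec(tx, 10, 40, OrfClass.OUORF, tid="i2"),
            self._rec(tx, 100, 160, OrfClass.NCORF, tid="i3"),
            self._rec(tx, 112, 160, OrfClass.NCORF, tid="i4"),
        ]
        import itertools

        def key(out):
            return [
                (r.orf.block_key, r.orf_class, tuple(r.host_transcripts))
                for r in out
            ]

        baseline = key(collapse_unique(recs))
        for perm in itertools.permutations(recs):
            assert key(collapse_unique(list(perm))) == baseline

    def test_fixture_isoform_and_nested_counts(self, pipeline_run, world):
        manifest = world["manifest"]
        records = pipeline_run["records"]
        ids = {r.orf.orf_id for r in records}
        # isoform-shared ORF appears once, with both hosts
        shared = [o for o in manifest.orfs if len(o["hosts"]) > 1][0]
        rec = next(r for r in records if r.orf.orf_id == shared["orf_id"])
        assert rec.host_transcripts == sorted(shared["hosts"])
        # nested duplicate is absent, its containing ORF present
        nested = [o for o in manifest.orfs if o["decoy_type"] == "nested_duplicate"][0]
        assert nested["orf_id"] not in ids

    def test_no_internal_records_emitted(self, pipeline_run):
        assert all(
            r.orf_class is not OrfClass.INTERNAL for r in pipeline_run["records"]
        )
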