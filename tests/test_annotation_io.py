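"""Tests for GTF/FASTA reading, transcript coordinate maps and BED12+ output."""

import textwrap

import pytest

from smorf_caller import (
    GenomeSequence,
    read_bed12_plus,
    read_gtf,
    spliced_sequence,
    write_bed12_plus,
)
from smorf_caller.annotation_io import TranscriptModel

from conftest import single_exon_tx


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


GTF_BASIC = """\
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\tCDS\t121\t200\t.\t+\t0\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\tCDS\t301\t337\t.\t+\t0\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\tstop_codon\t338\t340\t.\t+\t0\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\texon\t501\t600\t.\t-\t.\tgene_id "g2"; transcript_id "t2"; gene_biotype "lncRNA";
"""


class TestReadGtf:
    def test_coordinates_become_zero_based_half_open(self, tmp_path):
        txs = read_gtf(_write(tmp_path, "a.gtf", GTF_BASIC))
        t1 = next(t for t in txs if t.transcript_id == "t1")
        assert t1.exons == [(100, 200), (300, 400)]
        assert t1.strand == "+"
        assert t1.biotype == "protein_coding"

    def test_stop_codon_merged_into_cds_and_length_multiple_of_three(self, tmp_path):
        txs = read_gtf(_write(tmp_path, "a.gtf", GTF_BASIC))
        t1 = next(t for t in txs if t.transcript_id == "t1")
        assert t1.cds == [(120, 200), (300, 340)]
        assert sum(e - s for s, e in t1.cds) % 3 == 0
        assert t1.cds_transcript_interval() == (20, 140)

    def test_biotype_fallback_and_filtering(self, tmp_path):
        path = _write(tmp_path, "a.gtf", GTF_BASIC)
        assert {t.biotype for t in read_gtf(path)} == {"protein_coding", "lncRNA"}
        only = read_gtf(path, biotypes={"lncRNA"})
        assert [t.transcript_id for t in only] == ["t2"]

    def test_key_equals_value_dialect(self, tmp_path):
        gtf = 'chr1\ts\texon\t1\t30\t.\t+\t.\tgene_id=gX; transcript_id=tX; transcript_biotype=lncRNA\n'
        txs = read_gtf(_write(tmp_path, "b.gtf", gtf))
        assert txs[0].transcript_id == "tX"
        assert txs[0].biotype == "lncRNA"

    def test_unknown_strand_skipped_and_exonless_dropped(self, tmp_path, caplog):
        gtf = (
            'chr1\ts\texon\t1\t30\t.\t?\t.\tgene_id "g"; transcript_id "tbad";\n'
            'chr1\ts\ttranscript\t1\t30\t.\t+\t.\tgene_id "g"; transcript_id "tnoexon";\n'
        )
        with caplog.at_level("WARNING"):
            txs = read_gtf(_write(tmp_path, "c.gtf", gtf))
        assert txs == []

    def test_unparseable_line_names_line_number(self, tmp_path):
        gtf = 'chr1\ts\texon\tnotanumber\t30\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        with pytest.raises(ValueError, match="line 1"):
            read_gtf(_write(tmp_path, "d.gtf", gtf))


class TestSplicedSequence:
    def test_plus_strand_concatenation(self):
        genome = GenomeSequence(chrT="ATGTAA")
        tx = single_exon_tx(6)
        assert spliced_sequence(tx, genome) == "ATGTAA"

    def test_minus_strand_reverse_complement(self):
        genome = GenomeSequence(chrT="ATGTAA")
        tx = single_exon_tx(6, strand="-")
        assert spliced_sequence(tx, genome) == "TTACAT"

    def test_out_of_bounds_exon_raises(self):
        genome = GenomeSequence(chrT="ATG")
        with pytest.raises(ValueError):
            spliced_sequence(single_exon_tx(10), genome)

    def test_fixture_transcripts_match_manifest(self, world):
        """Spliced sequences (incl. multi-exon minus strand) equal the
        generator's independently stored sequences."""
        genome = GenomeSequence.from_fasta(world["genome"])
        txs = {t.transcript_id: t for t in read_gtf(world["gtf"])}
        manifest = world["manifest"]
        assert len(txs) == manifest.data["n_transcripts"]
        for t in manifest.transcripts:
            tx = txs[t["id"]]
            assert tx.biotype == t["biotype"]
            assert [list(e) for e in tx.exons] == t["exons"]
            seq = spliced_sequence(tx, genome)
            assert len(seq) == tx.spliced_length == t["spliced_length"]
            assert seq == t["spliced_sequence"]


class TestBed12Plus:
    def _records(self, pipeline_run):
        return pipeline_run["records"]

    def test_block_encoding_round_trip(self, pipeline_run, tmp_path):
        records = self._records(pipeline_run)
        path = tmp_path / "out.bed"
        write_bed12_plus(records, path)
        rows = read_bed12_plus(path)
        assert len(rows) == len(records)
        by_name = {r["name"]: r for r in rows}
        for rec in records:
            row = by_name[rec.orf.orf_id]
            assert row["blocks"] == list(rec.orf.genomic_blocks)
            assert row["strand"] == rec.orf.strand
            assert row["orf_class"] == rec.orf_class.value
            assert row["peptide"] == rec.peptide

    def test_single_and_multi_exon_block_fields(self, pipeline_run, tmp_path):
        records = self._records(pipeline_run)
        path = tmp_path / "out.bed"
        write_bed12_plus(records, path)
        lines = [l.split("\t") for l in path.read_text().splitlines() if not l.startswith("#")]
        for fields in lines:
            assert len(fields) == 25
            sizes = [int(x) for x in fields[10].split(",")]
            offsets = [int(x) for x in fields[11].split(",")]
            assert len(sizes) == len(offsets) == int(fields[9])
            assert offsets[0] == 0
            assert int(fields[1]) + offsets[-1] + sizes[-1] == int(fields[2])

    def test_peptide_column_retranslates_from_genome(self, pipeline_run, world):
        """The written peptide, re-derived from the genome through the ORF's
        blocks, translates back to itself (writer/scanner agreement)."""
        from Bio.Seq import Seq

        genome = GenomeSequence.from_fasta(world["genome"])
        for rec in self._records(pipeline_run):
            orf = rec.orf
            nt = "".join(genome.fetch(orf.chrom, s, e) for s, e in orf.genomic_blocks)
            if orf.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            assert str(Seq(nt[:-3]).translate()) == rec.peptide
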