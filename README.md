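# smorf-caller

Stringent discovery and classification of actively translated **small open
reading frames (smORFs, ≤ 100 codons)** from ribosome profiling (Ribo-Seq)
and RNA-Seq data.

smORFs — and the micropeptides they encode — are systematically
under-annotated because the genome contains enormous numbers of short
ATG…stop intervals, most of which are never translated. Ribosome profiling
resolves this: an elongating ribosome protects a ~28–30 nt mRNA footprint
(RPF) whose inferred P-site advances in exact 3-nt steps along the reading
frame of a translated ORF, and ribosomes are released at the stop codon.
`smorf-caller` turns these two signatures, plus expression support from
matched RNA-Seq, into a filtered catalogue of translated smORFs for any
genome with a transcript annotation. It is intended for bench and
computational groups mining their own Ribo-Seq libraries for micropeptide
candidates (uORF regulators, lncRNA-encoded peptides, short secreted
proteins).

## Method

The pipeline has three stages:

1. **Putative smORF prediction.** Every annotated transcript's spliced
   sequence is scanned in three frames. A putative ORF runs from the first
   AUG after the previous in-frame stop to the next in-frame stop (one ORF
   per (frame, stop); nested same-stop AUGs are kept only as alternative
   starts). ORFs of 5–100 sense codons are retained and classified by
   position relative to the annotated CDS: `canonical`,
   `canonical_extended`, `canonical_truncated` (shared stop codon),
   `nuORF`/`ouORF` (upstream, non-overlapping/overlapping),
   `ndORF`/`odORF` (downstream), and `ncORF` (on non-coding RNA).

2. **P-site calibration.** Per-read-length 5′-end offsets are estimated from
   a metagene of read 5′ ends around annotated start codons; read lengths
   whose offset leaves < 50 % of P-sites in frame 0 are rejected. Accepted
   reads become a strand-aware single-nucleotide P-site track.

3. **Translation evidence and filtering.** For each ORF with frame-0,
   frame-1, frame-2 P-site totals F₁, F₂, F₃ (interior codons, counts capped
   at the 97.5th percentile):

   - **ORFScore** = log₂(1 + Σᵢ (Fᵢ − F̄)² / F̄), negated when frame 1 is
     not maximal — the 3-nt periodicity bias;
   - **RRS** (ribosome release score) =
     (RPF_ORF/RPF_downstream) ÷ (RNA_ORF/RNA_downstream), densities with
     pseudocount 1 — translation termination at the stop codon;
   - **coverage** — fraction of interior codons with ≥ 1 frame-0 P-site;
   - **FPKM** (RPF and RNA) and **TE** = FPKM_RPF / FPKM_RNA.

   ORFs pass an AND-cascade (host RNA FPKM ≥ 1, coverage ≥ 0.5,
   ORFScore ≥ 6, RRS ≥ 5; all configurable), isoform duplicates are merged
   and nested same-frame ORFs removed, and the unique set is written as a
   genome-browser-ready BED12+ table whose final column is the peptide.

## Worked example

The package ships a synthetic-world generator that plants smORFs of every
class with known translation status — useful both for testing and for
getting a feel for the outputs:

```bash
smorf-caller fixtures --seed 1 --out demo
smorf-caller run --genome demo/genome.fa --gtf demo/annot.gtf \
                 --ribo demo/ribo.bam --rna demo/rna.bam --out demo/out
```

prints

```
world with 20 transcripts and 23 planted ORFs written to demo
11 unique smORFs written to demo/out
```

The run recovers exactly the 11 planted translated smORFs: the 12 decoy
ORFs (no RPF signal, non-periodic signal, stop-codon read-through, or
unexpressed host) are each removed by the gate designed for them, the
isoform-shared ORF is reported once with both hosts, and the nested
same-frame duplicate is collapsed. `demo/out/offsets.tsv` shows the
calibration recovering the simulated footprint geometry:

```
read_length  p_site_offset  n_reads  frame0_fraction
28           12             389      0.7352
30           13             399      0.8195
```

and `demo/out/metrics.tsv` holds the per-ORF evidence, e.g. the planted
canonical smORF:

```
orf_id            orf_class  length_codons  orf_score  coverage  rrs
chr1:1070-1403:+  canonical  60             9.14       1.00      306
```

`demo/out/smorfs.bed` is the BED12+ table (class, hosts, metrics, peptide in
columns 13–25), `class_composition.tsv` the per-class breakdown, and
`run_report.json` records every effective parameter and per-stage ORF
counts (here 42 scanned → 1 failed expression, 25 coverage, 2 ORFScore,
1 RRS → 13 passed → 11 after collapsing).

The same functionality is available as a library:

```python
from smorf_caller import make_world, run_pipeline

manifest = make_world("demo", seed=1)
records, report = run_pipeline("demo/genome.fa", "demo/annot.gtf",
                               "demo/ribo.bam", "demo/rna.bam", out_dir="demo/out")
```

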