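# Methods

This note documents the models and procedures implemented in
`smorf-caller`, the parameters that matter, the design decisions taken
where several reasonable choices existed, and what the synthetic test
world does and does not demonstrate.

## Coordinate conventions

All internal genomic coordinates are 0-based half-open; transcript
coordinates are 0-based offsets into the spliced 5′→3′ sequence. GTF
(1-based closed) is converted on read, BED on write. `stop_codon` GTF
features are merged into the stored CDS interval, so the CDS used
throughout spans start codon through stop codon inclusive. This makes a
scanned ORF that coincides with the annotation occupy *exactly* the CDS
interval, which the classifier relies on; GTFs that annotate no
`stop_codon` feature will classify exact matches as `odORF`-adjacent
rather than `canonical` (a known limitation).

## ORF scanning

A putative ORF is **maximal**: first permitted start codon after the
previous in-frame stop, through the next in-frame stop. Consequences:

- one ORF per (frame, stop) pair — in-frame downstream AUGs are recorded
  as alternative starts, never emitted as separate ORFs, so the caller
  does not produce same-stop redundancy;
- an ORF whose maximal form exceeds `max_codons` is not emitted at all,
  even if a downstream AUG would give a sub-100-codon truncation. This is
  deliberate: in-frame truncations of a long translated CDS would
  otherwise inherit the CDS's periodic signal and flood the output.

Defaults: `min_codons = 5` (shorter ORFs cannot support frame statistics),
`max_codons = 100` sense codons (stop excluded), start-codon set `{ATG}`
(configurable; near-cognate starts may be added, at a large cost in
candidate count). Transcripts with > 10 % ambiguous bases are skipped.
Annotated CDSs that start at a non-AUG codon are handled naturally: the
scanner starts at the first in-frame AUG and the classifier reports
`canonical_truncated` via the shared stop.

## Positional classification

Decided purely in transcript coordinates against the stop-inclusive CDS
`[cs, ce)`, which makes the scheme strand-agnostic after splicing. For an
ORF `[s, e)`: same stop (`e == ce`) → canonical / canonical_extended /
canonical_truncated by start position; `e <= cs` → nuORF; `s < cs < e`
(different stop) → ouORF; `s >= ce` → ndORF; start inside the CDS with
`e > ce` → odORF; fully inside the CDS with a different stop → sentinel
`internal`, discarded and never emitted. Transcripts without a CDS host
`ncORF`s. A transcript carrying a CDS but a non-coding biotype is
classified by CDS presence, with a warning.

**Collapsing.** Records with identical genomic blocks (isoforms) merge
into one record listing all hosts; the retained label follows the
precedence canonical > canonical_extended > canonical_truncated > ouORF >
nuORF > odORF > ndORF > ncORF, chosen so that annotation-anchored labels
win over incidental ones. An ORF whose blocks are a strict same-frame
contiguous subset of another retained ORF's blocks (a 5′-truncated
isoform's view of the same stop) is removed. Both operations are
order-independent.

## P-site calibration

Reads are assigned a P-site at a fixed per-read-length offset from the 5′
end — the dominant Ribo-Seq convention. Offsets are estimated per length
from the histogram of read 5′ ends relative to annotated start codons
(window −40…+20 nt, transcript coordinates, all coding transcripts
pooled): initiating ribosomes dwell on the start codon, so the upstream
peak of that histogram sits exactly one offset before the start, and
`offset = −argmax` over upstream positions (ties broken toward the start
codon). A length is rejected when it has < 100 usable reads or when,
after offsetting, < 50 % of its window P-sites fall in frame 0. Accepted
lengths default to the 25–34 nt footprint range; uniqueness of mapping is
enforced by a MAPQ ≥ 10 threshold (aligner-agnostic, rather than NH
tags). Offsets are applied along aligned reference positions, so
junction-spanning (N-CIGAR) reads land on the correct exonic base. RNA
reads are never offset; they are counted by alignment overlap,
strand-blind (unstranded library convention), for FPKM only.

## Translation-evidence metrics

**ORFScore.** Frame totals (F₁, F₂, F₃) are accumulated over the ORF's
sense codons excluding the first and last codon (initiation and
termination peaks distort the frame distribution). Per-codon totals are
capped at the 97.5th percentile of codon totals within the ORF — a codon
whose total exceeds the cap has its three frame counts scaled down
proportionally — so a single pile-up cannot dominate. Then

    ORFScore = log2(1 + Σ (Fi − F̄)² / F̄),  F̄ = (F₁+F₂+F₃)/3,

negated when F₂ > F₁ or F₃ > F₁; all-zero counts give 0. Closed form for
pure frame-0 signal: ORFScore((n,0,0)) = log₂(1 + 2n).

**Coverage** is the fraction of interior codons with ≥ 1 frame-0 P-site.

**RRS.** With densities d = (count + 1)/length (pseudocount keeps the
score finite on sparse data),

    RRS = (d_RPF,ORF / d_RPF,down) ÷ (d_RNA,ORF / d_RNA,down).

The downstream region runs from the ORF stop to
min(stop + 150 nt, transcript end). For ORFs lying upstream of an
annotated CDS with a different stop, it is truncated at the CDS start —
the main ORF is itself translated and would mask release. For uORFs that
overlap the CDS start (ouORF) this leaves no downstream region at all, so
their RRS is reported missing and the RRS gate is skipped for them; every
other gate still applies. This adaptation of the release score to smORFs
is the main place where the package had to make an inventive choice, and
it is recorded in the run report.

**FPKM** = count × 10⁹ / (length × library size), with library size the
number of accepted primary alignments of the respective BAM (P-site count
for RPF, overlap count for RNA). **TE** = FPKM_RPF / FPKM_RNA, undefined
when the RNA FPKM is zero.

## Filter cascade

Gates are applied per ORF, in order: host-transcript RNA FPKM ≥ 1
(expression), coverage ≥ 0.5, ORFScore ≥ 6, RRS ≥ 5 (skipped when
missing); then classification (internal ORFs discarded) and collapsing.
The threshold values are package defaults exposed in the configuration —
they are conservative settings in line with the published uses of these
metrics, not values with a privileged derivation — and every effective
value is echoed in the run report together with per-stage input/output
counts (the counts telescope: scanned = Σ failed + passed). An empty or
uncalibratable RPF library degrades gracefully: the P-site track is empty
and every ORF fails the coverage gate.

## Synthetic world generator

`make_world` builds a fully specified test universe: two chromosomes
(~100 kb, random background), ~20 transcripts covering every positional
class, multi-exon and minus-strand cases, an isoform pair sharing one ORF,
a 5′-truncated isoform producing a nested same-frame duplicate, and decoy
ORFs that are silent, non-periodic, stop-codon read-through, or on an
unexpressed host. Overlap classes (ouORF/odORF) are carved into real
translated 130-codon CDSs by constrained rejection sampling; every planted
ORF is verified against the first-AUG / stop / no-internal-stop
invariants, so the manifest is an exact oracle for what the scanner must
emit. Untranslated-region filler is generated ATG-free so the planted
starts are the scanner's choices by construction.

Reads are emitted pre-aligned (sorted, indexed BAM with correct FLAG/CIGAR
including junction N operations), removing any aligner dependency.
Defaults, which constitute the simulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `depth` | 4.0 | mean P-site reads per codon (abundance 1, TE 1) |
| `fidelity` | 0.85 | probability a P-site falls in frame 0 |
| `init_peak` | 5.0 | fold accumulation of initiating ribosomes on codon 0 |
| `offsets` | 28→12, 30→13 | read lengths and planted 5′ offsets |
| `rna_coverage` | 10.0 | mean RNA-Seq per-base coverage (abundance 1) |

`depth = 4` corresponds to a well-covered library for a highly expressed
gene; `fidelity = 0.85` is typical of good CHX-arrested data. The
initiation peak is what renders the metagene argmax identifiable —
without it all in-frame upstream bins have equal expectation. The RNA
coverage default was chosen so that ORF-level FPKM and TE estimates have
meaningful precision (tens of reads per smORF); shallower settings make
TE rank recovery noisy. Transcript abundances (0.5–2×) and TE multipliers
(0.5/1/2) are planted so expression-proportionality and TE ordering are
testable. The stop-codon read-through decoy is fully periodic by design —
it exists to probe the RRS gate specifically and is therefore excluded
from ORFScore-discrimination comparisons.

**What the generator does not emulate:** sequencing errors, rRNA and
multimapping contamination, UMI duplicates, nucleotide-specific ligation
bias, overlapping genes, alternative TIS usage heterogeneity, and the
long-tailed expression distributions of real libraries. Passing tests on
this world therefore demonstrate the correctness of the algorithms and
their statistical behaviour under clean, known conditions — not the
false-discovery rate that would be observed on real lymphocyte data.

## Numerical and degenerate-input choices

- Metagene argmax ties break toward the position nearest the start codon.
- ORF metrics require ≥ 3 sense codons (guaranteed by `min_codons = 5`).
- The 97.5th-percentile cap uses linear interpolation (`numpy.percentile`).
- FPKM with an empty library raises; the pipeline guards the RPF library
  size with max(n, 1) when the track is legitimately empty.
- Transcripts on contigs missing from the FASTA are dropped with a
  warning; GTF transcripts without exon records likewise.
- Output ordering is fully deterministic (sorted by genomic coordinate),
  so identical inputs give byte-identical BED output.

## Known limitations

- Scans annotated transcripts only; no de-novo transcript assembly.
- Standard genetic code only; no readthrough or frameshift ORFs.
- Canonical classification requires stop-inclusive CDS intervals (see
  above).
- Conservation scores (e.g. PhyloCSF) are pass-through annotations
  supplied by the user, not computed.
- The RRS adaptation for ouORFs (gate skipped) means a CDS-start-
  overlapping uORF is supported by periodicity and coverage evidence only.
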