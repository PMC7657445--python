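# Methods

This note documents the models, parameter choices and numerical conventions
behind `stress5p`, and what the synthetic-data experiments do and do not
demonstrate.

## The binding model

Each transcript carries two occupancy components for a scanning initiation
factor:

- a **5′ component** confined to the 5′UTR plus the first 150 nt of coding
  sequence (the region covered during 43S recruitment and scanning); and
- a **pervasive component** spread uniformly along the whole transcript
  body (the Ded1-like pattern).

With per-transcript weights `(fw, pw)`, per-condition retentions
`(fr, pr) ∈ [0, 1]²` and per-condition relative abundance `a`, the expected
probability that a sequenced crosslink originates from transcript *t* is

    p_t(c) ∝ a_t(c) · (fw_t · fr(c) + pw_t · pr(c)),

renormalized over all transcripts. Defaults: eIF4B-like transcripts put 90%
of their occupancy in the 5′ component (`fivep_share = 0.9`); Ded1-like
(pervasive) transcripts put 20% there (`pervasive_fivep_share = 0.2`,
keeping pervasive ≥ 5′ weight as the class definition requires). The true
in-vivo shares are not measurable from the data this package models, so
these are free parameters of the generator, not estimates.

Stress kinetics defaults: glucose withdrawal sets `fr = 0.1` from the 30 s
time point onward with `pr = 1` (5′ binding ablated almost immediately,
body binding retained); heat shock at 16 min sets `fr = 0.2, pr = 0.5`
(progressive, more general loss). Cycloheximide co-treatment keeps the
mRNA-decay multipliers at 1 but does not restore 5′ binding — initiation
shutdown is upstream of decay in this model.

rRNA-like background loci are **stress-insensitive** (effective retentions
1): over these time scales ribosomes neither disassemble nor lose their
rRNA contacts. Real CRAC libraries for initiation factors are dominated by
such rRNA background, and this stability is what makes the background
usable as an internal normalization standard (below).

mRNA decay is modeled as per-regulon abundance multipliers. Defaults:
ribosomal-protein (RP) and ribosome-biogenesis (RiBi) regulons ×1/2.5 under
glucose withdrawal and ×1/16 under heat shock, other mRNAs ×0.9; all
multipliers 1 for control, mock and cycloheximide conditions.

## The synthetic-data generators

`build_toy_genome` lays out single-exon transcripts (contiguous 5′UTR /
CDS / 3′UTR; CDS a multiple of 3, ≥ 300 nt by default) with random spacers
on one chromosome per species; spike-in transcripts never share a
chromosome with study transcripts, mirroring alignment to a concatenated
two-species genome. Splicing is deliberately out of model: the analysis
this package implements maps reads to an intron-removed genome, so a
single-exon transcript model is exact, not an approximation. 10% of study
mRNAs are labeled RP and 15% RiBi by default.

`simulate_crac_reads` emits error-free, strand-matched reads of the form
`[3-nt UMI][sample barcode][genomic insert][adapter TGGAATTCTCGGGTGCCAAGGC]
[random filler]`, truncated to the read length (default 75 nt, constant
Phred-40 qualities). Insert 5′ ends are drawn from the mixture above;
insert lengths are uniform on 20–40 nt, and pervasive start positions are
drawn so the insert fits at full length within the transcript (5′-component
inserts are clamped at the transcript end). A configurable fraction of
emitted reads are exact copies of earlier reads (PCR duplicates) or
low-complexity contaminants (homopolymers / dinucleotide repeats). Every
read's provenance (source transcript, transcript-coordinate offset, genomic
position, category, duplicate parent) is recorded in a truth table, which
makes every downstream statistic recomputable independently of the
pipeline.

`simulate_rnaseq_reads` samples plain reads proportional to per-condition
*molar* abundance, uniformly along each transcript. The spike species is
planted at 2% of the molar input of the reference condition and held
constant across conditions, so study-wide decay changes the spike's share
of reads — exactly the signal spike normalization recovers.

`simulate_trapp_ratios` writes long-format protein ratio tables
(protein, condition, time ∈ {2, 4, 8, 12, 16} min, replicate, log2 ratio,
peptide count); entries are planted effect + Gaussian noise, independently
missing with a configurable probability.

What the generators do **not** emulate: sequencing errors, antisense reads,
paired ends, intron-containing genes, barcode bleed-through, non-uniform
fragmentation or amplification biases, and peptide-level quantification
noise structure. Passing tests therefore demonstrate correctness of the
analysis logic under the stated statistical model, not robustness to every
artifact of real libraries.

## Preprocessing conventions

- **Demultiplexing** is an exact match of the barcode field at positions
  `[umi_len, umi_len + barcode_len)`; the UMI is recorded and the prefix
  removed.
- **Trimming** follows the published parameter set (minimum adapter overlap
  4, ≤ 2 uncalled bases, minimum length 11, right-end adapter removal,
  3′ quality-tail trimming) with two choices the original description
  leaves open, fixed here as this package's normative definitions: quality
  trimming precedes adapter removal, and adapter matching is exact
  (zero mismatches). The quality-tail threshold is Phred 20 (the original
  tail mode names no value; synthetic qualities are constant so tests are
  insensitive to it).
- **Duplicate collapsing** keeps the first read per distinct
  (UMI, sequence) pair, after trimming. Two independent molecules that
  happen to share both insert and UMI are merged — that is the UMI's
  intrinsic false-collapse rate (UMI length 3 ⇒ 64 tags), visible in the
  truth table and accounted for in the tests.
- **Entropy filter** (normative dialect): a read is scored by the *maximum*
  over all windows of length 10 of the Shannon entropy of the window's
  6-mer frequency distribution, normalized by `ln(min(window−k+1, 4^k))`;
  reads shorter than the window are scored on the full read; reads shorter
  than k are kept; keep iff score ≥ 0.5. Whether the original tool scores
  by mean or max window entropy is not recoverable from its published
  parameters; max was chosen so that a single informative window rescues a
  read, and the definition is frozen by oracle tests.

## Alignment and counting

The aligner places a read at every exact match on either strand and picks
one location uniformly at random (seeded) when there are several, flagging
it multimapped — the random-assignment policy used for CRAC data.
Mismatches and indels are out of scope because the simulator is error-free;
coordinate-sorted SAM/BAM from a real aligner can be imported instead.
Internally all coordinates are 0-based half-open; GFF3 I/O converts to
1-based inclusive.

A read is assigned to the transcript containing its **crosslink-proximal
base** (the 5′-most aligned base: start on `+`, end−1 on `-`), sense-strand
only. Single-base assignment makes every boundary case deterministic: a 5′
base at CDS offset 150 is the first base *outside* the 5′ region
(half-open). For CDS shorter than 150 nt the 5′ region is the whole CDS.
Overlapping transcripts (absent from the toy genome but allowed) are
resolved by a seeded uniform choice.

RPM normalization adds 3 pseudocounts to both metrics and divides by a
configurable library size: transcript-assigned reads (default), all mapped
reads (the total-library-size convention), or an explicit per-condition
value such as the read count on a stable internal-standard locus.

## Why the recovery experiments normalize to an internal standard

Per-library RPM measures *relative* binding only: when a stress removes a
large fraction of total binding, the surviving reads are renormalized and
the apparent per-transcript fold change is compressed by the factor
`Z_ctrl / Z_stress` (the ratio of total retained occupancy). No choice of
within-mRNA library size can undo this — it is a property of the
measurement, not a bug. The retention-recovery experiment therefore gives
the toy genome a stable rRNA-like background locus and normalizes fold
changes to the read count on that locus; because the background's expected
share scales as `1/Z` in exactly the way the mRNA counts do, the
renormalization cancels and the planted retention becomes identifiable.
The experiment also uses long transcripts (CDS 1.8–3 kb) so that the fixed
5′ window is a minor fraction of the body: the pervasive occupancy that
falls inside the window is not scaled by the 5′ retention, and on short
transcripts that leak-through would dominate the planted signal. The
residual positive bias of ≈ 0.1 log2 units at retention 0.1 (leak-through
plus the pseudocount floor) is expected and stable.

## Metagene and pervasive statistics

Metagene profiles tally read 5′ bases at offsets relative to the first CDS
base (offset 0 = A of AUG; window default −200…+500, clipped to transcript
bounds), normalize each transcript's vector to sum 1, average with equal
weight over transcripts with ≥ 1 in-window read, and renormalize — so
highly bound transcripts do not dominate. A pooled-count mode is provided.
Because the profile always sums to 1, loss of 5′ binding appears as a
*shift* of mass; the scale-free readout used in tests is the
5′-window/downstream mass **ratio** (odds), which drops ~8–9-fold under a
planted retention of 0.1.

The pervasive statistic compares raw counts (not densities): a transcript
is pervasive iff downstream count ≥ 5′ count, inclusive; the fraction is
taken over transcripts with ≥ 1 read. A density mode (counts divided by
region lengths) is available and reported separately. The count comparison
is only identifiable when the 5′ region is a minority of the transcript:
with the default Ded1-like weights (0.2/0.8) transcripts of ≥ ~1 kb
classify correctly with high probability at ~500 reads per transcript,
which is why the pervasive-recovery experiment uses CDS 900–1800 nt.

## Spike-in normalization

Scale factors are defined on read *shares*,
`f(s) = (spike/study)_ref / (spike/study)_s`, rather than absolute spike
counts, making them invariant to sequencing depth; factors rebase exactly
(factors against reference A, divided by A's factor against B, equal
factors against B). Adjusted RPKM is plain RPKM × factor. Log fold changes
of lowly expressed transcripts are guarded by a pseudo-RPKM ε = 0.1.
RPKM denominators use mapped study-species reads.

## TRAPP / SILAC analysis

Ratio tables are filtered to proteins identified with ≥ 2 peptides, then to
proteins with ≥ 2 non-missing replicates at every scoped time point;
replicates are aggregated by the median; classification at 16 min uses a
*strict* 2-fold threshold (values exactly at log2 2 are unclassified, per
the "greater than 2-fold" definition). PCA uses column-mean centering
without scaling (log2 ratios are already on a common scale), economy SVD,
explained variance σᵢ²/Σσ², and a sign convention that makes the
largest-magnitude loading of each component positive. The matrix must be
complete; imputation is deliberately not offered — complete-case filtering
mirrors how such time courses are analyzed.

## Problem sizes and numerical choices

The recovery experiments use 20–100 transcripts and 50,000 (CRAC) or
100,000 (RNA-seq) reads per library, chosen so that per-transcript counts
are deep enough for the estimators' asymptotic behavior (5′ counts ≥ ~200
per transcript under the strongest planted loss) while each experiment
completes in seconds. Random draws all flow from numpy `default_rng`
seeded per (seed, stream label) via CRC-hashed labels, so every generator
is byte-reproducible and conditions are statistically independent.
Tie-breaks are deterministic throughout (transcript id lexicographic for
rankings, smaller coordinate for summit ties). Degenerate inputs raise
rather than guess: empty genomes, zero library sizes, zero spike reads,
missing conditions, incomplete PCA matrices.

## Known limitations

- Exact-match alignment cannot place reads with sequencing errors; real
  libraries must be aligned externally and imported.
- The retention estimate depends on a stable internal standard; without
  one, only relative binding changes are recoverable (and the package makes
  that explicit rather than hiding it).
- The entropy-filter and trimming dialects are normative re-specifications
  of published tool parameters, not re-implementations validated against
  those tools' binaries.
- Regulon labels are input annotations; no functional enrichment analysis
  is provided.
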