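# Methods

This note documents the models, conventions and numerical choices behind
`tcprof`, and what the synthetic-data tests do and do not establish about
real data.

## Coordinate frame and annotation

All computation happens in transcript space: position 0 is the first
nucleotide of the annotated 5′UTR; coordinates are 0-based with
half-open intervals. The CDS includes the stop codon (yeast GFF
convention), so with `A = utr5_len` (first nt of the start codon) and
`S = utr5_len + cds_len − 3` (first nt of the stop codon), offsets
quoted "relative to the 3′UTR start" are `pos − (S + 3)`.

Annotations are assembled from a GFF3 CDS file (splice-joined,
strand-aware; parsed with gffutils), a genome FASTA (Biopython) and a
tab-separated UTR-length table; a consolidated one-file cache format is
provided for reuse. Dubious ORFs and transcripts whose genomic spans
intersect another transcript (on either strand — same-strand-only would
silently admit antisense overlaps) are always excluded from analyses;
genes with 5′UTR introns are additionally excluded from quantitation and
position-average analyses. Overlap detection spans CDS plus UTRs by
default (`overlap_span="cds"` restricts it), since the annotation does
not say which convention defines "overlapping" and the wider reading is
the conservative one.

## Read preprocessing

The modified library protocol leaves each read as
`[2-nt RT UMI][insert][5-nt linker UMI][5-nt barcode][linker constant]`.
Demultiplexing locates the linker constant (exact suffix/substring match
by default; a mismatch allowance is configurable but off so tests are
deterministic), assigns the barcode (0 mismatches by default — the
tolerance is unstated in the protocol, so the strictest choice is the
default) and concatenates linker UMI + RT UMI into the 7-nt key.
PCR duplicates are collapsed on (sample, insert sequence, 7-nt UMI)
before alignment; keying on the insert sequence is equivalent to keying
on the alignment position pre-alignment and keeps deduplication
independent of aligner behaviour. Libraries built with the original
UMI-less protocol bypass deduplication via a per-sample protocol flag.
Size selection keeps 15–80-nt inserts for 40S libraries and 25–34 nt for
80S, bounds inclusive.

## Classification and quantitation

- **Region classification** uses the unshifted whole-footprint interval:
  START if it intersects `[A−3, A+6)` (the 9-nt window centered on the
  start codon — "centered" fixes the endpoints), else STOP if it
  intersects `[S−6, S+3)` (the 9-nt window ending with the stop codon),
  else the region containing the 5′ end. START takes precedence over
  STOP; the tie is only possible for very short CDSs and is logged.
- **P-site shift**: +14 nt (40S), +13 nt (80S), 0 (mRNA-seq). Offsets
  are fixed constants of the assay, not learned.
- **Peak height**: sum of shifted 5′-end counts in `[C−2, C+2]`
  (5 nt) centered on the first nt of the anchor codon — the position at
  which a stalled complex's shifted 5′ end accumulates. Windows
  truncated by transcript ends are flagged.
- **Densities**: rpkm over the end-trimmed ORF `[A+15, S+3−15)` (15-nt
  trims remove initiating/terminating ribosomes) and over the 3′UTR
  extended 25 nt past its annotated endpoint (poly(A)-protecting
  footprints). In transcript space no alignment can extend past the
  annotated transcript, so the extension affects the length denominator
  only; this is stated rather than hidden. rpm denominators are the
  per-sample total of retained transcript-mapped footprints after
  deduplication and size selection — the reproducible choice given that
  ncRNA contaminants are removed upstream.
- **Inclusion thresholds** (5 rpkm ORF, 0.5 rpkm 3′UTR) are inclusive
  (≥): the protocol language ("a threshold … was required") does not
  specify strictness and inclusive bounds are the natural reading.
- **Focused length range**: most 40S analyses restrict to 26–45 nt.
  The narrower 26–42-nt range that appears in one description of read
  processing is available by passing `length_range=(26, 42)`.
- Multimapping reads are excluded entirely; all weights are 1.

## Metagene and metacodon averages

A metagene is the equal-weight mean across genes of per-gene rpm tracks
of footprint 5′ (or 3′) ends at each offset from the anchor codon; genes
qualify when the flanking features cover the window (100 nt of UTR and
300 nt of ORF for the default 1-D windows, ±100 nt of the feature for
2-D), and qualifying genes with zero reads in the window contribute
zeros (excluding them would bias the average upward). 3′-end alignment
uses `five_prime + length − 1` (last protected nucleotide), which keeps
the 5′/3′ relation an exact per-row shift by the footprint length.
The 2-D variant resolves the same average by footprint length (15–80
nt); summing its rows reproduces the 1-D trace to machine precision.

Metacodon (position-average) profiles average the rpm track over every
exact occurrence of a motif inside a UTR, in all frames (plain substring
scan — `STOP` searches TAA/TAG/TGA jointly). Genes with no reads in the
relevant UTR are excluded; occurrences whose window leaves the
transcript are dropped; windows that reach into the CDS are kept by
default (`truncate_at_cds` zeroes them), since the plotted window around
a UTR motif legitimately includes flanking CDS occupancy. With
ORF normalization, tracks are divided by the gene's ORF density and
genes under 5 rpkm are excluded.

## Penultimate-codon bootstrap

Per-gene ratios are mutant/WT stop-peak **rpm** (depth cancels; raw
counts would conflate library depth with biology). Genes whose WT peak
count is below `min_wt_count` are omitted; the default floor is 1 (a
zero denominator is undefined; any stricter floor is an analysis choice
the caller must make explicitly, since the original inclusion rule is
not documented).

For each codon c at a fixed position (default −1, the penultimate
codon) with n_c ≥ 10 occurrences, the observed mean ratio m_c is
compared against 20,000 means of n_c ratios drawn with replacement from
the pooled all-gene ratios. The two-sided percentile p-value uses an
add-one correction, `p = (1 + #{|null − μ| ≥ |m_c − μ|}) / (n_boot + 1)`
with μ the pooled mean; two-sided because both increased and decreased
ratios are biologically meaningful (slow vs fast tRNA release), and
add-one so p is never exactly 0. Significance is `p < 0.01` per codon
with **no multiple-testing correction** across the 61 sense codons —
the per-codon 99% confidence statement is the deliverable, so roughly
0.6 false flags per transcriptome-wide sweep are expected and the
position sweep reports counts per position rather than corrected calls.
Codon groups are summarized by the mean (not median). All resampling is
reproducible from a seed; the position sweep spawns an independent
stream per position so adding positions never perturbs existing ones.

### Small-denominator bias of ratio means

The mean of per-gene ratios is biased upward when WT peak counts are
small: for a Poisson denominator W,
`E[M/W | W ≥ 1] = E[M]·E[1/W | W ≥ 1] ≈ fold·(1 + 1/λ + 2/λ² + …)`.
At desk-scale depths (10⁵ reads over ~600 genes, λ ≈ 4–8 per gene) this
inflates the mean of ratios by ~15–30% over the planted rpm fold, while
leaving relative codon effects (codon mean ÷ pooled mean) unbiased,
because the bias factor is shared. The package therefore reports both
the mean of per-gene ratios (the conventional summary) and, in ground
truth, the planted fold; consumers comparing the two should expect this
gap whenever per-gene WT counts are in single digits. The ratio of
summed peaks is the unbiased alternative when only the global fold is
wanted.

## Synthetic-data generator

The generator emulates the occupancy structure the analysis assumes,
with every expected statistic recomputable in closed form from the
recorded ground truth (the per-gene × per-component sampling matrix):

- **Components**: 5′UTR background, start peak (5′ end at `A − shift`),
  ORF background (3-nt P-site periodicity, default 90% frame 0), stop
  peak (`S − shift`, so the shifted P site is the stop codon), 3′UTR
  background, 3′UTR-AUG peaks at planted AUGs, and queued-80S reads at
  `S − 46` with ±3-nt satellites — i.e. −49/−46/−52 nt from the 3′UTR
  start, one footprint length behind the stalled complex.
- **Lengths** are drawn independently of the 5′ end (3′-end variability
  only): 40S mode 32 nt (clip 26–45) plus a minor 21-nt class (8%); 80S
  mode 28 nt (clip 25–34).
- **Backgrounds are planted clear of the start/stop classification
  windows**, so component labels and region labels coincide exactly and
  planted mixtures are recovered up to multinomial noise.
- **Genotypes** reweight components: the recycling-mutant profile
  multiplies each gene's stop peak by `stop_fold_change` × a
  per-penultimate-codon multiplier and boosts 3′UTR/queued components;
  the 60S-shortage profile boosts start peaks. When the boosted mass is
  below 1, unboosted components are rescaled so both genotypes keep the
  same total and the expected rpm fold equals the configured fold
  exactly; otherwise the whole mixture is renormalized (logged) and the
  truth matrix carries the realized fold.
- **Sequences** are uniform-random with valid start/stop codons, a
  balanced penultimate-codon design (cycling the 61 sense codons so
  each reaches equal count), planted 3′UTR AUGs/dORFs, and accidental
  UTR AUGs scrubbed so planted motif positions are the exact truth.
- **Default occupancy weights** (40S WT: 9% 5′UTR, 58% start, 24% ORF,
  4% stop, 5% 3′UTR) are start-dominated like real 40S libraries. The
  stop-peak weight is set at the upper end of the plausible range so
  that per-gene stop-peak counts at the default depth (10⁵ reads, ~160
  reads/gene) are large enough for stable per-gene ratios; real WT
  libraries show a smaller stop fraction (~2.5%), and the constant
  `PAPER_WT_REGION_MIXTURE` provides that observed mixture as an
  explicit preset for region-fraction emulation. `stop_fold_change`
  defaults to 20 — the order of magnitude observed for recycling
  mutants (transcriptome averages of ~23-fold).
- **Expression** is uniform across genes by default
  (`expression_dispersion = 0`), which isolates the mixture structure;
  setting it to ~1 draws log-normal per-gene levels spanning roughly an
  order of magnitude, which is required for between-gene correlation
  analyses to be meaningful.
- **FASTQ emission** renders footprints with the full linker/UMI/barcode
  structure; UMIs are assigned distinct within each (sample, insert)
  group so that planted duplicate counts are recovered exactly — a
  designed ground truth, slightly cleaner than fully random UMIs whose
  rare collisions would make "exact" recovery probabilistic.

### What the synthetic tests do not show

The generator draws iid multinomial reads from fixed mixtures. It has no
sequence-dependent ligation/RT bias, no rRNA/tRNA contamination, no
mappability structure, no overdispersion between biological replicates,
and (by default) no expression variation. Passing tests therefore
establish the correctness of the computations and their calibration
under the stated model, not robustness to the technical artefacts of
real libraries.

## Problem sizes and determinism

Tests and the acceptance script run on transcriptomes of 30–610 genes
and libraries of 10³–2×10⁵ reads, with 2,000-draw bootstraps in loops
and the full 20,000 draws for single analyses — sizes chosen so the
whole suite completes in seconds while keeping Monte-Carlo error well
inside the asserted tolerances (documented per test). Every stochastic
step takes a seed or a NumPy `Generator`; pipeline stages derive their
streams from the run seed, making end-to-end outputs byte-identical
across reruns.

## Known limitations

- P-site offsets are fixed constants; no offset learning from periodicity.
- Transcript-space only: genome-space visualization, wiggle export and
  alignment itself are out of scope (the BED-like dialect and SAM/BAM in
  transcript coordinates are the ingestion boundary).
- The UTR-intron flag must be supplied via the UTR table; it is not
  derived from the GFF.
- IUPAC/degenerate motifs are not supported in metacodon scans.
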