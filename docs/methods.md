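# Methods

This note documents the models and procedures implemented in `multiclip`,
the assumptions behind them, the tunable parameters and their defaults, and
what the synthetic-data generator does and does not emulate.

## Background and scope

PAR-CLIP identifies protein–RNA crosslink sites through diagnostic T→C
transitions introduced during reverse transcription at 4SU-crosslinked
uridines. For an RNA-binding protein with many tandem RNA-binding domains
(the motivating case has 15 KH domains), binding is *multivalent*: clusters
of short CU-rich four-mers within a window of a few tens of nucleotides
allow several domains to engage simultaneously, and such multivalent
regions concentrate in the coding sequences of ER-targeted (membrane-class)
mRNAs. `multiclip` implements the downstream analyses that quantify this
picture — crosslink filtering and normalization, mRNA localization classes
from fractionation RNA-seq, k-mer and multivalency statistics, ribosome
P-site metagenes and codon occupancy, and tRNA/proximity-labeling/pSILAC
filters — starting from transcript-space pileup and count tables. Read
trimming, alignment, and cluster *calling* are out of scope; clusters and
pileups are consumed as input.

All internal coordinates are 0-based half-open in transcript space on the
sense strand (BED convention); protein coordinates and human-facing reports
are 1-based inclusive. Sequences are normalized to a single alphabet at
load (default DNA/T); k-mers in output tables are spelled in RNA.

## Crosslink filtering and summaries

**Reproducible clusters.** A replicate-1 cluster is kept when a replicate-2
cluster on the same transcript (i) overlaps it by ≥50% of the nucleotide
length — interpreted *reciprocally* (≥50% of both cluster lengths), the
stricter and symmetric reading; an either-length mode is available —
(ii) has its maximum-T-C position ≤10 nt away, and (iii) the pair's mean
T-C sum is ≥3. All three thresholds are boundary-inclusive. The kept
cluster carries replicate-1 coordinates (union coordinates available);
when several replicate-2 clusters support one replicate-1 cluster, the
pair with the highest mean T-C wins. Ties for the maximum-T-C position are
broken toward the smaller coordinate.

**Reproducible sites.** Positions must show T-C transitions in both
replicates, with transition specificity (T-C count / coverage) below 0.95
in both; positions at specificity ≈1 are genomic variants rather than
crosslinks. T-C per million normalizes each replicate by its library total;
the default library total is the replicate's total T-C events (rather than
total mapped reads), which makes the normalization self-contained on a
site table.

**Gene summaries.** Per-gene T-C totals split exactly across 5′UTR, CDS and
3′UTR. Crosslink enrichment E = total T-C / whole-cell TPM corrects for
expression bias. The CDS-vs-3′UTR preference is
R = log2(((tc_cds + 0.5)/L_cds) / ((tc_3utr + 0.5)/L_3utr)); the 0.5
pseudocount admits genes with zero 3′UTR signal, and genes without a 3′UTR
are excluded from R. Genes are grouped low/mid/high by a configurable
statistic cut at (0.3, 1.39); the default statistic is log2(E + 0.5),
since the scale of the published thresholds is not fully specified.

**Meta-transcript profile.** Transcripts need ≥5 T-C per million in both
replicates. Site values (mean T-C per million across replicates) are scaled
to the per-transcript maximum, positions are mapped to fixed relative bins
per region (100/300/200 for 5′UTR/CDS/3′UTR by default; per-nucleotide mode
available), and each transcript contributes its per-bin maximum — so every
included transcript attains exactly 1 somewhere and the averaged profile
stays in [0, 1].

## mRNA localization classes

Counts are normalized by median-of-ratios size factors (geometric-mean
reference over genes with all-positive counts; the direct natural-scale
median). Membrane enrichment is M = log2 of the ratio of normalized
condition means (membrane over cytosol) with one pseudocount on both sides;
a mean-of-replicate-ratios mode exists. Classes: membrane iff M ≥ 1.5,
cytosolic iff M ≤ 0.5, undefined between, excluded below TPM 10 — all
boundaries inclusive. TPM is computed directly from counts and effective
lengths (no EM; one isoform per gene is enforced at load, keeping the
highest-TPM isoform).

A caveat that matters for interpretation: when *every* gene differs between
fractions (as in fractionation designs) and there are no spike-ins,
median-of-ratios fixes an arbitrary global location constant, so M is
identified only up to that offset. The classification cutoffs tolerate the
small offset this induces at realistic class mixtures; the test suite
checks location-free bias rather than absolute bias, and separately bounds
the offset itself.

Targeting classes are assigned with precedence mtDNA (gene symbol prefix
"MT-") → tail-anchored (TM helix, no signal peptide, first TM starting ≤50
aa from the C-terminus; protein length = CDS codons − 1 stop) → SP+TM → SP
only → TM only → nuclear-encoded mitochondrial (from a provided list) →
membrane-localized without known signal → no signal.

## K-mer and multivalency statistics

**Crosslinked k-mers** (4 ≤ k ≤ 12): every k-window overlapping the
crosslinked nucleotide contributes one count (up to k windows, truncated at
transcript ends). A single-register "anchored" mode counts only the window
starting at the site. The overlap convention is the default because a
crosslink inside a CU repeat should credit the repeat in all registers.
Frequencies are normalized within sample; ranking is by frequency with
lexicographic tie-breaks.

**Per-gene k-mer signal**: a site's T-C count is attributed once to each
*distinct* k-mer overlapping it, summed per (gene, region), then divided
by region length and whole-cell TPM; k-mers are ranked by the median log2
normalized signal across genes.

**Class-wise z-scores**: k-mer frequencies from all k-windows of two
sequence sets (e.g. membrane CDS vs cytosolic CDS); delta_f = f(A) − f(B)
standardized into z over the k-mers observed in either set (absent k-mers
have delta_f = 0 exactly and are omitted from the standardization — at
k = 12 the 16M absent k-mers would only dilute the constants). If the SD of
delta_f is 0, all z are set to 0. The top-crosslinked group is compared to
all other k-mers with a two-sided Wilcoxon rank-sum test.

**Multivalency score**: for each crosslink site, the number of occurrences
of a four-mer group (default: the top ten crosslinked four-mers) whose
start lies within ±40 nt, excluding the open interval (−4, +4) — offsets
of exactly ±4 count. Overlapping occurrences each count; no masking.
Anchors are quantile-binned into five near-equal groups (sizes differ by
≤1; stable tie-break by score, transcript, position). `window_tc` sums the
T-C per million of sites under the same window/exclusion geometry, and the
per-bin positional profile distributes that signal over the 81 offsets as
percentages summing to 100. Anchors within 40 nt of a transcript end are
kept but flagged truncated.

**Sliding-window potential**: occurrences of a four-mer group counted in
30-nt windows sliding 1 nt (an occurrence belongs to windows containing its
start); windows with fewer than 3 occurrences are discarded; the
per-transcript score is the mean over kept windows (0 if none). Class and
region comparisons use the rank-sum test.

## Ribosome profiling

Footprints arrive as 5′-end positions; the P-site is 5′ end + 13 nt (the
fixed published offset; per-length offset estimation is out of scope).
Reads whose shifted position leaves the transcript are dropped and counted,
so retained + dropped equals the input.

The start/stop metagene excludes the first and last two codons from the
scaling mean (initiation/termination peaks), requires total codon coverage
≥5, scales each transcript by its trimmed-CDS mean, averages positionally,
and smooths with a centered 10-nt rolling mean (truncated at edges). The
targeting-signal metagene normalizes codon coverage to the transcript's
mean over codons 20–40, averages over codons 1–500 for transcripts carrying
a signal (grouped signal-peptide vs first-TM, TPM ≥10 when supplied),
smooths with a 5-codon rolling mean, and masks codons supported by fewer
than 5 transcripts — the far tail of the span is otherwise dominated by the
few longest CDSs. The pause locator reports the first codon reaching
halfway between the profile median (a robust baseline, since the 20–40
normalization window may overlap the pause) and the maximum; half-rise is
robust to the plateau shape of a multi-codon pause, unlike an argmax.

Codon occupancy is footprint-weighted: per replicate, the frequency of each
of the 61 sense codons among P-site (or E-site = P-site − 1 codon)
footprints, stop codons excluded and frequencies renormalized. The shift is
delta = mean(KO) − mean(WT) per codon, whose sum is 0 by construction, with
SD across replicate pairs.

Translation efficiency is the normalized ratio-of-ratios point estimate
log2(((RPF_KO+1)/(RNA_KO+1)) / ((RPF_WT+1)/(RNA_WT+1))) on size-factor
normalized condition means — no p-values; downstream use compares
fold-change distributions between gene groups, which the point estimate
supports, and it is exactly antisymmetric under swapping conditions.

## tRNA, BioID, pSILAC, RIP

tRNA enrichment = (library-normalized T-C over non-masked positions) /
(library-normalized abundance reads), ranked descending with ties by id.
Masking (dihydrouridine positions, which cause RT misincorporation that
mimics crosslink signal) is applied before summation.

BioID: per replicate pair (Dox batches 1, 2, 3 against untreated batches
2, 2, 3 — the asymmetric pairing reuses untreated batch 2), a protein
passes with LFQ(Dox)/LFQ(noDox) ≥ 3 (raw ratios, not log2) and log2
LFQ(Dox) ≥ 27, or with log2 LFQ(Dox) ≥ 27 alone when the denominator is 0;
all three pairs must pass, plus ≥3 razor unique peptides. Ranking is by
mean Dox LFQ; the display enrichment for zero-denominator proteins is the
table's maximum mean log2 enrichment + 2.

pSILAC: pairs quantified from two requantified intensities are removed;
reverse-orientation ratios are negated onto the KO/WT scale (the labels are
switched in the reverse experiment; a flag disables the inversion); a
protein needs at least one value in both orientations.

RIP-qPCR fold enrichment defaults to 2^(Ct_IgG − Ct_bait), which is ≥1 for
bait-bound RNAs under Ct semantics (lower Ct = more template); the literal
bait-minus-control exponent is available by flag.

## Synthetic-data generator

The generator plants the statistical structure each analysis assumes and
serializes the ground truth, so every stage is testable end to end without
deposited data. One global seed expands into per-stage streams by a fixed
spawn order (transcriptome, PAR-CLIP, fractions, footprints, tRNA,
proteomics); the same seed reproduces every table byte for byte.

- **Transcriptome** (default 300 genes; 35% membrane / 50% cytosolic / 15%
  undefined): uniform random background sequence; 5′UTR 60–200 nt, CDS
  150–400 codons, 3′UTR 150–600 nt. Membrane transcripts carry CDS hotspots
  (≈4 per CDS kb) of 2–4 motifs from {UUCU, CUUC, UCUU, CUCU} within 40-nt
  windows, plus a planted signal peptide (end fixed at aa 25, in 60% of
  membrane genes) or TM helix (start 25–60); cytosolic transcripts carry
  ≈1 isolated motif per kb split between CDS and 3′UTR. Planted log2
  membrane enrichment is +2.5 / −1.0 / 0 per class plus N(0, 0.3) per-gene
  scatter — effect sizes chosen so class separation is unambiguous at desk
  scale (hundreds of genes, tens of counts per gene), all configurable.
- **PAR-CLIP**: coverage at T positions is Poisson with mean ∝ TPM × depth
  (default 50×); T-C counts are Binomial(coverage, conv_rate × propensity +
  err_rate) with conv_rate 0.3 and err_rate 0.001, where the propensity is
  the local motif multivalency of the realized sequence (occurrences within
  ±20 nt, saturating at 4) at U positions. Clusters are the maximal runs of
  non-zero local multivalency with ±3 nt replicate-jittered boundaries.
  Pileups are emitted for T positions (the only convertible ones).
- **Fractions**: Negative Binomial (Gamma–Poisson, dispersion 0.05;
  Poisson at 0) around per-gene means that split expression between
  membrane and cytosol by the planted enrichment. Fraction samples share a
  common normalization mass so the planted enrichment is identifiable from
  count ratios (a spike-in-like convention; see the localization caveat).
- **Footprints**: per-codon Poisson counts ∝ TPM × depth, modulated by
  dwell multipliers — WT pauses ×2.0 over 10 codons starting at the
  signal-end codon; KO keeps a reduced ×1.2 pause and gains ×1.3 dwell on
  {CUU, CUC, UUC, UUU}; 5′ ends are emitted at P-site − 13 nt.
- **tRNA/proteomics**: 20 random tRNAs + one "modification-only" control;
  3 tRNAs get 3× crosslink excess at unmasked U positions; masked D-loop
  positions (16, 17, 20) get condition-independent high T-C noise. The
  per-position conversion rate is scaled by U content so per-tRNA
  crosslinkability reflects only the planted excess. BioID: 200 proteins,
  20 true positives at Dox/noDox ratio 8 with noDox LFQ ≈ 2^25.5 (so Dox
  clears the 2^27 floor with a wide margin); background ratios ≈1. pSILAC:
  100 proteins, true log2 KO/WT ~ N(0, 0.5), forward and reverse
  orientations with 10% forward-only dropout and 10% requantification flags
  per side.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: alignment and mappability artifacts, PCR
duplicates and UMI structure, non-uniform nucleotide composition and codon
usage, RNA secondary structure effects on crosslinking, isoform mixtures,
overdispersion beyond the NB fraction model (PAR-CLIP coverage is Poisson),
batch effects, and correlated replicate noise. Tests demonstrate that the
implementations recover planted structure under the stated noise models,
not that the biological conclusions reproduce from raw reads.

## Numerical conventions

Rolling means are centered with truncated windows at edges. Quantile bins
are near-equal with deterministic tie-breaks. Ranking ties break
lexicographically by identifier. Degenerate inputs raise: zero library
totals, zero-length regions where a region is required, coverage 0 with
T-C > 0, CDS shorter than twice the metagene trim, pause windows past the
CDS end. Problem sizes in the test and acceptance runs (60–500 genes,
depth 50–80×, 20 seeds for rate estimates) are the package's desk-scale
defaults; all are config keys.
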