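# Methods

This note documents the models and procedures behind each stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical/design choices made where the procedure was
genuinely open.

## Coordinates and sequence space

All coordinates are 0-based half-open internally; tables intended for human
reading carry `_1based` column suffixes. All RNA is handled in DNA space
(U→T on input), so "G:U wobble" appears as the pairs (G,T) and (T,G).

## Discovery

**Size filter.** Reads of 20–24 nt are retained (`min_len`/`max_len`): the
size range of plant miRNAs and siRNAs produced by Dicer-like enzymes.

**Condensation.** Sequencing around an abundant sRNA produces a cloud of
low-abundance variants (sequencing error, imprecise processing). Unique
reads are visited in decreasing total-count order (ties broken
lexicographically, which makes the pass deterministic and
permutation-invariant); a read within `condense_dist` (default 2)
Levenshtein edits of an already-accepted representative joins the
highest-ranked such representative, otherwise it seeds a new cluster.
Cluster abundance is the combined abundance of all clustered reads.
Clusters whose maximum per-library RPM falls below `rpm_min` (default 0.5)
are discarded. Two choices the procedure leaves open: the RPM denominator
is the per-library total of size-filtered reads, computed before host
filtering; and the 0.5 RPM floor applies to the maximum across libraries
(the most permissive reading of "0.5 RPM or higher"). Levenshtein distances
are computed with edlib; the test suite checks them against an independent
dynamic-programming implementation and checks the whole condensation pass
against a brute-force transcription of the greedy algorithm.

**Host filtering.** An sRNA in an interface library may come from the host
rather than the parasite. A condensed sRNA is removed when any of three
rules fires: (1) it is within `host_mirna_dist` (default 2, matching the
condensation radius) edits of an annotated host miRNA; (2) it or its
reverse complement occurs verbatim in the host genome/transcriptome
(either-strand exact substring — note this deliberately removes perfect
complements of host mRNAs, which are indistinguishable from host
degradation products); (3) its mean control-library RPM exceeds 1/100 of
its mean parasite-library RPM (zero parasite signal with any control signal
also removes it; both zero retains it).

**Differential accumulation.** Interface vs parasite-stem counts are tested
per sRNA with a negative-binomial Wald test: library size factors by the
median-of-ratios method; per-sRNA dispersion α (Var = μ + αμ²) estimated by
method of moments pooled across the two conditions and floored at 0.01; the
log2 fold change uses a 0.5 pseudo-count and its standard error comes from
the delta method on the replicate mean. Two-sided p-values are
Benjamini–Hochberg corrected; calls require padj < `fdr` (default 0.1) and
log2fc > 0. This is a deliberate, documented stand-in for DESeq2's full
shrinkage machinery: acceptance is parameter recovery on synthetic data
(measured sensitivity 100% at the default 8-fold/3v3 conditions; null
false-call proportion ≈ 1%, within the ≤ 15% calibration band — the MoM
dispersion with 3 replicates is slightly anticonservative).

## Families and superfamilies

**Modified Hamming distance.** Superfamily clustering bars indels yet must
absorb the 20–24-nt length spread, so the distance is the minimum over all
ungapped offsets of (mismatches in the overlap + total overhang length).
Equal-length sequences reduce to plain Hamming distance at offset 0; the
function is symmetric and zero only for identical sequences.

**Clustering.** Families (edit distance ≤ 1) and superfamilies (modified
Hamming ≤ 5) are single-linkage connected components; components are
reported in decreasing size (ties by lexicographically smallest member),
which fixes the ids without affecting membership. The superfamily MSA pads
members to the longest member's length at their best ungapped offset — no
internal gaps, consistent with the no-indel clustering.

**Shuffle null.** The chance-grouping rate of the distance-5 cutoff is
estimated by re-clustering dinucleotide-preserving shuffles
(Altschul–Erickson Euler-path shuffle: the output has exactly the input's
dinucleotide multiset and both terminal nucleotides). Both a per-sequence
rate (fraction of sequences in multi-member clusters) and a per-cluster
rate are reported, since either convention is defensible.

## Target prediction

Duplexes are scored with position-weighted penalties: mismatch 1.0, G:U
0.5, each bulged nucleotide 1.0, all doubled when the guide position
involved lies in positions 2–13 from the 5′ end (`core_start`/`core_end`,
exposed in config because the exact core boundary is a convention). At most
one single-nucleotide bulge is allowed per duplex — larger loops would
exceed the usable score range anyway. A bulged guide nucleotide takes its
own position's weight; a bulged target nucleotide takes the weight of the
guide position 5′-adjacent to the insertion point. The scan scores every
window of every transcript (ungapped plus every single-bulge geometry) and
keeps, per (start, span) window, the minimal-score pairing; interactions at
or below `confirm_score` (default 6) are reported. The predicted cleavage
position is the target base paired to guide position 10 (cleavage between
guide positions 10/11); when position 10 itself is bulged the 3′-adjacent
pair defines the cut. Thermodynamic machinery (RNAplex folding, MFE ratios)
is intentionally out of scope: every downstream filter consumes only the
complementarity score.

One scoring asymmetry worth noting: G:U wobble is not preserved under
reverse-complementing both strands, so scanning the reverse-complemented
transcript with the reverse-complemented guide mirrors coordinates exactly
only for wobble-free duplexes (the test suite checks the involution on
perfect-complement sites).

## Confirmation

**Secondary-siRNA channel.** Cleavage guided by 22-nt sRNAs can convert the
target mRNA into a source of phased secondary siRNAs. Gene loci are tested
for interface vs control-stem up-regulation with the same NB machinery,
then filtered: a strong predicted site (score ≤ 6); unstranded
accumulation, quantified as plus-strand fraction in [0.2, 0.8] (no number
exists for "unstranded"; the band is exposed in config); predominant read
length 21/22 nt (modal length, ties including 21 or 22 pass); depth ≥ 20
reads. Phasing diagnostics assign each plus-strand 5′ end to register
((pos − cut) mod 21) + 1; register 1 is in phase with the predicted cut.

**Degradome channel.** Cleavage leaves the 3′ fragment's 5′ end at the cut
position. Six filters, each a slot in the reported pass vector: (1) score ≤
6; (2) site start > 100 nt into the transcript (0-based; avoids capped-TSS
artifacts); (3) target not organellar; (4) pooled treatment peak depth
exceeds the median depth over occupied positions of that transcript (the
median over *all* positions of a long transcript is 0, which would make the
filter vacuous); (5) peak present (≥ 1 read within `peak_window`, default
0, of the cut) in every treatment replicate; (6) peak ≥ 10-fold over the
mean control depth, with a 0.5 pseudo-count for empty controls. The fold
ratio uses the minimum over replicates that detect the peak, so filters 5
and 6 toggle independently — a truth-table property the tests enforce.
`require_control_fold=False` supports designs with no degradome control.
Manual by-eye curation has no automated surrogate here; the ranked
per-filter diagnostics are the intended replacement.

The two channels are computed independently; "confirmed by both" is the set
intersection of their confirmed gene sets.

## Covariation

Per-position variability is Shannon entropy in bits over non-gap symbols
(columns with fewer than two non-gap symbols are dropped from n). Guide
position i maps to sense-strand target column site_end − i (antiparallel).
The statistic is an OLS regression of superfamily entropy on homolog
target-site entropy: slope, Pearson r, and the two-sided p-value of the
regression t-statistic (R `lm` convention, kept two-sided although the
biological claim is directional). Positions invariant in both alignments
stay in n by default — they carry signal for a positive slope — with a
`drop_invariant` switch. A superfamily with zero entropy variance yields a
degenerate "no variation" result with p = 1 rather than an error. Measured
calibration: 100% power at the default planted conditions (8 members, 12
species, n = 21) and a permuted-column null whose p-values are uniform (KS
p ≫ 0.01, empirical size ≈ 5%).

Window conservation slides an 8-residue window (step 1) over the translated
homolog alignment, reporting the target window's mean column entropy
against the median and quartiles of all other windows. Motif discovery
scans superfamily members at high stringency (score ≤ 3), collapses
overlapping windows of one duplex to the best-scoring window per cleavage
position, translates sites fully inside the CDS in their reading frame
(sites spanning the CDS boundary are skipped with a log entry), and
clusters peptides greedily in descending frequency order at ≤ 3 amino-acid
edits.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
every planted feature recorded in a truth registry:

* **Superfamilies/homologs.** A random 7-codon peptide defines a 21-nt
  target site; species variants substitute synonymous codons at 0.5/codon
  and nonsynonymous ones at 0.02/codon (high-synonymous/low-nonsynonymous
  divergence, as deep coding-region conservation implies); 8-codon flanks
  diverge freely at 0.5/codon. Covarying families' members are reverse
  complements of sampled species variants — "perfect compensation". Null
  families vary at the positions of an independent pseudo-site passed
  through a fixed column permutation, which breaks the codon-frame
  alignment of their variation. Member 0 is the perfect complement of the
  reference site (host-filtered by design, as in real data); member 1 is a
  "causative" variant with ≥ 3 synonymous substitutions confined to the
  site's first codons, so it pairs the guide's 3′ region — outside the 5′
  core — scoring ~3 against the host site while sitting outside the
  condensation radius of member 0.
* **Libraries.** Negative-binomial counts (Var = μ + αμ², matching the DE
  model so recovery is well-posed) across per-isolate interface/stem
  triplicates plus shared host controls: planted sRNAs at base mean 100,
  8-fold up in interface; background sRNAs flat; host-derived reads (exact
  transcript substrings, one annotated-miRNA clone) present in control and
  interface but not stems; error-variant clouds at 3% of parent abundance
  within ≤ 2 edits. Reads whose length falls outside 20–24 exercise the
  size filter. Same-isolate planted sRNAs within the condensation radius of
  an earlier one are recorded as `expected_condensed` — absorbing them is
  correct pipeline behavior, not a miss.
* **Transcriptome/degradome/loci.** 30 random 600-nt transcripts with CDS
  [51, 531); each family's reference homolog region is planted in-frame
  > 100 nt from the transcript start. One decoy per confirmation filter is
  planted on its own transcript (near-TSS, organellar, below-median peak,
  2-of-3-replicates peak, 5-fold-over-control peak; single-stranded,
  24-nt-predominant, 19-read, and non-up-regulated loci). Degradome
  treatment replicates carry Poisson(0.02) background plus Poisson(50)
  peaks at true cut sites; locus reads are placed in 21-nt registers
  downstream of the cut on both strands (minus-strand 5′ ends offset by the
  2-nt duplex overhang) with a 10% off-register fraction; 12
  non-differential background loci anchor the locus-level normalization,
  as a genome-wide locus table would.

What the generator does **not** emulate: read-level FASTQ with quality
strings and instrument error models; positional/ligation bias; multiple
true targets per sRNA; genuinely divergent transcript families (homolog
sets are supplied pre-anchored and in-frame, so only padding, not full
MSA, is performed — with real data a pre-computed alignment is accepted as
input); and hairpin-precursor structure (miRNA/siRNA distinction needs a
genome and stays out of scope). Passing tests therefore demonstrate correct
implementation of the procedures and sound statistical calibration under
the stated model, not robustness to every artifact of real sequencing data.

## Problem sizes

The default scenario (6 families × 8 members over 4 isolates, ~240 unique
reads over 26 libraries, 30 transcripts, 3+3 degradome replicates) runs the
full pipeline in ~10 s; the statistical calibrations use 20 seeds (power,
sensitivity) and 200 seeds (null uniformity). These sizes give
Monte-Carlo error comfortably inside every asserted margin while keeping
the whole suite fast enough to run habitually.

## Known limitations

* The NB Wald stand-in is mildly anticonservative with 3 replicates (≈ 1%
  null call rate at nominal FDR 0.1); DESeq2's shrinkage would tighten it.
* Exact-substring host filtering (rule 2) cannot remove host reads carrying
  sequencing errors; in practice rule 1/rule 3 catch most of these, and the
  condensation step absorbs the rest into host-matching representatives.
* The exhaustive scan is quadratic in transcriptome size × guide count;
  it is vectorized per transcript and fast at the tens-of-megabase scale,
  but no seed-index shortcut is implemented.
* `peak_window` defaults to 0 (exact cut-position match); degradome
  libraries with imprecise 5′ ends may need ±1.
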