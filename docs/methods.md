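# Methods

## Scope and data model

All coordinates are 0-based half-open (BED convention). A peak is a
`GenomicInterval`; a dataset is a `PeakSet`; overlap queries run on
per-chromosome interval trees. Gene models are single-isoform refFlat-like
records (gene id, chrom, strand, tx/cds bounds, exon list); TSS is the
transcription start in gene orientation, and all windows around it are
strand-aware. Midpoints of even-length intervals take the lower median
(floor), so every point rule is deterministic.

## Consensus peaks from replicates

Candidate regions are the union-merge of all replicate peaks. A replicate
supports a candidate when it contains a peak whose overlap with the
candidate covers at least `share_frac` (default 0.5) of the *peak*; since
candidates are unions of the replicate peaks, each peak is wholly contained
in one candidate and the effective criterion is "the replicate contributed a
peak". Candidates reaching the quorum are the consensus. Quorums default to
half the replicates rounded up per dataset (4/8 focal TF, 2/3 open
chromatin, 3/5 H3K27Ac, 2/3 Isl1, 2/2 Brn3a). Directionality of overlap
fractions is explicit (`overlap_fraction(a, b)` = fraction of `a` covered)
because the common command-line tools' `-f/-F` flags are directional and
callers must say which side a threshold applies to.

Artefact filtering removes peaks whose *summed* repeat-element coverage
exceeds 60% of the peak (strict inequality: exactly 60% is kept), and any
peak overlapping a blacklist interval by one or more bases. Blacklist
removal is deliberately stricter than the repeat rule: blacklist regions
mark systematic signal artefacts.

An open design point: whether replicate support should be scored against an
anchor replicate or the union. The union was chosen because it is symmetric
in the replicates and independent of replicate ordering. Consensus with
quorum q+1 is always a subset (base-wise) of consensus with quorum q.

## Motif scanning

IUPAC patterns expand to their concrete words; with both strands requested
the reverse complements are unioned in (set semantics deduplicate
palindromes). The RUNX consensus RCCRCA yields exactly 8 words. Scanning
counts every start position whose window matches any word of the set —
overlapping occurrences all count, palindromic double-hits count once, and
windows containing non-ACGT letters never match. A peak is motif-bearing
(`TF_TFBS`) iff its count is ≥ 1, so the overlap-counting choice cannot
change downstream classes. The scanner is vectorised (per-word boolean
conjunction over shifted encoded arrays); tests hold it equal to a
regular-expression lookahead oracle on random sequences.

The Brn3a/Isl1 patterns shipped in `PipelineConfig` (`ATAATTAA`, `CTAATGG`)
are synthetic placeholder consensi for the POU- and LIM-homeodomain AT-rich
cores, used by the synthetic study only; real analyses must supply their own
library definitions.

## Peak classification

Location is decided by the peak midpoint with precedence
promoter > UTR > coding exon > intron > intergenic; promoter windows default
to TSS ± 1 kb. The midpoint rule gives each peak exactly one label, which
the summary fractions require; the promoter window size is exposed because
published annotations of the same data differ between ±1 kb variants.

Chromatin states are computed after width normalisation — TF and H3K27Ac
peaks resized to 300 bp around their midpoint, ATAC to 500 bp (clamping at
chromosome ends shortens, never shifts) — with ≥1 bp overlap and no
fractional threshold. K27-only is representable even where reports collapse
it into "none".

Co-occupancy classifies the union-merge of the three TF_TFBS sets: each
merged region receives the subset of TFs contributing ≥1 peak, mapped to
categories {focal}=1, {B}=2, {I}=3, {focal,B}=4, {focal,I}=5, {B,I}=6,
{focal,B,I}=7. Chaining is transitive: if A overlaps B and B overlaps C, all
three share one region even when A and C do not touch. This is deterministic
and order-independent; the alternative (pairwise anchor logic) was rejected
as order-dependent. Under projection (removing one TF and re-running), a
region without bridging peaks maps 5→1, 6→2, 7→4; bridged chains may split.

## Gene association

Closest-TSS assignment minimises |peak midpoint − TSS| with ties broken by
lexicographically smallest gene id; distances are signed (negative =
upstream in gene orientation). Regulatory domains follow the
basal-plus-extension rule: basal = TSS −5 kb/+1 kb (strand-aware); each side
extends to the nearest other gene's basal boundary, capped at 1 Mb from the
TSS and the chromosome edge, and never shrinks below the basal. Extensions
of neighbouring genes may overlap (both reach the other's basal), so a
midpoint between two genes is often assigned to both — this matches the
published description of the domain tool; the curated-domain refinements of
that tool are not reproduced. Genes group as P-only / I-only / P-I by the
coarse locations (promoter vs intron/intergenic) of their associated peaks;
genes whose peaks are all exonic/UTR are reported separately.

## Target calling

DEG filtering keeps |linear fold change| ≥ 1.8 (inclusive; a 1e-12 slack on
the log2 threshold keeps the boundary inclusive after log round-trip) and
padj < 0.05 (strict). The strict preset (2.0 / FDR 0.05) is a parameter
choice away.

The eligible region of a gene is the union of its promoter window, introns,
5'/3' UTRs and the two flanking intergenic intervals reaching the nearest
neighbouring gene's transcription span (chromosome edge when none). Coding
exons are excluded, following the enumerated definition ("promoter, introns,
5'-UTR, or 3'-UTR"); `include_cds_exons` restores them for laxer screening.
A DEG is an RBS-evidence HCT iff ≥1 motif-bearing focal-TF peak midpoint
falls in its eligible region; among the remaining DEGs, those with a
motif-lacking focal-TF peak there form the noRBS-evidence list (the two
lists are disjoint by construction). The manual genome-browser screening
step of the original workflow is formalised as exactly this rule — no
discretionary inclusion — trading curation for reproducibility.

### Contingency statistics

For a 2×2 table [[a,b],[c,d]] with margins r1,r2,c1,c2 and N = a+b+c+d:
χ² = N(ad−bc)²/(r1 r2 c1 c2); the Yates correction replaces |ad−bc| with
max(0, |ad−bc| − N/2). Fisher's exact p is two-sided by the
probability-mass method (sum of hypergeometric probabilities ≤ the observed
table's). With a zero margin the chi-squares are undefined (reported as
such); Fisher is always computed. Note: applying the Yates formula to the
published down/up target split (86/150 vs 158/475) gives 26.75 (plain
27.75), not the 22.0461 printed alongside those counts in the source
experiment's report; the implementation follows the standard formula and
the tests pin the computed value.

### Clustering and signal comparison

Target genes of one direction are encoded as binary rows over the 7
categories and clustered by k-means (k-means++ init, Euclidean distance,
best of 10 restarts, fixed seed; k=4 up-regulated, k=2 down-regulated as in
the emulated analysis). The upstream analysis's clustering tool does not
document its seeding, so cluster *numbering* is not reproducible; labels are
therefore renumbered by descending cluster size, and only cluster-content
properties are asserted. The two-sample KS statistic is the exact ECDF
supremum over the pooled points; its p-value uses the asymptotic Kolmogorov
distribution with effective size nm/(n+m). Signal comparisons run on linear
(non-log) values.

## Synthetic data generator

The generator emulates the *statistical* structure of the emulated
experiment, not its sequences: uniform random genome, non-overlapping
single-isoform genes packed with random spacing, planted binding sites,
replicate peak sets (per-replicate Bernoulli detection, rounded-Gaussian
centre jitter, Poisson false peaks placed off-site), chromatin co-marking
drawn per site class, and a DEG table with planted targets. One global seed
spawns per-component child seeds (all < 2^31); every output is
bit-reproducible.

Key defaults, chosen once to mirror the emulated study's densities at
roughly 1/40 genomic scale (12 Mb, 600 genes):

| parameter | default | rationale |
|---|---|---|
| rbs_fraction | 0.71 | published motif-bearing fraction of focal peaks |
| partner motif fraction | 0.72 | published Brn3a/Isl1 fractions (72.1/71.4%) |
| detect_prob | 0.8 | modelling choice; no published replicate concordance |
| jitter_sd | 20 bp | typical summit variation between replicates |
| fp_rate | 0.5 /Mb/rep | sparse irreproducible peaks (quorum removes them) |
| background focal sites | 250 (+92 target, +20 decoy) | ≈0.4 motif peaks/gene as published |
| promoter-resident fraction | 0.35 | published ~38% promoter share |
| co-binding (B given focal, I given B) | 0.30 / 0.57 | published pairwise overlap fractions |
| co-marking per class | promoter 90/8/2, distal 35/26/4/35 | published state distributions |
| planted targets | 80 RBS + 12 noRBS (down:up ≈ 35:65) | published 244+37 at ~1/3, direction split 86:158 |
| extra DEGs | 18 down + 98 up | published 150/475 DEG split at ~1/3 scale |

Motif planting writes one concrete word (uniform over the strand-unioned
expansion) at a uniform position in each chosen site. Sites *not* chosen are
actively scrubbed of chance occurrences, including a 150 bp flank, so that
site-level truth flags and sequence scans agree even after replicate jitter
widens consensus peaks; previously planted words of other factors are
protected from scrubbing and overwriting at co-bound sites. This is a
deliberate departure from leaving background sequence untouched: with a
6-mer set of 8 words, a ~200 bp uniform site would contain a chance hit
~30% of the time, making planted "motif-free" sites meaningless.

What the generator does **not** model: reads, fragment sizes, duplication,
mappability, GC composition, multi-isoform genes, overlapping genes, and
signal-dependent detection. Passing recovery tests therefore demonstrate
correctness of the interval/motif/association logic under the stated noise
model, not performance on real libraries.

## Problem sizes and determinism

The default study is 12 Mb / 600 genes (~2 s to generate, ~1 s to analyse);
recovery measurements use 6 Mb / 300 genes with 200 planted targets across
multiple seeds; consensus recall uses 600 planted sites against the
binomial tail P(Bin(8, 0.9) ≥ 4). These sizes give Monte-Carlo standard
errors small enough for the three-sigma test bands while keeping the whole
suite inside a coffee break. All randomness flows from explicit seeds;
k-means restarts, replicate noise and table generation are reproducible
bit-for-bit.

## Known limitations

- Consensus support is binary per replicate; no reproducibility scoring
  (IDR) or summit estimation.
- One gene model per gene id; the generator emits one isoform per gene.
- The KS p-value is asymptotic; for very small samples it is conservative
  rather than exact.
- The noRBS secondary list inherits every ambiguity of the eligible-region
  rule: in dense gene neighbourhoods a DEG may be claimed by a background
  peak of another gene's territory, which is the method's definition rather
  than a defect, but users should read the planted-truth precision numbers
  with that in mind.
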