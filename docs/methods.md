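# Methods

## Problem setting

A low-input CLIP-style assay (LACE-seq) reads out where an RNA-binding
protein sits on the transcriptome of a scarce cell population. Because
input is tiny, the raw IP library is dominated by background; the
analysis therefore leans on two negative controls measured alongside —
an IgG immunoprecipitation and the same IP in a knockout that lacks the
protein. Everything downstream (feature preference, motif, coupling to
translation efficiency, poly(A) tails, and protein output) is computed
from the control-filtered binding sites.

## Transcript model

Coordinates are 0-based half-open internally; GTF (1-based closed) is
converted at parse. Each gene is collapsed to one canonical transcript —
the longest spliced isoform, ties broken by lexicographically smallest
transcript id — and all gene-level statistics use it. Transcript
coordinates run 5'→3', so offset 0 of a minus-strand transcript is its
genomically rightmost exonic base; the partition 5'UTR + CDS + 3'UTR is
derived from the CDS span and asserted to cover the spliced length.
CDS records are taken to include the stop codon, so the stop-codon
anchor used by metagene windows is the first base of the final codon.
Non-coding transcripts enter peak annotation as a single
"non-coding exonic" category and are skipped by codon-anchored
profiles. Repeat intervals are strand-agnostic and merged at load.

## Crosslink signal and peak calling

Each aligned read contributes one count at its 5'-most aligned base
(start on +, end−1 on −): reverse transcription in the assay stops at
the crosslink, so the read start is signal-proximal. Candidate peaks per
canonical transcript come from a `window` = 50 nt sliding window; a
window passes if it holds ≥ `min_reads` = 5 read ends and beats the
transcript's own uniform rate (Poisson upper tail, p < 0.01 — the
per-transcript background makes highly expressed transcripts their own
null). Passing windows within `merge_distance` = 10 nt are merged and
each merged region is trimmed to its covered read extent, so point
sources yield compact sites; the summit is the position of the maximum
single-position count (5'-most on ties). Peaks called on overlapping
genes are de-duplicated toward the transcript holding more reads.

The false-positive filter follows the fivefold rule: a peak survives iff
RPM_IP / RPM_control ≥ `fold` = 5 for *every* control, where both
densities get a +1-read pseudocount before per-million scaling. The
filter is anti-monotone in `fold` by construction. A practical note on
its calibration: when candidate peaks are noise fluctuations in a sparse
library, the control's expected count in the same window is small, and
the pseudocount ratio lets a minority of them through; against a
depth-matched background control the filter removes the large majority
of noise windows but not literally all of them. The test suite asserts
the guarantee the pipeline actually relies on (most noise candidates
removed, planted sites retained).

Replicates are pooled after a correlation gate: Pearson r of per-gene
log2(RPM+1) densities over genes with signal in at least one library
(default minimum r = 0.5; pooling proceeds with a warning if missed).
Gene-level binding density is peak-overlapping IP reads per kb of
canonical transcript per million mapped reads; genes without peaks are
absent, not zero.

## Site categories and metagene profiles

A peak is classified by its center position ((start+end)//2) with
precedence repeat > exonic feature > intron > intergenic — a
deterministic, tie-free rule for sites spanning junctions. Category
fractions always sum to one and a combined-UTR figure (5'+3') is
reported alongside.

Gene-body profiles bin each transcript's exonic RPM into 100 scaled
bins as per-nt densities and normalise each transcript's profile to
mean 1 before averaging, so deeply covered genes do not dominate;
uniform coverage yields an exactly flat profile. Anchored profiles
average raw RPM at single-nt offsets within ±100 nt of the anchor
(TSS, TTS, start codon, stop codon, or annotated 3' end standing in for
the poly(A) site — no poly(A)-site calling is attempted); transcripts
whose window does not fit are skipped and counted.

## Hexamer statistics

Observed counts are overlapping occurrences summed over peak sequences
(T/U equivalent at ingest). The null preserves each sequence's exact
dinucleotide counts via the Altschul–Erickson Euler-walk shuffle
(random last-edge arborescence into the terminal character, remaining
edges permuted), re-counted per iteration; 100 shuffles by default,
seeded. z = (observed − null mean) / max(null sd, 0.5); the sd floor
keeps z finite for hexamers the shuffles never produce. The table sorts
by z, ties broken lexicographically, and is deterministic given a seed.

The consensus matrix aligns each of the top-k (default 20) hexamers
ungapped to the rank-1 hexamer at the offset in {−2..+2} maximising
matches (ties prefer offset 0, then smaller magnitude, then the
positive offset); base frequencies are accumulated with z-weights
clipped at zero and columns normalised. "GC-rich" motifs are the top-20
hexamers with GC fraction ≥ 5/6 (configurable). Positional profiles
bin motif occurrence positions into scaled gene-body bins, each
transcript normalised to unit mass.

## Integration statistics

Targets are genes with ≥ 1 filtered peak. TE is RPKM(RPF)/RPKM(mRNA)
over the canonical transcript, with genes below 1 RPKM mRNA density
excluded. Quartile associations rank genes ascending by the
conditioning variable (ties broken by gene id), split into four groups
whose sizes differ by ≤ 1 with the remainder assigned to lower
quartiles, and compare response distributions between adjacent groups
and Q1 vs Q4.

The shared two-tailed Wilcoxon rank-sum machinery is exact whenever
both samples have ≤ 10 observations: the full rank-sum distribution
over all group assignments is computed by dynamic programming on
doubled mid-ranks, which handles ties exactly as well. The choice is
deliberate — the normal approximation's error at n = 8 is ~0.02, too
coarse for small-group comparisons — and larger samples use the
asymptotic test with tie and continuity correction (within 0.01 of
enumeration just above the cutover). No multiple-testing correction is
applied to the pairwise quartile p-values (raw p reported,
configurable). Proteomics differential calls use Welch's
unequal-variance t-test on log2 replicate intensities, two valid
replicates per condition required, direction by the sign of the mean
difference.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes
and is the ground truth for every test. Defaults (the standard study
conditions): 1000 genes on one synthetic chromosome, alternating
strands, 1–3 exons each, intergenic spacers of 300–1000 nt; UTR/CDS
lengths log-normal (medians ≈ 150 / 900 / 400 nt, CDS a multiple of 3);
uniform base composition; a repeat track covering 5% of the genome;
30% target genes with GCGCGC planted once at a uniform random 5'UTR
offset (5'UTRs of targets floored at twice the motif length); two IP
replicates of 100k reads and IgG/knockout controls of 100k reads each.
IP reads are signal with probability 0.7 — target chosen proportional
to a log-normal abundance weight, position normal around the motif
offset with sd 8 nt (chosen so mean site lengths land near the
~50-nt scale reported for this assay class), clipped to the transcript —
and uniform background otherwise; controls are background-only;
replicates differ only by random stream. Measurements couple to the
true binding weight B: log TE = a + b·log1p(B) + N(0, 0.3) with
b = 0.5; RPF/mRNA count tables are Poisson samples consistent with the
planted TE; poly(A) tail = 60 + 80·(binding rank percentile) + N(0, 15),
floored at 10 nt; proteomics replicates (3 per condition, sd 0.3) are
Gaussian around per-gene baselines with target means shifted −1 log2
unit in the knockout. Per-stage random streams derive from the single
seed, so regeneration is byte-identical and toggling one stage cannot
perturb another's randomness.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: sequencing error, PCR duplication and
UMI structure, isoform diversity (one transcript per gene), non-uniform
background (real IgG libraries have structure), crosslinking sequence
bias, and overdispersion beyond Poisson in the count tables.

## Problem sizes and numerical choices

The default dataset (1000 genes, 400k reads total) runs end to end in
well under a minute; the test suite uses 80–200-gene configurations for
module tests and the full default for end-to-end recovery checks. Null
calibration uses 20 seeded replicates at 400 genes with the TE and
proteomics couplings zeroed, expecting rejections at the nominal 5%
within binomial slack. Degenerate inputs are defined errors: empty peak
lists, empty motif sets, zero-read control libraries, < 8 genes for
quartiles, < 3 proteins per group, and all-short motif sequences all
raise with explicit messages rather than returning NaN.

## Known limitations

- The peak-caller parameters are declared defaults, not a reimplementation
  of any published caller; absolute site counts depend on them.
- The fivefold filter's density ratio (rather than a count ratio) and the
  +1 pseudocount are declared choices; both affect borderline sparse peaks.
- Whether published combined-UTR percentages split 5' vs 3' as here is
  not derivable from category fractions alone; both are reported.
- Hexamer z-scores depend on the shuffle null; values are comparable
  within a run, not across background models.
- The poly(A) anchor is the annotated transcript 3' end; no tail-length
  estimation or poly(A)-site calling is performed.
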