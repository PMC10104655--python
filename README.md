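# lacebind

Binding-landscape analysis for low-input CLIP-style (LACE-seq) data on
RNA-binding proteins, built for settings — such as mouse oocytes — where
an IP library must be cleaned against IgG and knockout control libraries
before any downstream claim is made. The package takes aligned-read
positions per library, a transcript annotation, and optional
transcript sequences and multi-omic tables, and produces:

1. **Background-filtered binding sites.** Read 5' ends (the
   reverse-transcription stop adjacent to the protein-RNA crosslink) are
   piled up per strand; candidate peaks come from a 50-nt sliding window
   per canonical transcript tested against the transcript's own uniform
   background (Poisson upper tail, p < 0.01); a candidate is kept only if
   its reads-per-million density is at least fivefold above *every*
   control library (pseudocount +1 read, so the enrichment ratio is
   always finite).
2. **Feature annotation and metagene profiles.** Each site is assigned
   one category by its center (repeat > 5'UTR/CDS/3'UTR/non-coding exon >
   intron > intergenic), and coverage is averaged over transcripts in
   scaled gene-body bins or fixed windows anchored at the TSS, TTS,
   start/stop codon, or annotated poly(A) site.
3. **Hexamer motif statistics.** For each of the 4096 hexamers h the
   z-score is z(h) = (obs(h) − mean_null(h)) / max(sd_null(h), 0.5), where
   the null re-counts per-sequence dinucleotide-preserving shuffles
   (Altschul–Erickson Euler-walk); consensus matrices, GC-rich motif
   sets, motif-containing-peak fractions, and positional profiles follow.
4. **Multi-omic integration.** Target sets and Venn overlaps; translation
   efficiency TE = RPKM(RPF)/RPKM(mRNA); quartile associations (genes
   ranked by a conditioning variable, split Q1–Q4, compared with the
   two-tailed Wilcoxon rank-sum test — exact, tie-aware, for samples of
   ≤ 10); bound-vs-unbound protein fold-change shifts; per-protein
   Welch t-tests on replicate intensities.
5. **A ground-truth synthetic generator** producing the full input set —
   GTF, genome/transcript FASTA, per-library BED6 reads, TE/poly(A)/
   proteomics tables — with a GC-rich hexamer planted in target 5'UTRs
   and measurements coupled to the true binding weights, so every stage
   can be validated against known truth.

## Worked example

The `examples/` directory holds one short script per capability. On a
200-gene synthetic dataset (60 planted targets, motif GCGCGC, seed 7),
`examples/02_peaks_and_filtering.py` prints:

```
replicate correlation (log2 RPM+1, per gene): r = 0.983
candidate peaks: 138; after fivefold control filter: 60
derived targets: 60  precision 1.00, recall 1.00
```

— the control filter removed the 78 background windows and kept one site
per planted target. `examples/04_motif_enrichment.py` then recovers the
planted motif from the peak sequences alone:

```
top five hexamers by z-score:
hexamer  observed  null_mean         z
 GCGCGC        69       5.47 26.134740
 CGCGCG        29       5.46 12.223995
 ...
peaks containing a GC-rich hexamer: 100.0%
```

and `examples/05_multiomic_integration.py` shows the planted couplings:
TE medians rise across binding-density quartiles (Q1 1.159 → Q4 1.815,
Wilcoxon p = 6.2e-3) and bound genes shift down at the protein level
(median log2FC −0.94 vs −0.01, p = 5.1e-29).

A thin CLI wraps the same library:

```bash
lacebind simulate --out data/ --n-genes 1000 --seed 42
lacebind run --dataset data/ --out results/ --fold 5
lacebind metagene --dataset data/ --mode anchored --anchor start_codon --out prof.tsv
```

## Layout

```
src/lacebind/
  transcriptome.py   GTF/FASTA loading, strand-aware coordinate mapping
  signal.py          pileup, peak calling, control filter, densities
  annotate.py        site categories, metagene profiles
  motifs.py          hexamer z-scores, shuffles, consensus, profiles
  integrate.py       target sets, Venn, TE, Wilcoxon, proteomics
  simulate.py        ground-truth synthetic data generator
  pipeline.py        end-to-end orchestration with a JSON run report
  cli.py             thin click CLI (`lacebind`)
docs/methods.md      model, assumptions, parameter choices, limitations
examples/            one narrative script per capability
```
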