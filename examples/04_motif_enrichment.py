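"""Hexamer over-representation at binding sites.

Observed hexamer counts across the peak sequences are compared with a
null from per-sequence dinucleotide-preserving shuffles; the z-score is
the standardised excess. The top hexamers are aligned into a consensus
matrix, and the fraction of peaks containing a GC-rich (or any top-20)
hexamer is reported.
"""

import lacebind as lb
from lacebind.motifs import gc_rich_motifs, top_motifs
from lacebind.signal import merge_coverages

truth = lb.generate_truth(lb.SyntheticConfig(
    n_genes=200, seed=7,
    depths={"ip_rep1": 30_000, "ip_rep2": 30_000, "igg": 15_000, "cko": 15_000},
))
libs = lb.simulate_reads(truth)
cov = {lib: lb.pileup_read_ends(df, lib) for lib, df in libs.items()}
ip = merge_coverages([cov["ip_rep1"], cov["ip_rep2"]], "ip_pooled")
peaks = lb.filter_peaks_by_controls(
    lb.call_candidate_peaks(ip, truth.annotation), ip, [cov["igg"], cov["cko"]]
)

seqs = lb.peak_sequences(peaks, truth.annotation)
table = lb.hexamer_zscores(seqs, n_shuffles=100, seed=7)
print("top five hexamers by z-score:")
print(table.top(5)[["hexamer", "observed", "null_mean", "z"]].to_string(index=False))

consensus = lb.consensus_from_top_hexamers(table, k=20)
print(f"consensus from top 20 hexamers: {consensus.consensus}")

gc = gc_rich_motifs(table)
print(f"peaks containing a GC-rich hexamer: "
      f"{100 * lb.motif_peak_fraction(seqs, gc):.1f}%")
print(f"peaks containing any top-20 hexamer: "
      f"{100 * lb.motif_peak_fraction(seqs, top_motifs(table)):.1f}%")

profile = lb.motif_positional_profile(gc, truth.annotation, n_bins=10)
print(f"motif density by gene-body decile: "
      f"{[round(float(b), 3) for b in profile.bins]}")
# The planted GCGCGC tops the table and its occurrences concentrate in
# the first deciles, i.e. the 5'UTR.
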