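"""Feature categories of binding sites and metagene profiles.

Each filtered peak is assigned one category by its center position
(repeat > 5UTR/CDS/3UTR/noncoding exon > intron > intergenic), and the
pooled IP coverage is averaged across transcripts in 100 scaled
gene-body bins plus fixed windows around the start codon.
"""

import numpy as np

import lacebind as lb
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

annotated = lb.annotate_peaks(peaks, truth.annotation)
dist = lb.category_distribution(annotated)
for cat, frac in sorted(dist.fractions.items(), key=lambda kv: -kv[1]):
    if frac:
        print(f"{cat:>15s}: {100 * frac:5.1f}%")
print(f"combined UTR fraction: {100 * dist.utr_fraction:.1f}%")

body = lb.metaprofile(ip, truth.annotation, mode="gene_body", n_bins=100)
print(f"gene-body profile over {body.n_transcripts} transcripts; "
      f"peak bin = {int(np.argmax(body.bins))} (5' end = bin 0)")

start = lb.metaprofile(ip, truth.annotation, mode="anchored", anchor="start_codon")
offset = int(np.argmax(start.bins)) - 100
print(f"start-codon window maximal at offset {offset} nt")
# Signal planted in 5'UTRs shows up as an early gene-body peak and
# density concentrated upstream of the start codon.
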