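"""Self-contained synthetic dataset with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a single-chromosome transcriptome with alternating strands and
intergenic spacers; a subset of target genes carrying a GC-rich hexamer
planted in their 5'UTR; an IP library whose signal reads concentrate
around the planted motif positions (with two replicates differing only
by random stream) while IgG and knockout control libraries contain
background only; and measurement tables in which translation efficiency,
poly(A) tail length and protein fold change are coupled to the true
binding weight of each target.

Everything is a deterministic function of the seed: per-stage random
streams are derived from it, so regenerating with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .integrate import TargetSet
from .transcriptome import (
    GenomicInterval,
    Transcript,
    TranscriptomeAnnotation,
    reverse_complement,
    write_gtf,
)

CHROM = "chrS"
BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n_genes: int = 1000
    seed: int = 42
    target_fraction: float = 0.3
    motif: str = "GCGCGC"
    motifs_per_target: int = 1

    # transcript architecture (log-normal length parameters, nt)
    utr5_log_mean: float = float(np.log(150))
    utr5_log_sd: float = 0.35
    cds_log_mean: float = float(np.log(900))
    cds_log_sd: float = 0.4
    utr3_log_mean: float = float(np.log(400))
    utr3_log_sd: float = 0.5
    base_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    max_exons: int = 3
    intron_log_mean: float = float(np.log(200))
    intron_log_sd: float = 0.5
    spacer_min: int = 300
    spacer_max: int = 1000
    repeat_fraction: float = 0.05
    repeat_length: int = 200

    # read libraries
    depths: Dict[str, int] = field(
        default_factory=lambda: {
            "ip_rep1": 100_000,
            "ip_rep2": 100_000,
            "igg": 100_000,
            "cko": 100_000,
        }
    )
    signal_fraction: float = 0.7
    positional_sd: float = 8.0
    read_length: int = 30
    abundance_log_sd: float = 0.5

    # measurement couplings
    te_a: float = 0.0
    te_b: float = 0.5
    te_sd: float = 0.3
    rna_log_mean: float = float(np.log(50))
    rna_log_sd: float = 1.0
    polya_base: float = 60.0
    polya_slope: float = 80.0
    polya_sd: float = 15.0
    polya_floor: float = 10.0
    prot_replicates: int = 3
    prot_baseline_mean: float = 20.0
    prot_baseline_sd: float = 2.0
    prot_rep_sd: float = 0.3
    prot_delta: float = 1.0

    def validate(self) -> None:
        for name in ("target_fraction", "signal_fraction", "repeat_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if any(d < 0 for d in self.depths.values()):
            raise ValueError("library depths must be >= 0")
        if abs(sum(self.base_probs) - 1) > 1e-9:
            raise ValueError("base_probs must sum to 1")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent per-stage random stream derived from the global seed."""
    return np.random.default_rng([seed, *key])


@dataclass
class SyntheticTruth:
    annotation: TranscriptomeAnnotation
    target_genes: TargetSet
    motif_positions: Dict[str, List[int]]  # gene -> transcript offsets (5'UTR)
    abundance: Dict[str, float]  # per-target binding weight, 0 for non-targets
    genome_seq: str
    config: SyntheticConfig


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Sample gene structures, sequences, targets and planted motif positions."""
    config.validate()
    rng = _stream(config.seed, 0)
    n = config.n_genes
    motif = config.motif.upper().replace("U", "T")

    n_targets = int(round(config.target_fraction * n))
    target_idx = set(
        rng.choice(n, size=n_targets, replace=False).tolist() if n_targets else []
    )

    transcripts: Dict[str, Transcript] = {}
    gene_to_canonical: Dict[str, str] = {}
    sequences: Dict[str, str] = {}
    motif_positions: Dict[str, List[int]] = {}
    abundance: Dict[str, float] = {}
    genome_parts: List[str] = []
    cursor = 0
    base_probs = np.asarray(config.base_probs)

    for i in range(n):
        gene_id, tid = f"G{i:04d}", f"T{i:04d}"
        is_target = i in target_idx

        utr5 = max(20, int(round(rng.lognormal(config.utr5_log_mean, config.utr5_log_sd))))
        if is_target and utr5 < 2 * len(motif):
            utr5 = 2 * len(motif)
        cds = max(60, int(round(rng.lognormal(config.cds_log_mean, config.cds_log_sd))))
        cds -= cds % 3
        utr3 = max(20, int(round(rng.lognormal(config.utr3_log_mean, config.utr3_log_sd))))
        L = utr5 + cds + utr3

        seq = rng.choice(BASES, size=L, p=base_probs)
        if is_target:
            offsets = sorted(
                int(o)
                for o in rng.integers(0, utr5 - len(motif) + 1, config.motifs_per_target)
            )
            for off in offsets:
                seq[off : off + len(motif)] = list(motif)
            motif_positions[gene_id] = offsets
            abundance[gene_id] = float(rng.lognormal(0.0, config.abundance_log_sd))
        else:
            abundance[gene_id] = 0.0
        tx_seq = "".join(seq)

        n_exons = int(rng.integers(1, config.max_exons + 1))
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, L), size=n_exons - 1, replace=False))
        else:
            cuts = np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), L]
        introns = [
            max(50, int(round(rng.lognormal(config.intron_log_mean, config.intron_log_sd))))
            for _ in range(n_exons - 1)
        ]

        # oriented locus: exon/intron blocks in transcript order
        strand = "+" if i % 2 == 0 else "-"
        oriented_parts: List[str] = []
        exon_oriented: List[Tuple[int, int]] = []
        opos = 0
        for j in range(n_exons):
            a, b = bounds[j], bounds[j + 1]
            oriented_parts.append(tx_seq[a:b])
            exon_oriented.append((opos, opos + (b - a)))
            opos += b - a
            if j < n_exons - 1:
                ilen = introns[j]
                oriented_parts.append(
                    "".join(rng.choice(BASES, size=ilen, p=base_probs))
                )
                opos += ilen
        locus_len = opos
        oriented_seq = "".join(oriented_parts)

        spacer_len = int(rng.integers(config.spacer_min, config.spacer_max + 1))
        genome_parts.append("".join(rng.choice(BASES, size=spacer_len, p=base_probs)))
        cursor += spacer_len

        if strand == "+":
            genome_parts.append(oriented_seq)
            exons = [
                GenomicInterval(CHROM, cursor + a, cursor + b, strand)
                for a, b in exon_oriented
            ]
        else:
            genome_parts.append(reverse_complement(oriented_seq))
            exons = [
                GenomicInterval(
                    CHROM, cursor + locus_len - b, cursor + locus_len - a, strand
                )
                for a, b in exon_oriented
            ]
        cursor += locus_len

        t = Transcript(tid, gene_id, exons)
        g1 = t.transcript_to_genome(utr5)
        g2 = t.transcript_to_genome(utr5 + cds - 1)
        cds_span = (min(g1, g2), max(g1, g2) + 1)
        transcripts[tid] = Transcript(tid, gene_id, exons, cds_span)
        gene_to_canonical[gene_id] = tid
        sequences[tid] = tx_seq

    genome_parts.append(
        "".join(rng.choice(BASES, size=500, p=base_probs)) if n else ""
    )
    cursor += 500 if n else 0
    genome_seq = "".join(genome_parts)

    repeats: List[GenomicInterval] = []
    if n and config.repeat_fraction > 0:
        n_repeats = int(cursor * config.repeat_fraction / config.repeat_length)
        starts = rng.integers(0, max(1, cursor - config.repeat_length), n_repeats)
        repeats = [
            GenomicInterval(CHROM, int(s), int(s) + config.repeat_length, "+")
            for s in sorted(starts.tolist())
        ]

    annotation = TranscriptomeAnnotation(
        transcripts=transcripts,
        gene_to_canonical=gene_to_canonical,
        repeats=repeats,
        sequences=sequences,
    )
    return SyntheticTruth(
        annotation=annotation,
        target_genes=TargetSet("true_targets", frozenset(motif_positions)),
        motif_positions=motif_positions,
        abundance=abundance,
        genome_seq=genome_seq,
        config=config,
    )


def simulate_reads(truth: SyntheticTruth, config: Optional[SyntheticConfig] = None) -> Dict[str, pd.DataFrame]:
    """Simulate BED6 read alignments per library.

    IP reads mix a motif-centred signal component (gene chosen in
    proportion to its abundance weight, position normal around a planted
    motif offset) with a uniform background; IgG and knockout libraries
    are background only. Replicates share parameters and differ only by
    random stream.
    """
    config = config or truth.config
    ann = truth.annotation
    genes = sorted(ann.gene_to_canonical)
    tx = [ann.canonical(g) for g in genes]
    lengths = np.array([t.spliced_length for t in tx])
    target_list = sorted(truth.target_genes.genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    if target_list:
        w = np.array([truth.abundance[g] for g in target_list])
        w = w / w.sum()
    genome_len = len(truth.genome_seq)

    libraries: Dict[str, pd.DataFrame] = {}
    for lib_no, (lib, depth) in enumerate(sorted(config.depths.items())):
        rng = _stream(config.seed, 1, lib_no)
        if depth == 0:
            libraries[lib] = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
            continue
        is_ip = lib.startswith("ip")
        n_signal = (
            rng.binomial(depth, config.signal_fraction)
            if is_ip and target_list
            else 0
        )
        n_bg = depth - n_signal

        gene_ids = np.empty(depth, dtype=np.int64)
        tx_pos = np.empty(depth, dtype=np.int64)
        if n_signal:
            sig_targets = rng.choice(len(target_list), size=n_signal, p=w)
            for k in range(n_signal):
                g = target_list[sig_targets[k]]
                offs = truth.motif_positions[g]
                off = offs[rng.integers(len(offs))] if len(offs) > 1 else offs[0]
                gi = gene_index[g]
                pos = int(round(rng.normal(off, config.positional_sd)))
                gene_ids[k] = gi
                tx_pos[k] = min(max(pos, 0), lengths[gi] - 1)
        if n_bg:
            bg_genes = rng.integers(0, len(genes), n_bg)
            u = rng.random(n_bg)
            gene_ids[n_signal:] = bg_genes
            tx_pos[n_signal:] = (u * lengths[bg_genes]).astype(np.int64)

        # map transcript positions to genomic 5' ends, grouped per gene
        gpos = np.empty(depth, dtype=np.int64)
        strands = np.empty(depth, dtype="<U1")
        for gi in np.unique(gene_ids):
            mask = gene_ids == gi
            gpos[mask] = tx[gi].transcript_to_genome_array(tx_pos[mask])
            strands[mask] = tx[gi].strand

        plus = strands == "+"
        starts = np.where(plus, gpos, np.maximum(0, gpos + 1 - config.read_length))
        ends = np.where(plus, np.minimum(genome_len, gpos + config.read_length), gpos + 1)
        libraries[lib] = pd.DataFrame(
            {
                "chrom": CHROM,
                "start": starts,
                "end": ends,
                "name": [f"{lib}_r{j}" for j in range(depth)],
                "score": 0,
                "strand": strands,
            }
        )
    return libraries


@dataclass
class Measurements:
    te: pd.DataFrame  # gene_id, te_true
    rpf_counts: pd.Series
    rna_counts: pd.Series
    polya: pd.DataFrame  # gene_id, tail_length_nt
    proteomics: pd.DataFrame  # gene_id, wt_*/cko_* replicate log2 intensities, log2fc


def simulate_measurements(
    truth: SyntheticTruth, config: Optional[SyntheticConfig] = None
) -> Measurements:
    """Measurement tables coupled to the true binding weights.

    log TE is linear in log1p(binding weight) with Gaussian noise;
    poly(A) tail length is linear in the binding-rank percentile (floored);
    proteomics replicates are Gaussian around a per-gene baseline, with
    target means shifted down by ``prot_delta`` in the knockout condition.
    """
    config = config or truth.config
    rng = _stream(config.seed, 2)
    ann = truth.annotation
    genes = sorted(ann.gene_to_canonical)
    n = len(genes)
    kb = np.array([ann.canonical(g).spliced_length for g in genes]) / 1e3
    B = np.array([truth.abundance[g] for g in genes])

    log_te = config.te_a + config.te_b * np.log1p(B) + rng.normal(0, config.te_sd, n)
    te = np.exp(log_te)
    rna_rpkm = rng.lognormal(config.rna_log_mean, config.rna_log_sd, n)
    rna_counts = rng.poisson(rna_rpkm * kb).astype(float)
    rpf_counts = rng.poisson(te * rna_rpkm * kb).astype(float)

    pct = rankdata(B, method="average") / n
    tail = config.polya_base + config.polya_slope * pct + rng.normal(0, config.polya_sd, n)
    tail = np.maximum(tail, config.polya_floor)

    baseline = rng.normal(config.prot_baseline_mean, config.prot_baseline_sd, n)
    is_target = np.array([g in truth.target_genes.genes for g in genes])
    reps = config.prot_replicates
    prot = {"gene_id": genes}
    for r in range(reps):
        prot[f"wt_{r + 1}"] = baseline + rng.normal(0, config.prot_rep_sd, n)
    for r in range(reps):
        prot[f"cko_{r + 1}"] = (
            baseline
            - config.prot_delta * is_target
            + rng.normal(0, config.prot_rep_sd, n)
        )
    proteomics = pd.DataFrame(prot)
    wt_cols = [f"wt_{r + 1}" for r in range(reps)]
    ko_cols = [f"cko_{r + 1}" for r in range(reps)]
    proteomics["log2fc"] = proteomics[ko_cols].mean(axis=1) - proteomics[wt_cols].mean(axis=1)

    return Measurements(
        te=pd.DataFrame({"gene_id": genes, "te_true": te}),
        rpf_counts=pd.Series(rpf_counts, index=genes, name="count"),
        rna_counts=pd.Series(rna_counts, index=genes, name="count"),
        polya=pd.DataFrame({"gene_id": genes, "tail_length_nt": tail}),
        proteomics=proteomics,
    )


def write_dataset(
    truth: SyntheticTruth,
    libraries: Dict[str, pd.DataFrame],
    measurements: Measurements,
    outdir: str,
) -> Dict[str, str]:
    """Write the standard files the real pipeline consumes; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: Dict[str, str] = {}

    paths["gtf"] = os.path.join(outdir, "annotation.gtf")
    write_gtf(truth.annotation, paths["gtf"])

    paths["genome_fasta"] = os.path.join(outdir, "genome.fa")
    with open(paths["genome_fasta"], "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(truth.genome_seq), 80):
            fh.write(truth.genome_seq[i : i + 80] + "\n")

    paths["transcript_fasta"] = os.path.join(outdir, "transcripts.fa")
    with open(paths["transcript_fasta"], "w") as fh:
        for tid in sorted(truth.annotation.sequences):
            fh.write(f">{tid}\n{truth.annotation.sequences[tid]}\n")

    paths["repeats_bed"] = os.path.join(outdir, "repeats.bed")
    with open(paths["repeats_bed"], "w") as fh:
        for j, r in enumerate(truth.annotation.repeats):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\trep_{j}\t0\t+\n")

    for lib, df in libraries.items():
        paths[lib] = os.path.join(outdir, f"{lib}.bed")
        df.to_csv(paths[lib], sep="\t", header=False, index=False)

    paths["rpf_counts"] = os.path.join(outdir, "rpf_counts.tsv")
    measurements.rpf_counts.rename_axis("gene_id").to_csv(paths["rpf_counts"], sep="\t")
    paths["rna_counts"] = os.path.join(outdir, "rna_counts.tsv")
    measurements.rna_counts.rename_axis("gene_id").to_csv(paths["rna_counts"], sep="\t")
    paths["polya"] = os.path.join(outdir, "polya.tsv")
    measurements.polya.to_csv(paths["polya"], sep="\t", index=False)
    paths["proteomics"] = os.path.join(outdir, "proteomics.tsv")
    measurements.proteomics.to_csv(paths["proteomics"], sep="\t", index=False)

    paths["truth"] = os.path.join(outdir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "target_genes": sorted(truth.target_genes.genes),
                "motif_positions": truth.motif_positions,
                "abundance": truth.abundance,
                "config": dataclasses.asdict(truth.config),
            },
            fh,
            indent=1,
        )
    return paths
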