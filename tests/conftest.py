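import numpy as np
import pytest

import lacebind as lb
from lacebind.signal import merge_coverages
from lacebind.transcriptome import GenomicInterval, Transcript, TranscriptomeAnnotation


def make_annotation(transcripts, repeats=(), sequences=None):
    """Build an annotation from Transcript objects (one gene per transcript)."""
    tx = {t.transcript_id: t for t in transcripts}
    return TranscriptomeAnnotation(
        transcripts=tx,
        gene_to_canonical={t.gene_id: t.transcript_id for t in transcripts},
        repeats=list(repeats),
        sequences=dict(sequences or {}),
    )


def single_exon_transcript(
    tid="T1",
    gene="G1",
    chrom="chr1",
    start=0,
    length=1000,
    strand="+",
    cds=None,
):
    exons = [GenomicInterval(chrom, start, start + length, strand)]
    return Transcript(tid, gene, exons, cds)


@pytest.fixture
def toy_annotation():
    """Three single-exon genes on both strands, one with a CDS."""
    t1 = single_exon_transcript("T1", "G1", start=100, length=300, strand="+",
                                cds=(200, 320))
    t2 = single_exon_transcript("T2", "G2", start=1000, length=400, strand="-")
    t3 = single_exon_transcript("T3", "G3", start=2000, length=200, strand="+")
    return make_annotation([t1, t2, t3])


@pytest.fixture(scope="session")
def small_truth():
    cfg = lb.SyntheticConfig(
        n_genes=120,
        seed=1,
        depths={"ip_rep1": 20_000, "ip_rep2": 20_000, "igg": 10_000, "cko": 10_000},
    )
    return lb.generate_truth(cfg)


@pytest.fixture(scope="session")
def small_run(small_truth):
    """Pileups, peaks and target set on the small synthetic dataset."""
    libs = lb.simulate_reads(small_truth)
    cov = {lib: lb.pileup_read_ends(df, lib) for lib, df in libs.items()}
    ip = merge_coverages([cov["ip_rep1"], cov["ip_rep2"]], "ip_pooled")
    candidates = lb.call_candidate_peaks(ip, small_truth.annotation)
    peaks = lb.filter_peaks_by_controls(candidates, ip, [cov["igg"], cov["cko"]])
    return {
        "truth": small_truth,
        "libs": libs,
        "cov": cov,
        "ip": ip,
        "candidates": candidates,
        "peaks": peaks,
        "targets": lb.derive_target_set(peaks),
    }


@pytest.fixture(scope="session")
def default_truth():
    """The standard study conditions: 1000 genes, 30% targets, seed 42."""
    return lb.generate_truth(lb.SyntheticConfig())


@pytest.fixture(scope="session")
def default_run(default_truth):
    """Full-scale end-to-end products on the default dataset."""
    truth = default_truth
    libs = lb.simulate_reads(truth)
    cov = {lib: lb.pileup_read_ends(df, lib) for lib, df in libs.items()}
    ip = merge_coverages([cov["ip_rep1"], cov["ip_rep2"]], "ip_pooled")
    candidates = lb.call_candidate_peaks(ip, truth.annotation)
    peaks = lb.filter_peaks_by_controls(candidates, ip, [cov["igg"], cov["cko"]])
    annotated = lb.annotate_peaks(peaks, truth.annotation)
    targets = lb.derive_target_set(peaks)
    seqs = lb.peak_sequences(peaks, truth.annotation)
    hexamers = lb.hexamer_zscores(seqs, n_shuffles=100, seed=42)
    measurements = lb.simulate_measurements(truth)
    densities = {
        d.gene_id: d.density
        for d in lb.gene_binding_density(peaks, ip, truth.annotation)
    }
    return {
        "truth": truth,
        "cov": cov,
        "ip": ip,
        "candidates": candidates,
        "peaks": peaks,
        "annotated": annotated,
        "targets": targets,
        "peak_seqs": seqs,
        "hexamers": hexamers,
        "measurements": measurements,
        "densities": densities,
    }
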