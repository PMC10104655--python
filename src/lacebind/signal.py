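"""Crosslink coverage, candidate peak calling, and the control-based filter.

Each aligned read contributes one count at its 5'-most aligned base (the
crosslink-proximal position for reverse-transcription-stop protocols:
read starts mark where the RT fell off at the protein-RNA adduct).
Candidate peaks come from a fixed-width sliding window per canonical
transcript tested against the transcript's own uniform background
(Poisson upper tail); false positives are then removed by requiring the
immunoprecipitation (IP) density to exceed every control library (IgG,
knockout) by a fold threshold, five by default.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome import GenomicInterval, Transcript, TranscriptomeAnnotation

logger = logging.getLogger(__name__)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str) -> pd.DataFrame:
    """Read a BED6 file of aligned reads into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed6(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


class CrosslinkCoverage:
    """Strand-specific read-5'-end counts per genomic position for one library."""

    def __init__(self, library_id: str) -> None:
        self.library_id = library_id
        self._counter: Dict[Tuple[str, str], Counter] = {}
        self._positions: Dict[Tuple[str, str], np.ndarray] = {}
        self._counts: Dict[Tuple[str, str], np.ndarray] = {}
        self.total_reads = 0
        self.n_rejected = 0
        self._finalized = False

    def add(self, chrom: str, strand: str, position: int, count: int = 1) -> None:
        if self._finalized:
            raise RuntimeError("coverage already finalized")
        self._counter.setdefault((chrom, strand), Counter())[position] += count
        self.total_reads += count

    def finalize(self) -> "CrosslinkCoverage":
        for key, counter in self._counter.items():
            pos = np.array(sorted(counter), dtype=np.int64)
            cnt = np.array([counter[p] for p in pos], dtype=np.int64)
            self._positions[key] = pos
            self._counts[key] = cnt
        self._counter.clear()
        self._finalized = True
        return self

    # ------------------------------------------------------------------
    def keys(self) -> Iterable[Tuple[str, str]]:
        return self._positions.keys()

    def items(self) -> Iterable[Tuple[Tuple[str, str], Dict[int, int]]]:
        for key in self._positions:
            pos, cnt = self._positions[key], self._counts[key]
            yield key, dict(zip(pos.tolist(), cnt.tolist()))

    def count_at(self, chrom: str, strand: str, position: int) -> int:
        pos = self._positions.get((chrom, strand))
        if pos is None:
            return 0
        i = int(np.searchsorted(pos, position))
        if i < len(pos) and pos[i] == position:
            return int(self._counts[(chrom, strand)][i])
        return 0

    def reads_in(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Total read 5' ends in genomic [start, end) on one strand."""
        pos = self._positions.get((chrom, strand))
        if pos is None:
            return 0
        lo, hi = np.searchsorted(pos, [start, end])
        return int(self._counts[(chrom, strand)][lo:hi].sum())

    def reads_in_interval(self, interval: GenomicInterval) -> int:
        return self.reads_in(interval.chrom, interval.strand, interval.start, interval.end)

    def transcript_profile(self, transcript: Transcript) -> np.ndarray:
        """Per-position counts along the spliced transcript (5'->3')."""
        prof = np.zeros(transcript.spliced_length, dtype=np.int64)
        key = (transcript.chrom, transcript.strand)
        pos = self._positions.get(key)
        if pos is None:
            return prof
        cnt = self._counts[key]
        for exon in transcript.exons:
            lo, hi = np.searchsorted(pos, [exon.start, exon.end])
            if lo == hi:
                continue
            for p, c in zip(pos[lo:hi], cnt[lo:hi]):
                tx = transcript.genome_to_transcript(int(p))
                if tx is not None:
                    prof[tx] += c
        return prof

    def rpm(self, reads: float, pseudocount: float = 0.0) -> float:
        if self.total_reads == 0:
            raise ValueError(f"library {self.library_id} has zero total reads")
        return (reads + pseudocount) / self.total_reads * 1e6


AlignmentLike = Union[pd.DataFrame, Iterable[Tuple[str, int, int, str]]]


def pileup_read_ends(alignments: AlignmentLike, library_id: str) -> CrosslinkCoverage:
    """Build crosslink coverage from aligned-read intervals.

    Each read contributes exactly one count at its 5'-most aligned base:
    ``start`` for + strand reads, ``end - 1`` for - strand reads.
    Records with ``start >= end`` are rejected and counted.
    """
    cov = CrosslinkCoverage(library_id)
    if isinstance(alignments, pd.DataFrame):
        rows = zip(
            alignments["chrom"].astype(str),
            alignments["start"].astype(int),
            alignments["end"].astype(int),
            alignments["strand"].astype(str),
        )
    else:
        rows = iter(alignments)
    for chrom, start, end, strand in rows:
        if start >= end:
            cov.n_rejected += 1
            continue
        five_prime = start if strand == "+" else end - 1
        cov.add(chrom, strand, five_prime)
    if cov.n_rejected:
        logger.warning(
            "library %s: rejected %d alignments with start >= end",
            library_id,
            cov.n_rejected,
        )
    return cov.finalize()


def pileup_bam(bam_path: str, library_id: str) -> CrosslinkCoverage:
    """Pile up read 5' ends from a coordinate-accessible BAM/SAM file."""
    import pysam  # optional heavyweight dependency, imported on use

    cov = CrosslinkCoverage(library_id)
    with pysam.AlignmentFile(bam_path) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            five_prime = aln.reference_start if strand == "+" else aln.reference_end - 1
            cov.add(aln.reference_name, strand, five_prime)
    return cov.finalize()


def merge_coverages(covs: Sequence[CrosslinkCoverage], library_id: str) -> CrosslinkCoverage:
    """Pool replicate libraries into a single coverage."""
    merged = CrosslinkCoverage(library_id)
    for cov in covs:
        for (chrom, strand), counts in cov.items():
            for pos, c in counts.items():
                merged.add(chrom, strand, pos, c)
    return merged.finalize()


@dataclass
class Peak:
    """A candidate or filtered binding site on a canonical transcript."""

    interval: GenomicInterval
    summit: int
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    tx_start: int = -1
    tx_end: int = -1
    ip_reads: int = 0
    ip_density: float = 0.0
    control_density: Dict[str, float] = field(default_factory=dict)
    enrichment: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError("summit must lie inside the peak interval")

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def min_enrichment(self) -> float:
        return min(self.enrichment.values()) if self.enrichment else float("nan")


def call_candidate_peaks(
    ip: CrosslinkCoverage,
    annotation: TranscriptomeAnnotation,
    window: int = 50,
    merge_distance: int = 10,
    min_reads: int = 5,
    p_threshold: float = 0.01,
) -> List[Peak]:
    """Sliding-window candidate peaks per canonical transcript.

    A window of ``window`` nt passes if it holds at least ``min_reads``
    read 5' ends and its count beats the transcript's uniform background
    (rate = transcript total / length, Poisson upper tail p < ``p_threshold``).
    Passing windows within ``merge_distance`` nt are merged; each merged
    region is trimmed to its covered read extent, and the summit is the
    position of the maximum single-position count (5'-most on ties).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    canonicals = annotation.canonical_transcripts()
    if not canonicals:
        raise ValueError("annotation has no canonical transcripts")

    kernel = np.ones(window, dtype=np.int64)
    peaks: List[Peak] = []
    for t in sorted(canonicals, key=lambda t: (t.chrom, t.genomic_start)):
        prof = ip.transcript_profile(t)
        total = int(prof.sum())
        if total == 0 or t.spliced_length < window:
            continue
        L = t.spliced_length
        win_sums = np.convolve(prof, kernel, mode="valid")
        lam = total / L * window
        # smallest count with Poisson upper-tail P(X >= c) < p_threshold
        candidates = np.unique(win_sums[win_sums >= min_reads])
        sig = candidates[stats.poisson.sf(candidates - 1, lam) < p_threshold]
        if sig.size == 0:
            continue
        min_hit = int(sig[0])
        hits = np.flatnonzero(win_sums >= min_hit)
        if hits.size == 0:
            continue
        # group window starts into merged candidate regions
        breaks = np.flatnonzero(np.diff(hits) > window + merge_distance)
        groups = np.split(hits, breaks + 1)
        for g in groups:
            s, e = int(g[0]), int(g[-1]) + window
            covered = np.flatnonzero(prof[s:e])
            if covered.size == 0:
                continue
            ts, te = s + int(covered[0]), s + int(covered[-1]) + 1
            summit_tx = ts + int(np.argmax(prof[ts:te]))
            gpos = t.transcript_to_genome_array(np.array([ts, te - 1]))
            gstart, gend = int(gpos.min()), int(gpos.max()) + 1
            peaks.append(
                Peak(
                    interval=GenomicInterval(t.chrom, gstart, gend, t.strand),
                    summit=t.transcript_to_genome(summit_tx),
                    gene_id=t.gene_id,
                    transcript_id=t.transcript_id,
                    tx_start=ts,
                    tx_end=te,
                    ip_reads=int(prof[ts:te].sum()),
                )
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return _dedupe_overlapping(peaks)


def _dedupe_overlapping(peaks: List[Peak]) -> List[Peak]:
    """Among same-strand overlapping peaks from different genes keep the
    one whose transcript holds more reads at the summit region."""
    kept: List[Peak] = []
    for p in peaks:
        if kept:
            q = kept[-1]
            same = (
                q.interval.chrom == p.interval.chrom
                and q.interval.strand == p.interval.strand
                and p.interval.start < q.interval.end
                and q.gene_id != p.gene_id
            )
            if same:
                if p.ip_reads > q.ip_reads:
                    kept[-1] = p
                continue
        kept.append(p)
    return kept


def filter_peaks_by_controls(
    candidates: Sequence[Peak],
    ip: CrosslinkCoverage,
    controls: Sequence[CrosslinkCoverage],
    fold: float = 5.0,
) -> List[Peak]:
    """Remove candidate peaks not enriched ``fold``-times over every control.

    Densities are reads-per-million within the peak interval with a +1 read
    pseudocount applied before RPM scaling (both IP and controls), so the
    enrichment ratio is always finite. A peak is kept iff its IP density is
    at least ``fold`` times the density in EVERY control library.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if not controls:
        raise ValueError("at least one control library is required")
    for c in controls:
        if c.total_reads == 0:
            raise ValueError(f"control library {c.library_id} has zero total reads")

    kept: List[Peak] = []
    for peak in candidates:
        reads = ip.reads_in_interval(peak.interval)
        peak.ip_reads = reads
        peak.ip_density = ip.rpm(reads, pseudocount=1)
        peak.control_density = {}
        peak.enrichment = {}
        ok = True
        for c in controls:
            c_density = c.rpm(c.reads_in_interval(peak.interval), pseudocount=1)
            ratio = peak.ip_density / c_density
            peak.control_density[c.library_id] = c_density
            peak.enrichment[c.library_id] = ratio
            if ratio < fold:
                ok = False
        if ok:
            kept.append(peak)
    return kept


def replicate_correlation(
    a: CrosslinkCoverage,
    b: CrosslinkCoverage,
    annotation: TranscriptomeAnnotation,
    level: str = "gene",
    peaks: Optional[Sequence[Peak]] = None,
    log: bool = True,
) -> float:
    """Pearson correlation of per-gene (or per-peak) log2(RPM+1) densities.

    Only features with nonzero signal in at least one library enter the
    correlation; fewer than three such features is an error.
    """
    if a.total_reads == 0 or b.total_reads == 0:
        raise ValueError("both libraries must be non-empty")
    if level == "gene":
        feats = [
            (t.chrom, t.strand, t.genomic_start, t.genomic_end)
            for t in annotation.canonical_transcripts()
        ]
    elif level == "peak":
        if peaks is None:
            raise ValueError("level='peak' requires peaks")
        feats = [
            (p.interval.chrom, p.interval.strand, p.interval.start, p.interval.end)
            for p in peaks
        ]
    else:
        raise ValueError(f"unknown level {level!r}")

    xs, ys = [], []
    for chrom, strand, start, end in feats:
        ra = a.reads_in(chrom, strand, start, end)
        rb = b.reads_in(chrom, strand, start, end)
        if ra == 0 and rb == 0:
            continue
        xs.append(a.rpm(ra))
        ys.append(b.rpm(rb))
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} features with signal; correlation undefined"
        )
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if log:
        x = np.log2(x + 1)
        y = np.log2(y + 1)
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class GeneBindingDensity:
    """Peak-overlapping IP reads per kb of canonical transcript per million reads."""

    gene_id: str
    density: float
    n_peaks: int
    peak_reads: int


def gene_binding_density(
    peaks: Sequence[Peak],
    ip: CrosslinkCoverage,
    annotation: TranscriptomeAnnotation,
) -> List[GeneBindingDensity]:
    """Per-gene binding density from filtered peaks (RPKM over the canonical
    transcript length). Genes without peaks are absent, not zero."""
    by_gene: Dict[str, List[Peak]] = {}
    for p in peaks:
        if p.gene_id is None:
            logger.warning("peak at %s lacks a gene assignment; skipped", p.interval)
            continue
        by_gene.setdefault(p.gene_id, []).append(p)

    out: List[GeneBindingDensity] = []
    for gene_id, gene_peaks in sorted(by_gene.items()):
        t = annotation.canonical(gene_id)
        reads = sum(ip.reads_in_interval(p.interval) for p in gene_peaks)
        density = reads / (t.spliced_length / 1e3) / (ip.total_reads / 1e6)
        out.append(
            GeneBindingDensity(
                gene_id=gene_id,
                density=density,
                n_peaks=len(gene_peaks),
                peak_reads=reads,
            )
        )
    return out


def peaks_to_dataframe(peaks: Sequence[Peak]) -> pd.DataFrame:
    """BED6+ representation of peaks (extra density/enrichment columns)."""
    rows = []
    for i, p in enumerate(peaks):
        row = {
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "name": f"peak_{i + 1}",
            "score": p.ip_reads,
            "strand": p.interval.strand,
            "summit": p.summit,
            "gene_id": p.gene_id or ".",
            "transcript_id": p.transcript_id or ".",
            "ip_rpm": p.ip_density,
        }
        for lib, d in p.control_density.items():
            row[f"{lib}_rpm"] = d
        row["enrichment_min"] = p.min_enrichment
        rows.append(row)
    return pd.DataFrame(rows)
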