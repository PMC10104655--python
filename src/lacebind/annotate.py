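"""Peak feature categorisation and metagene profiling.

A peak is assigned to exactly one category by its center position, with
the precedence repeat > exonic feature (5UTR/CDS/3UTR/noncoding exon) >
intron > intergenic. Metagene profiles come in two modes: scaled
gene-body bins from TSS to TTS, and fixed single-nucleotide windows
anchored at the TSS, TTS, start codon, stop codon, or annotated poly(A)
site of each canonical transcript.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .signal import CrosslinkCoverage, Peak
from .transcriptome import Transcript, TranscriptomeAnnotation

CATEGORIES = ("5UTR", "CDS", "3UTR", "noncoding_exon", "intron", "repeat", "intergenic")

ANCHORS = ("TSS", "TTS", "start_codon", "stop_codon", "polyA_site")


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class CategoryDistribution:
    """Counts and fractions per category plus the combined-UTR fraction."""

    counts: Dict[str, int]
    fractions: Dict[str, float]
    utr_fraction: float  # 5UTR + 3UTR, the combined figure usually reported
    n_peaks: int


class _TranscriptIndex:
    """Sorted per-(chrom, strand) lookup of canonical transcripts by span."""

    def __init__(self, annotation: TranscriptomeAnnotation) -> None:
        self._by_key: Dict[Tuple[str, str], Tuple[List[int], List[Transcript]]] = {}
        by_key: Dict[Tuple[str, str], List[Transcript]] = {}
        for t in annotation.canonical_transcripts():
            by_key.setdefault((t.chrom, t.strand), []).append(t)
        for key, ts in by_key.items():
            ts.sort(key=lambda t: t.genomic_start)
            self._by_key[key] = ([t.genomic_start for t in ts], ts)

    def overlapping(self, chrom: str, strand: str, pos: int) -> List[Transcript]:
        entry = self._by_key.get((chrom, strand))
        if entry is None:
            return []
        starts, ts = entry
        i = bisect.bisect_right(starts, pos)
        # transcripts are laid out without containment on the synthetic
        # genome, but scan back a little to tolerate overlapping loci
        out = []
        for j in range(max(0, i - 5), i):
            if ts[j].genomic_start <= pos < ts[j].genomic_end:
                out.append(ts[j])
        return out


def _get_index(annotation: TranscriptomeAnnotation) -> _TranscriptIndex:
    idx = getattr(annotation, "_tx_index", None)
    if idx is None:
        idx = _TranscriptIndex(annotation)
        annotation._tx_index = idx  # type: ignore[attr-defined]
    return idx


def assign_peak_category(
    peak: Peak, annotation: TranscriptomeAnnotation
) -> AnnotatedPeak:
    """Categorise one peak by its center position ((start+end)//2)."""
    iv = peak.interval
    center = (iv.start + iv.end) // 2
    if annotation.in_repeat(iv.chrom, center):
        return AnnotatedPeak(peak, "repeat")

    # prefer the transcript the peak was called on, if it covers the center
    candidates: List[Transcript] = []
    if peak.transcript_id is not None:
        t = annotation.transcripts.get(peak.transcript_id)
        if t is not None and t.genomic_start <= center < t.genomic_end:
            candidates = [t]
    if not candidates:
        candidates = _get_index(annotation).overlapping(iv.chrom, iv.strand, center)

    in_gene_span = False
    for t in candidates:
        in_gene_span = True
        tx = t.genome_to_transcript(center)
        if tx is not None:
            return AnnotatedPeak(peak, t.feature_at(tx))
    if in_gene_span:
        return AnnotatedPeak(peak, "intron")
    return AnnotatedPeak(peak, "intergenic")


def annotate_peaks(
    peaks: Sequence[Peak], annotation: TranscriptomeAnnotation
) -> List[AnnotatedPeak]:
    return [assign_peak_category(p, annotation) for p in peaks]


def category_distribution(annotated: Sequence[AnnotatedPeak]) -> CategoryDistribution:
    if not annotated:
        raise ValueError("no annotated peaks given")
    counts = {c: 0 for c in CATEGORIES}
    for ap in annotated:
        counts[ap.category] += 1
    n = len(annotated)
    fractions = {c: counts[c] / n for c in CATEGORIES}
    return CategoryDistribution(
        counts=counts,
        fractions=fractions,
        utr_fraction=fractions["5UTR"] + fractions["3UTR"],
        n_peaks=n,
    )


@dataclass
class MetaProfile:
    """Mean per-bin density across canonical transcripts."""

    mode: str  # "gene_body" or "anchored"
    anchor: Optional[str]
    bins: np.ndarray
    n_transcripts: int
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        if self.mode == "anchored":
            flank = (len(self.bins) - 1) // 2
            index = np.arange(-flank, flank + 1)
            name = "offset"
        else:
            index = np.arange(len(self.bins))
            name = "bin"
        return pd.DataFrame({name: index, "mean_density": self.bins})


def _anchor_position(t: Transcript, anchor: str) -> Optional[int]:
    """Transcript-coordinate position of a metagene anchor.

    The CDS here includes the stop codon, so the stop-codon anchor is the
    first base of the final codon. Codon anchors are undefined for
    non-coding transcripts.
    """
    if anchor == "TSS":
        return 0
    if anchor == "TTS" or anchor == "polyA_site":
        return t.spliced_length - 1
    if not t.is_coding:
        return None
    cds = next((s, e) for name, s, e in t.feature_partition if name == "CDS")
    if anchor == "start_codon":
        return cds[0]
    if anchor == "stop_codon":
        return cds[1] - 3
    raise ValueError(f"unknown anchor {anchor!r}")


def metaprofile(
    coverage: CrosslinkCoverage,
    annotation: TranscriptomeAnnotation,
    mode: str = "gene_body",
    anchor: Optional[str] = None,
    n_bins: int = 100,
    flank: int = 100,
) -> MetaProfile:
    """Average read-density profile over canonical transcripts.

    gene_body mode: each transcript's exonic RPM is binned into ``n_bins``
    scaled bins (TSS->TTS) as per-nt bin densities, then normalised to
    mean 1 so every transcript carries equal weight; the profile is the
    unweighted mean over transcripts with at least one read.

    anchored mode: raw RPM at single-nt offsets within ±``flank`` of the
    anchor; transcripts whose window does not fit (or, for codon anchors,
    non-coding transcripts) are skipped and counted.
    """
    if mode not in ("gene_body", "anchored"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "anchored" and anchor not in ANCHORS:
        raise ValueError(f"anchored mode needs an anchor from {ANCHORS}")

    profiles: List[np.ndarray] = []
    n_skipped = 0
    for t in annotation.canonical_transcripts():
        prof = coverage.transcript_profile(t)
        if prof.sum() == 0:
            continue
        rpm = prof / coverage.total_reads * 1e6
        if mode == "gene_body":
            L = t.spliced_length
            if L < n_bins:
                n_skipped += 1
                continue
            idx = (np.arange(L) * n_bins) // L
            sums = np.bincount(idx, weights=rpm, minlength=n_bins)
            widths = np.bincount(idx, minlength=n_bins)
            dens = sums / widths
            profiles.append(dens / dens.mean())
        else:
            pos = _anchor_position(t, anchor)
            if pos is None or pos - flank < 0 or pos + flank >= t.spliced_length:
                n_skipped += 1
                continue
            profiles.append(rpm[pos - flank : pos + flank + 1])

    if not profiles:
        raise ValueError("no transcripts usable for the requested profile")
    return MetaProfile(
        mode=mode,
        anchor=anchor if mode == "anchored" else None,
        bins=np.mean(profiles, axis=0),
        n_transcripts=len(profiles),
        n_skipped=n_skipped,
    )


def plot_metaprofile(profile: MetaProfile, path: str) -> None:
    """Minimal line plot of a metagene profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile.to_frame()
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(df.iloc[:, 0], df["mean_density"])
    ax.set_xlabel(df.columns[0] + (f" from {profile.anchor}" if profile.anchor else ""))
    ax.set_ylabel("mean density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def annotated_peaks_to_frame(annotated: Sequence[AnnotatedPeak]) -> pd.DataFrame:
    from .signal import peaks_to_dataframe

    df = peaks_to_dataframe([ap.peak for ap in annotated])
    df["category"] = [ap.category for ap in annotated]
    return df
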