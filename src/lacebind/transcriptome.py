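"""Transcript models and strand-aware genome/transcript coordinate mapping.

All coordinates are 0-based half-open internally. GTF input (1-based,
closed) is converted at parse time; BED input is used natively.

The annotation collapses each gene to one canonical transcript — the
longest spliced isoform, ties broken by lexicographically smallest
transcript_id — and every gene-level statistic downstream (binding
density, TE, metagene profiles) is computed on that transcript.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

CODING_FEATURES = ("5UTR", "CDS", "3UTR")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class Transcript:
    """A spliced transcript with optional CDS and derived UTR/CDS partition.

    Parameters
    ----------
    transcript_id, gene_id
        Identifiers from the annotation.
    exons
        Exon intervals on one chromosome and strand. Stored sorted by
        genomic coordinate; transcript coordinates always run 5'->3', so
        for minus-strand transcripts offset 0 is the genomically
        rightmost exonic base.
    cds_span
        Optional (genomic_start, genomic_end) of the coding region,
        half-open, spanning all CDS records.
    """

    def __init__(
        self,
        transcript_id: str,
        gene_id: str,
        exons: Sequence[GenomicInterval],
        cds_span: Optional[Tuple[int, int]] = None,
    ) -> None:
        if not exons:
            raise AnnotationError(f"transcript {transcript_id} has no exons")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"transcript {transcript_id} exons span multiple chroms/strands"
            )
        exons = sorted(exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"transcript {transcript_id} has overlapping exons"
                )
        self.transcript_id = transcript_id
        self.gene_id = gene_id
        self.exons: Tuple[GenomicInterval, ...] = tuple(exons)
        self.chrom = exons[0].chrom
        self.strand = exons[0].strand
        self.cds_span = tuple(cds_span) if cds_span is not None else None

        # cumulative spliced offsets in genomic (left->right) order
        lengths = [len(e) for e in self.exons]
        self._cum = np.concatenate([[0], np.cumsum(lengths)])
        self.spliced_length = int(self._cum[-1])
        self.genomic_start = self.exons[0].start
        self.genomic_end = self.exons[-1].end

        self.feature_partition: List[Tuple[str, int, int]] = []
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if self.strand == "+":
                cds_tx_start = self.genome_to_transcript(cs)
                cds_tx_end = self.genome_to_transcript(ce - 1)
            else:
                cds_tx_start = self.genome_to_transcript(ce - 1)
                cds_tx_end = self.genome_to_transcript(cs)
            if cds_tx_start is None or cds_tx_end is None:
                raise AnnotationError(
                    f"CDS of {transcript_id} does not lie in its exons"
                )
            cds_tx_end += 1
            if cds_tx_end - cds_tx_start < 3:
                raise AnnotationError(
                    f"CDS of {transcript_id} shorter than one codon"
                )
            if cds_tx_start > 0:
                self.feature_partition.append(("5UTR", 0, cds_tx_start))
            self.feature_partition.append(("CDS", cds_tx_start, cds_tx_end))
            if cds_tx_end < self.spliced_length:
                self.feature_partition.append(
                    ("3UTR", cds_tx_end, self.spliced_length)
                )
            covered = sum(e - s for _, s, e in self.feature_partition)
            assert covered == self.spliced_length

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    def feature_lengths(self) -> Dict[str, int]:
        return {name: e - s for name, s, e in self.feature_partition}

    def feature_at(self, tx_pos: int) -> str:
        """Feature label (5UTR/CDS/3UTR or noncoding_exon) at a transcript offset."""
        if not 0 <= tx_pos < self.spliced_length:
            raise IndexError(f"transcript position {tx_pos} out of range")
        if not self.is_coding:
            return "noncoding_exon"
        for name, s, e in self.feature_partition:
            if s <= tx_pos < e:
                return name
        raise AssertionError("partition does not cover transcript")

    # ------------------------------------------------------------------
    # coordinate mapping
    # ------------------------------------------------------------------
    def genome_to_transcript(self, pos: int) -> Optional[int]:
        """Map a genomic position to a spliced transcript offset (5'->3').

        Returns ``None`` for intronic or out-of-range positions.
        """
        i = bisect.bisect_right([e.start for e in self.exons], pos) - 1
        if i < 0:
            return None
        exon = self.exons[i]
        if pos >= exon.end:
            return None
        left_offset = int(self._cum[i]) + (pos - exon.start)
        if self.strand == "+":
            return left_offset
        return self.spliced_length - 1 - left_offset

    def transcript_to_genome(self, tx_pos: int) -> int:
        """Map a transcript offset back to its genomic position."""
        if not 0 <= tx_pos < self.spliced_length:
            raise IndexError(f"transcript position {tx_pos} out of range")
        left = tx_pos if self.strand == "+" else self.spliced_length - 1 - tx_pos
        i = int(np.searchsorted(self._cum, left, side="right")) - 1
        exon = self.exons[i]
        return exon.start + (left - int(self._cum[i]))

    def transcript_to_genome_array(self, tx_pos: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`transcript_to_genome`."""
        tx_pos = np.asarray(tx_pos, dtype=np.int64)
        left = tx_pos if self.strand == "+" else self.spliced_length - 1 - tx_pos
        i = np.searchsorted(self._cum, left, side="right") - 1
        starts = np.array([e.start for e in self.exons], dtype=np.int64)
        return starts[i] + (left - self._cum[i].astype(np.int64))

    def exonic_positions(self) -> np.ndarray:
        """Genomic positions of every exonic base, in transcript (5'->3') order."""
        parts = [np.arange(e.start, e.end, dtype=np.int64) for e in self.exons]
        genomic = np.concatenate(parts)
        return genomic if self.strand == "+" else genomic[::-1]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Transcript({self.transcript_id}, {self.gene_id}, "
            f"{self.chrom}:{self.genomic_start}-{self.genomic_end}{self.strand}, "
            f"L={self.spliced_length}, coding={self.is_coding})"
        )


@dataclass
class TranscriptomeAnnotation:
    """Validated transcript models plus repeats and spliced sequences."""

    transcripts: Dict[str, Transcript]
    gene_to_canonical: Dict[str, str]
    repeats: List[GenomicInterval] = field(default_factory=list)
    sequences: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, seq in self.sequences.items():
            t = self.transcripts.get(tid)
            if t is not None and len(seq) != t.spliced_length:
                raise AnnotationError(
                    f"sequence length {len(seq)} != spliced length "
                    f"{t.spliced_length} for {tid}"
                )
        self._repeat_starts: Dict[str, np.ndarray] = {}
        self._repeat_ends: Dict[str, np.ndarray] = {}
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for r in self.repeats:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda r: r.start)
            merged: List[List[int]] = []
            for r in ivs:
                if merged and r.start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], r.end)
                else:
                    merged.append([r.start, r.end])
            self._repeat_starts[chrom] = np.array([m[0] for m in merged])
            self._repeat_ends[chrom] = np.array([m[1] for m in merged])

    def canonical_transcripts(self) -> List[Transcript]:
        return [self.transcripts[t] for t in self.gene_to_canonical.values()]

    def canonical(self, gene_id: str) -> Transcript:
        return self.transcripts[self.gene_to_canonical[gene_id]]

    def get_transcript(self, transcript_id: str) -> Transcript:
        try:
            return self.transcripts[transcript_id]
        except KeyError:
            raise KeyError(f"unknown transcript_id {transcript_id!r}") from None

    def sequence(self, transcript_id: str) -> Optional[str]:
        return self.sequences.get(transcript_id)

    def in_repeat(self, chrom: str, pos: int) -> bool:
        """Whether a position falls in any repeat interval (strand-agnostic)."""
        starts = self._repeat_starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return bool(i >= 0 and pos < self._repeat_ends[chrom][i])


def map_genome_to_transcript(
    annotation: TranscriptomeAnnotation, transcript_id: str, position: int
) -> Optional[int]:
    """Module-level convenience wrapper around :meth:`Transcript.genome_to_transcript`."""
    return annotation.get_transcript(transcript_id).genome_to_transcript(position)


# ----------------------------------------------------------------------
# loading
# ----------------------------------------------------------------------

def _parse_gtf(gtf_path: str) -> Tuple[Dict[str, dict], List[str]]:
    """Collect exon and CDS records per transcript from a GTF file."""
    records: Dict[str, dict] = {}
    warnings: List[str] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise AnnotationError(
                    f"malformed GTF line {lineno} in {gtf_path}: expected 9 "
                    f"tab-separated fields, got {len(line.split(chr(9)))}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationError(
                    f"malformed GTF line {lineno} in {gtf_path}: {exc}"
                ) from exc
            if feat.featuretype not in ("exon", "CDS"):
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise AnnotationError(
                    f"GTF line {lineno}: missing {exc} attribute"
                ) from exc
            rec = records.setdefault(
                transcript_id,
                {"gene_id": gene_id, "exons": [], "cds": []},
            )
            # GTF is 1-based closed; convert to 0-based half-open
            iv = (feat.seqid, feat.start - 1, feat.end, feat.strand)
            rec["exons" if feat.featuretype == "exon" else "cds"].append(iv)
    return records, warnings


def load_annotation(
    gtf_path: str,
    repeats_path: Optional[str] = None,
    fasta_path: Optional[str] = None,
    fasta_mode: str = "auto",
) -> TranscriptomeAnnotation:
    """Load a transcript annotation from GTF, with optional repeats and sequences.

    Parameters
    ----------
    gtf_path
        GTF with exon (and optionally CDS) records; attributes must carry
        ``gene_id`` and ``transcript_id``.
    repeats_path
        Optional BED6 of repeat intervals.
    fasta_path
        Optional FASTA. ``fasta_mode`` declares whether records are keyed
        by transcript id (``"transcript"``) or are chromosome sequences to
        be spliced (``"genome"``); ``"auto"`` detects by name matching.
    """
    records, _ = _parse_gtf(gtf_path)
    if not records:
        logger.warning("GTF %s contained no exon records; empty annotation", gtf_path)

    transcripts: Dict[str, Transcript] = {}
    for tid, rec in records.items():
        exons = [GenomicInterval(*iv) for iv in rec["exons"]]
        cds_span = None
        if rec["cds"]:
            cds_len = sum(e - s for _, s, e, _ in rec["cds"])
            if cds_len % 3 != 0:
                logger.warning(
                    "transcript %s CDS length %d not divisible by 3; kept",
                    tid,
                    cds_len,
                )
            cds_span = (
                min(s for _, s, _, _ in rec["cds"]),
                max(e for _, _, e, _ in rec["cds"]),
            )
        transcripts[tid] = Transcript(tid, rec["gene_id"], exons, cds_span)

    gene_to_canonical: Dict[str, str] = {}
    by_gene: Dict[str, List[Transcript]] = {}
    for t in transcripts.values():
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id, ts in by_gene.items():
        best = sorted(ts, key=lambda t: (-t.spliced_length, t.transcript_id))[0]
        gene_to_canonical[gene_id] = best.transcript_id

    repeats: List[GenomicInterval] = []
    if repeats_path is not None:
        bed = pd.read_csv(
            repeats_path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            comment="#",
        )
        for row in bed.itertuples(index=False):
            # repeat masking is strand-agnostic here; store on '+'
            repeats.append(GenomicInterval(str(row.chrom), int(row.start), int(row.end), "+"))

    sequences: Dict[str, str] = {}
    if fasta_path is not None:
        from Bio import SeqIO

        fasta = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
        mode = fasta_mode
        if mode == "auto":
            tx_hits = sum(1 for tid in transcripts if tid in fasta)
            chrom_hits = sum(
                1 for c in {t.chrom for t in transcripts.values()} if c in fasta
            )
            mode = "transcript" if tx_hits >= chrom_hits else "genome"
        if mode == "transcript":
            sequences = {tid: fasta[tid] for tid in transcripts if tid in fasta}
        elif mode == "genome":
            sequences = {
                tid: _splice(fasta[t.chrom], t)
                for tid, t in transcripts.items()
                if t.chrom in fasta
            }
        else:
            raise ValueError(f"unknown fasta_mode {fasta_mode!r}")

    return TranscriptomeAnnotation(
        transcripts=transcripts,
        gene_to_canonical=gene_to_canonical,
        repeats=repeats,
        sequences=sequences,
    )


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _splice(chrom_seq: str, t: Transcript) -> str:
    s = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return s if t.strand == "+" else reverse_complement(s)


def write_gtf(annotation: TranscriptomeAnnotation, path: str, source: str = "lacebind") -> None:
    """Write exon and CDS records (1-based closed coordinates) for all transcripts."""
    with open(path, "w") as fh:
        for t in sorted(
            annotation.transcripts.values(),
            key=lambda t: (t.chrom, t.genomic_start, t.transcript_id),
        ):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            if t.cds_span is not None:
                cs, ce = t.cds_span
                for e in t.exons:
                    lo, hi = max(e.start, cs), min(e.end, ce)
                    if lo < hi:
                        fh.write(
                            f"{t.chrom}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t"
                            f"{t.strand}\t.\t{attrs}\n"
                        )
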