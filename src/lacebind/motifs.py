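"""Hexamer over-representation statistics at binding-site sequences.

Observed hexamer counts (overlapping occurrences) across peak sequences
are compared with a null built from per-sequence dinucleotide-preserving
shuffles (Altschul-Erickson Euler-walk shuffle), which controls both GC
content and dinucleotide composition. The z-score is
(observed - null_mean) / max(null_sd, sd_floor); the sd floor keeps z
finite for hexamers the shuffles never produce.

Sequences may be given in DNA or RNA alphabet; T and U are equivalent at
ingest and the reporting alphabet is chosen per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotate import MetaProfile
from .transcriptome import TranscriptomeAnnotation

K = 6
N_KMERS = 4**K
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_BASES = "ACGT"


def normalize_alphabet(seq: str, alphabet: str = "DNA") -> str:
    seq = seq.upper()
    if alphabet == "DNA":
        return seq.replace("U", "T")
    if alphabet == "RNA":
        return seq.replace("T", "U")
    raise ValueError(f"unknown alphabet {alphabet!r}")


def _encode(seq: str) -> np.ndarray:
    """Map a DNA/RNA string to 0..3 codes; ambiguous bases become -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        lut[ord(base)] = code
    return lut[arr].astype(np.int64)


def count_hexamers(seqs: Iterable[str]) -> np.ndarray:
    """Occurrences (overlapping) of each of the 4^6 hexamers across sequences."""
    counts = np.zeros(N_KMERS, dtype=np.int64)
    weights = 4 ** np.arange(K - 1, -1, -1)
    for seq in seqs:
        codes = _encode(seq)
        n = len(codes) - K + 1
        if n <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, K)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        ids = windows[valid] @ weights
        counts += np.bincount(ids, minlength=N_KMERS)
    return counts


def kmer_to_string(idx: int, alphabet: str = "DNA") -> str:
    bases = _BASES if alphabet == "DNA" else "ACGU"
    out = []
    for _ in range(K):
        out.append(bases[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Euler-walk shuffle: the sequence is a walk on the graph whose edges
    are its dinucleotides; a uniform random last-edge arborescence into
    the terminal character is drawn (rejection sampling over a 4-node
    graph terminates quickly), remaining edges are permuted, and the walk
    is replayed.
    """
    if len(seq) <= 2:
        return seq
    chars = list(seq)
    edges: Dict[str, List[str]] = {}
    for a, b in zip(chars, chars[1:]):
        edges.setdefault(a, []).append(b)
    last_char = chars[-1]
    vertices = list(edges)

    def arborescence_ok(last_edge: Dict[str, str]) -> bool:
        for v in vertices:
            if v == last_char:
                continue
            seen = {v}
            cur = v
            while cur != last_char:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    return False
                seen.add(cur)
        return True

    while True:
        # only non-terminal vertices reserve a last edge (arborescence into
        # the terminal character)
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in vertices
            if v != last_char
        }
        if arborescence_ok(last_edge):
            break

    shuffled: Dict[str, List[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        reserved = None
        if v != last_char and v in last_edge:
            pool.remove(last_edge[v])
            reserved = last_edge[v]
        rng.shuffle(pool)
        if reserved is not None:
            pool.append(reserved)
        shuffled[v] = pool

    out = [chars[0]]
    pointers = {v: 0 for v in shuffled}
    cur = chars[0]
    for _ in range(len(chars) - 1):
        nxt = shuffled[cur][pointers[cur]]
        pointers[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class HexamerTable:
    """Per-hexamer observed counts, shuffle-null moments and z-scores."""

    table: pd.DataFrame  # columns: hexamer, observed, null_mean, null_sd, z
    n_shuffles: int
    sd_floor: float
    alphabet: str = "DNA"

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)


def hexamer_zscores(
    peak_seqs: Sequence[str],
    n_shuffles: int = 100,
    seed: int = 0,
    sd_floor: float = 0.5,
    alphabet: str = "DNA",
) -> HexamerTable:
    """Hexamer z-scores against a dinucleotide-preserving shuffle null.

    The table is sorted by z descending with ties broken by hexamer
    lexicographic order; identical seeds yield identical tables.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    seqs = [normalize_alphabet(s, "DNA") for s in peak_seqs]
    usable = [s for s in seqs if len(s) >= K]
    if not usable:
        raise ValueError("all sequences shorter than 6 nt")

    observed = count_hexamers(usable)
    rng = np.random.default_rng(seed)
    null = np.zeros((n_shuffles, N_KMERS), dtype=np.int64)
    for i in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(s, rng) for s in usable]
        null[i] = count_hexamers(shuffled)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    z = (observed - null_mean) / np.maximum(null_sd, sd_floor)

    hexamers = [kmer_to_string(i, alphabet) for i in range(N_KMERS)]
    df = pd.DataFrame(
        {
            "hexamer": hexamers,
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
        }
    )
    df = df.sort_values(["z", "hexamer"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    return HexamerTable(table=df, n_shuffles=n_shuffles, sd_floor=sd_floor, alphabet=alphabet)


@dataclass
class ConsensusMatrix:
    """Position-frequency matrix built from aligned top hexamers."""

    matrix: pd.DataFrame  # rows A/C/G/T(U), columns positions
    source_hexamers: List[str]

    @property
    def consensus(self) -> str:
        return "".join(self.matrix.idxmax(axis=0))


def _alignment_offset(hexamer: str, reference: str, max_shift: int = 2) -> int:
    """Ungapped offset in [-max_shift, max_shift] maximising matches to the
    reference; ties prefer offset 0, then smaller |offset|, then positive."""
    best = None
    for d in sorted(range(-max_shift, max_shift + 1), key=lambda d: (d != 0, abs(d), -d)):
        if d >= 0:
            matches = sum(
                1 for i in range(K - d) if hexamer[i] == reference[i + d]
            )
        else:
            matches = sum(
                1 for i in range(K + d) if hexamer[i - d] == reference[i]
            )
        if best is None or matches > best[0]:
            best = (matches, d)
    return best[1]


def consensus_from_top_hexamers(table: HexamerTable, k: int = 20) -> ConsensusMatrix:
    """Z-weighted position-frequency matrix from the top-k hexamers.

    Each hexamer is aligned ungapped to the rank-1 hexamer at the offset
    in {-2..+2} maximising base matches; z-weights are clipped at zero
    (uniform weights if all are non-positive), and columns normalised.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    df = table.table
    df = df[df["observed"] > 0]
    if len(df) < k:
        raise ValueError(f"only {len(df)} hexamers with observed > 0; need {k}")
    top = df.head(k)
    reference = normalize_alphabet(top.iloc[0]["hexamer"], "DNA")
    weights = np.clip(top["z"].to_numpy(dtype=float), 0, None)
    if weights.sum() == 0:
        weights = np.ones(k)

    col_counts: Dict[int, np.ndarray] = {}
    sources = []
    for (_, row), w in zip(top.iterrows(), weights):
        hx = normalize_alphabet(row["hexamer"], "DNA")
        sources.append(row["hexamer"])
        d = _alignment_offset(hx, reference)
        for i, base in enumerate(hx):
            col = i + d
            col_counts.setdefault(col, np.zeros(4))[_BASE_INDEX[base]] += w

    cols = sorted(col_counts)
    mat = np.stack([col_counts[c] / col_counts[c].sum() for c in cols], axis=1)
    bases = list(_BASES if table.alphabet == "DNA" else "ACGU")
    matrix = pd.DataFrame(mat, index=bases, columns=cols)
    return ConsensusMatrix(matrix=matrix, source_hexamers=sources)


@dataclass
class MotifSet:
    """A set of hexamers plus the rule that produced it."""

    hexamers: Set[str]
    rule: str = ""

    def __post_init__(self) -> None:
        self.hexamers = {normalize_alphabet(h, "DNA") for h in self.hexamers}

    def __len__(self) -> int:
        return len(self.hexamers)


def gc_rich_motifs(
    table: HexamerTable, top: int = 20, gc_min: float = 5 / 6
) -> MotifSet:
    """GC-rich members of the top hexamers (GC fraction >= ``gc_min``)."""
    chosen = set()
    for hx in table.top(top)["hexamer"]:
        dna = normalize_alphabet(hx, "DNA")
        gc = sum(1 for b in dna if b in "GC") / len(dna)
        if gc >= gc_min:
            chosen.add(dna)
    return MotifSet(chosen, rule=f"top {top} by z with GC fraction >= {gc_min:.3f}")


def top_motifs(table: HexamerTable, top: int = 20) -> MotifSet:
    return MotifSet(
        set(table.top(top)["hexamer"]), rule=f"top {top} hexamers by z"
    )


def _contains_any(seq: str, motifs: MotifSet) -> bool:
    s = normalize_alphabet(seq, "DNA")
    return any(m in s for m in motifs.hexamers)


def motif_peak_fraction(peak_seqs: Sequence[str], motifs: MotifSet) -> float:
    """Fraction of peak sequences containing at least one motif occurrence."""
    if not peak_seqs:
        raise ValueError("no peak sequences given")
    if not motifs.hexamers:
        raise ValueError("empty motif set")
    hits = sum(1 for s in peak_seqs if _contains_any(s, motifs))
    return hits / len(peak_seqs)


def motif_occurrences(seq: str, motifs: MotifSet) -> List[int]:
    """Start offsets of all (overlapping) motif occurrences in a sequence."""
    s = normalize_alphabet(seq, "DNA")
    out = []
    for m in motifs.hexamers:
        start = s.find(m)
        while start != -1:
            out.append(start)
            start = s.find(m, start + 1)
    return sorted(out)


def motif_positional_profile(
    motifs: MotifSet,
    annotation: TranscriptomeAnnotation,
    n_bins: int = 100,
) -> MetaProfile:
    """Scaled gene-body distribution of motif occurrences.

    Per canonical transcript, occurrence positions are binned into
    ``n_bins`` scaled bins and normalised by the transcript's total
    occurrences, so each transcript with at least one occurrence
    contributes unit mass; the profile is the mean over those transcripts.
    """
    if not motifs.hexamers:
        raise ValueError("empty motif set")
    profiles = []
    any_seq = False
    for t in annotation.canonical_transcripts():
        seq = annotation.sequence(t.transcript_id)
        if seq is None:
            continue
        any_seq = True
        occ = motif_occurrences(seq, motifs)
        if not occ:
            continue
        idx = (np.array(occ) * n_bins) // len(seq)
        hist = np.bincount(idx, minlength=n_bins).astype(float)
        profiles.append(hist / hist.sum())
    if not any_seq:
        raise ValueError("no transcript has a sequence")
    if not profiles:
        raise ValueError("no transcript contains a motif occurrence")
    return MetaProfile(
        mode="gene_body",
        anchor=None,
        bins=np.mean(profiles, axis=0),
        n_transcripts=len(profiles),
    )


def peak_sequences(
    peaks, annotation: TranscriptomeAnnotation
) -> List[str]:
    """Spliced-transcript sequence under each peak (5'->3')."""
    seqs = []
    for p in peaks:
        if p.transcript_id is None or p.tx_start < 0:
            raise ValueError("peak lacks transcript coordinates")
        seq = annotation.sequence(p.transcript_id)
        if seq is None:
            raise ValueError(f"no sequence for transcript {p.transcript_id}")
        seqs.append(seq[p.tx_start : p.tx_end])
    return seqs
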