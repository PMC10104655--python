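"""Target sets, overlaps, quartile associations and proteomics shifts.

This stage couples the binding landscape to orthogonal measurements:
translation efficiency (ribosome-protected-fragment density over mRNA
density), poly(A) tail lengths, and protein-level fold changes. Group
comparisons use the two-tailed Wilcoxon rank-sum (Mann-Whitney) test —
exact for small tie-free samples, normal approximation with tie and
continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import AnnotatedPeak
from .signal import Peak
from .transcriptome import TranscriptomeAnnotation


@dataclass(frozen=True)
class TargetSet:
    label: str
    genes: frozenset

    def __len__(self) -> int:
        return len(self.genes)


def derive_target_set(
    peaks: Sequence, min_peaks: int = 1, label: str = "targets"
) -> TargetSet:
    """Genes carrying at least ``min_peaks`` filtered peaks."""
    counts: Dict[str, int] = {}
    for p in peaks:
        peak = p.peak if isinstance(p, AnnotatedPeak) else p
        if peak.gene_id is not None:
            counts[peak.gene_id] = counts.get(peak.gene_id, 0) + 1
    genes = frozenset(g for g, n in counts.items() if n >= min_peaks)
    return TargetSet(label=label, genes=genes)


@dataclass(frozen=True)
class VennResult:
    only_a: int
    only_b: int
    shared: int

    @property
    def size_a(self) -> int:
        return self.only_a + self.shared

    @property
    def size_b(self) -> int:
        return self.only_b + self.shared

    @property
    def pct_shared_of_a(self) -> float:
        return 100.0 * self.shared / self.size_a if self.size_a else 0.0

    @property
    def pct_shared_of_b(self) -> float:
        return 100.0 * self.shared / self.size_b if self.size_b else 0.0


def venn_overlap(a: TargetSet, b: TargetSet) -> VennResult:
    shared = a.genes & b.genes
    return VennResult(
        only_a=len(a.genes - b.genes),
        only_b=len(b.genes - a.genes),
        shared=len(shared),
    )


def compute_te(
    rpf_counts: Mapping[str, float],
    rna_counts: Mapping[str, float],
    annotation: TranscriptomeAnnotation,
    min_rna_rpkm: float = 1.0,
) -> pd.DataFrame:
    """Translation efficiency per gene: RPKM(RPF) / RPKM(mRNA).

    Densities are reads per kb of canonical transcript per million reads
    in the respective table; genes below ``min_rna_rpkm`` mRNA density
    (or absent from the annotation) are excluded.
    """
    rpf = pd.Series(rpf_counts, dtype=float)
    rna = pd.Series(rna_counts, dtype=float)
    if rpf.sum() <= 0 or rna.sum() <= 0:
        raise ValueError("count tables must have positive totals")
    common = rpf.index.intersection(rna.index)
    rows = []
    for gene in common:
        try:
            t = annotation.canonical(gene)
        except KeyError:
            continue
        kb = t.spliced_length / 1e3
        rpf_density = rpf[gene] / kb / (rpf.sum() / 1e6)
        rna_density = rna[gene] / kb / (rna.sum() / 1e6)
        if rna_density < min_rna_rpkm:
            continue
        rows.append(
            {
                "gene_id": gene,
                "rpf_density": rpf_density,
                "rna_density": rna_density,
                "te": rpf_density / rna_density,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "rpf_density", "rna_density", "te"])


def _exact_tied_rank_p(ranks2: np.ndarray, n1: int, obs_sum2: int) -> float:
    """Exact two-sided p over all C(N, n1) group assignments.

    ``ranks2`` are doubled mid-ranks (integers even with ties). Counts
    subsets of size ``n1`` by doubled rank sum via dynamic programming and
    sums the probability of deviations at least as large as observed.
    """
    N = len(ranks2)
    total2 = int(ranks2.sum())
    # count[k][s] = number of subsets of size k with doubled rank sum s
    count = np.zeros((n1 + 1, total2 + 1), dtype=float)
    count[0, 0] = 1.0
    for r in ranks2:
        count[1 : n1 + 1, r:] += count[0:n1, : total2 + 1 - r]
    center2 = n1 * (N + 1)  # doubled mean of the size-n1 rank sum
    obs_dev = abs(obs_sum2 - center2)
    sums = np.arange(total2 + 1)
    mask = np.abs(sums - center2) >= obs_dev - 1e-9
    from math import comb

    return float(count[n1, mask].sum() / comb(N, n1))


def wilcoxon_two_tailed(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney U) test.

    When both samples have at most 10 observations the p-value is exact:
    the full rank-sum distribution over all group assignments, computed
    on mid-ranks so ties are handled exactly as well. Larger samples use
    the normal approximation with tie and continuity correction. Returns
    ``(U, p)`` with U the Mann-Whitney statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if max(n1, n2) <= 10:
        ranks2 = np.rint(ranks * 2).astype(int)
        p = _exact_tied_rank_p(ranks2, n1, int(round(ranks[:n1].sum() * 2)))
        return u1, min(p, 1.0)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float


@dataclass
class QuartileAssociation:
    """Genes split into quartiles Q1..Q4 of a conditioning variable, with
    response summaries and pairwise Wilcoxon p-values."""

    groups: List[List[str]]  # gene ids, Q1 (lowest) .. Q4 (highest)
    summaries: List[GroupSummary]
    pairwise_p: Dict[str, float]

    @property
    def medians(self) -> List[float]:
        return [s.median for s in self.summaries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [f"Q{i + 1}" for i in range(4)],
                "n": [s.n for s in self.summaries],
                "median": [s.median for s in self.summaries],
                "q1": [s.q1 for s in self.summaries],
                "q3": [s.q3 for s in self.summaries],
            }
        )


def quartile_association(
    conditioning: Mapping[str, float],
    response: Mapping[str, float],
) -> QuartileAssociation:
    """Quartile-group association between two gene-level variables.

    Genes present in both tables are ranked ascending by the conditioning
    value (ties broken by gene id), split into four groups whose sizes
    differ by at most one (remainder assigned to the lower quartiles),
    and the response distribution is summarised and compared between
    adjacent groups and Q1 vs Q4 with the two-tailed Wilcoxon test.
    """
    genes = sorted(set(conditioning) & set(response))
    if len(genes) < 8:
        raise ValueError(f"need >= 8 genes with both values, got {len(genes)}")
    ranked = sorted(genes, key=lambda g: (conditioning[g], g))
    n = len(ranked)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    groups: List[List[str]] = []
    start = 0
    for s in sizes:
        groups.append(ranked[start : start + s])
        start += s

    summaries = []
    values = []
    for group in groups:
        v = np.array([response[g] for g in group], dtype=float)
        values.append(v)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        summaries.append(GroupSummary(n=len(v), median=float(med), q1=float(q1), q3=float(q3)))

    pairwise = {}
    for i in range(3):
        _, p = wilcoxon_two_tailed(values[i], values[i + 1])
        pairwise[f"Q{i + 1}_vs_Q{i + 2}"] = p
    _, p = wilcoxon_two_tailed(values[0], values[3])
    pairwise["Q1_vs_Q4"] = p
    return QuartileAssociation(groups=groups, summaries=summaries, pairwise_p=pairwise)


@dataclass
class BoundShiftResult:
    bound: GroupSummary
    unbound: GroupSummary
    statistic: float
    p: float


def bound_vs_unbound_shift(
    proteomics: pd.DataFrame,
    targets: TargetSet,
    value_column: str = "log2fc",
    min_group: int = 3,
) -> BoundShiftResult:
    """Compare protein fold changes between target-bound and unbound genes."""
    df = proteomics.dropna(subset=[value_column])
    bound_mask = df["gene_id"].isin(targets.genes)
    bound = df.loc[bound_mask, value_column].to_numpy(dtype=float)
    unbound = df.loc[~bound_mask, value_column].to_numpy(dtype=float)
    if len(bound) < min_group or len(unbound) < min_group:
        raise ValueError(
            f"need >= {min_group} proteins per group, got "
            f"{len(bound)} bound / {len(unbound)} unbound"
        )
    stat, p = wilcoxon_two_tailed(bound, unbound)

    def summarise(v: np.ndarray) -> GroupSummary:
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return GroupSummary(n=len(v), median=float(med), q1=float(q1), q3=float(q3))

    return BoundShiftResult(
        bound=summarise(bound), unbound=summarise(unbound), statistic=stat, p=p
    )


@dataclass
class DifferentialCounts:
    n_down: int
    n_up: int
    n_tested: int
    n_skipped: int
    table: pd.DataFrame  # gene_id, log2fc, p, direction


def count_differential(
    proteomics: pd.DataFrame,
    cond_a_cols: Sequence[str],
    cond_b_cols: Sequence[str],
    alpha: float = 0.05,
    log_input: bool = True,
) -> DifferentialCounts:
    """Per-protein differential test between two replicate groups.

    Welch's unequal-variance t-test on log2 intensities; proteins with
    fewer than two valid replicates in either condition are skipped and
    tallied. Direction is the sign of mean(B) - mean(A): a negative
    difference counts as down-regulated in condition B.
    """
    rows = []
    n_skipped = 0
    for _, row in proteomics.iterrows():
        a = row[list(cond_a_cols)].to_numpy(dtype=float)
        b = row[list(cond_b_cols)].to_numpy(dtype=float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            n_skipped += 1
            continue
        if not log_input:
            if (a <= 0).any() or (b <= 0).any():
                n_skipped += 1
                continue
            a, b = np.log2(a), np.log2(b)
        diff = float(b.mean() - a.mean())
        if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and np.isclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        direction = "none"
        if p < alpha and diff < 0:
            direction = "down"
        elif p < alpha and diff > 0:
            direction = "up"
        rows.append(
            {"gene_id": row["gene_id"], "log2fc": diff, "p": p, "direction": direction}
        )
    table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p", "direction"])
    return DifferentialCounts(
        n_down=int((table["direction"] == "down").sum()) if len(table) else 0,
        n_up=int((table["direction"] == "up").sum()) if len(table) else 0,
        n_tested=len(table),
        n_skipped=n_skipped,
        table=table,
    )
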