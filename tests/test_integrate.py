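"""Target sets, Venn overlaps, TE, Wilcoxon machinery and proteomics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lacebind as lb
from lacebind.integrate import (
    TargetSet,
    bound_vs_unbound_shift,
    compute_te,
    count_differential,
    derive_target_set,
    quartile_association,
    venn_overlap,
    wilcoxon_two_tailed,
)
from lacebind.signal import Peak
from lacebind.transcriptome import GenomicInterval

from conftest import make_annotation, single_exon_transcript


def peak_for(gene):
    return Peak(
        interval=GenomicInterval("chr1", 0, 10, "+"), summit=0, gene_id=gene
    )


class TestTargetSet:
    def test_gene_collection_and_min_peaks(self):
        peaks = [peak_for(g) for g in ["A", "A", "B"]]
        assert derive_target_set(peaks).genes == {"A", "B"}
        assert derive_target_set(peaks, min_peaks=2).genes == {"A"}
        assert derive_target_set([]).genes == frozenset()


class TestVenn:
    def test_overlap_percentages_from_counts(self):
        """Set arithmetic on sets with the published cardinalities:
        1016 specific + 905 shared targets -> 1921 total, 47.1% shared;
        552 polyadenylated genes with 312 shared -> 56.5%, 128 -> 23.2%."""
        a = TargetSet("rbp_targets", frozenset(f"a{i}" for i in range(1016)) | frozenset(f"s{i}" for i in range(905)))
        b = TargetSet("other", frozenset(f"b{i}" for i in range(926)) | frozenset(f"s{i}" for i in range(905)))
        v = venn_overlap(a, b)
        assert v.size_a == 1921
        assert v.shared == 905
        assert round(v.pct_shared_of_a, 1) == 47.1

        polya = TargetSet("polya", frozenset(f"p{i}" for i in range(552)))
        targets = TargetSet("t", frozenset(f"p{i}" for i in range(312)) | frozenset(f"x{i}" for i in range(1609)))
        specific = TargetSet("spec", frozenset(f"p{i}" for i in range(128)) | frozenset(f"y{i}" for i in range(888)))
        assert round(venn_overlap(polya, targets).pct_shared_of_a, 1) == 56.5
        assert round(venn_overlap(polya, specific).pct_shared_of_a, 1) == 23.2

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        a=st.sets(st.integers(0, 60)),
        b=st.sets(st.integers(0, 60)),
    )
    def test_counts_consistent_for_arbitrary_sets(self, a, b):
        v = venn_overlap(
            TargetSet("a", frozenset(map(str, a))),
            TargetSet("b", frozenset(map(str, b))),
        )
        assert v.only_a + v.shared == len(a)
        assert v.only_b + v.shared == len(b)
        assert 0 <= v.pct_shared_of_a <= 100
        if a:
            assert v.pct_shared_of_a == pytest.approx(100 * len(a & b) / len(a))

    def test_disjoint_sets(self):
        v = venn_overlap(TargetSet("a", frozenset("xy")), TargetSet("b", frozenset("zw")))
        assert v.shared == 0
        assert v.pct_shared_of_a == 0 and v.pct_shared_of_b == 0

    def test_matches_brute_force_set_arithmetic_on_random_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            universe = [f"g{i}" for i in range(200)]
            a = frozenset(rng.choice(universe, rng.integers(1, 150), replace=False))
            b = frozenset(rng.choice(universe, rng.integers(1, 150), replace=False))
            v = venn_overlap(TargetSet("a", a), TargetSet("b", b))
            assert v.only_a == len(a - b)
            assert v.only_b == len(b - a)
            assert v.shared == len(a & b)
            assert v.only_a + v.shared == len(a)
            assert v.pct_shared_of_a == pytest.approx(100 * len(a & b) / len(a))


class TestComputeTE:
    def make_annotation_kb(self):
        return make_annotation(
            [
                single_exon_transcript("T1", "G1", start=0, length=1000),
                single_exon_transcript("T2", "G2", start=2000, length=2000),
            ]
        )

    def test_te_is_density_ratio(self):
        ann = self.make_annotation_kb()
        # equal totals; G1: rpf 10 / rna 40 -> te 0.25; G2: equal -> te 1
        te = compute_te(
            {"G1": 10, "G2": 90}, {"G1": 40, "G2": 60}, ann, min_rna_rpkm=0
        )
        te = te.set_index("gene_id")
        assert te.loc["G1", "te"] == pytest.approx(0.25)
        assert te.loc["G2", "te"] == pytest.approx(
            (90 / 2) / (60 / 2) * (100 / 100)
        )

    def test_low_rna_and_unknown_genes_excluded(self):
        ann = self.make_annotation_kb()
        te = compute_te(
            {"G1": 10, "G2": 10, "G9": 5},
            {"G1": 0, "G2": 10, "G9": 5},
            ann,
            min_rna_rpkm=1.0,
        )
        assert set(te["gene_id"]) == {"G2"}  # G1 rna=0, G9 unannotated


def enumeration_oracle_p(x, y):
    """Exhaustive two-sided rank-sum p over all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    mean = n1 * len(y) / 2
    obs = ranks[: n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestWilcoxon:
    def test_separated_triples_exact_p(self):
        stat, p = wilcoxon_two_tailed([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 extreme tables / 20

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_two_tailed([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_two_tailed([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(1, 4), (2, 5), (3, 3), (4, 6), (8, 8), (5, 8)])
    def test_exact_branch_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for tied in (False, True):
            if tied:
                x = rng.integers(0, 5, n1).astype(float)
                y = rng.integers(0, 5, n2).astype(float)
            else:
                x = rng.normal(size=n1)
                y = rng.normal(size=n2) + 0.5
            _, p = wilcoxon_two_tailed(x, y)
            assert p == pytest.approx(enumeration_oracle_p(x, y), abs=1e-9)

    def test_asymptotic_branch_close_to_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=9)
        y = rng.normal(size=12) + 0.4
        _, p = wilcoxon_two_tailed(x, y)
        assert abs(p - enumeration_oracle_p(x, y)) <= 0.01


class TestQuartileAssociation:
    def test_monotone_response_gives_monotone_medians(self):
        cond = {f"g{i}": float(i) for i in range(40)}
        resp = {f"g{i}": float(i) ** 2 for i in range(40)}
        qa = quartile_association(cond, resp)
        assert qa.medians == sorted(qa.medians)
        assert qa.medians[0] < qa.medians[3]

    def test_remainder_assigned_to_lower_quartiles(self):
        cond = {f"g{i}": float(i) for i in range(10)}
        resp = {f"g{i}": 1.0 * i for i in range(10)}
        qa = quartile_association(cond, resp)
        assert [s.n for s in qa.summaries] == [3, 3, 2, 2]

    def test_groups_partition_and_are_order_invariant(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(23)]
        cond = {g: float(v) for g, v in zip(genes, rng.integers(0, 5, 23))}
        resp = {g: float(v) for g, v in zip(genes, rng.normal(size=23))}
        qa1 = quartile_association(cond, resp)
        shuffled = dict(reversed(list(cond.items())))
        qa2 = quartile_association(shuffled, resp)
        assert qa1.groups == qa2.groups
        flat = [g for grp in qa1.groups for g in grp]
        assert sorted(flat) == sorted(genes)

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            quartile_association({"a": 1.0}, {"a": 2.0})

    def test_independent_variables_rarely_reject(self):
        """Null calibration: unlinked conditioning/response, n=400, 20 seeds
        -> Q1-vs-Q4 rejects at most at the nominal rate (binomial slack)."""
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(400)]
            cond = dict(zip(genes, rng.normal(size=400)))
            resp = dict(zip(genes, rng.normal(size=400)))
            qa = quartile_association(cond, resp)
            rejections += qa.pairwise_p["Q1_vs_Q4"] < 0.05
        assert rejections <= 3


class TestBoundVsUnbound:
    def make_proteomics(self, bound_shift, n=50, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"b{i}" for i in range(n)] + [f"u{i}" for i in range(n)]
        fc = np.concatenate(
            [rng.normal(-bound_shift, 0.3, n), rng.normal(0, 0.3, n)]
        )
        return pd.DataFrame({"gene_id": genes, "log2fc": fc})

    def test_planted_unit_shift_detected(self):
        df = self.make_proteomics(bound_shift=1.0)
        targets = TargetSet("t", frozenset(f"b{i}" for i in range(50)))
        res = bound_vs_unbound_shift(df, targets)
        assert res.bound.median == pytest.approx(res.unbound.median - 1.0, abs=0.25)
        assert res.p < 0.05

    def test_disjoint_targets_error(self):
        df = self.make_proteomics(bound_shift=0.0)
        targets = TargetSet("t", frozenset({"zz1", "zz2", "zz3"}))
        with pytest.raises(ValueError, match="bound"):
            bound_vs_unbound_shift(df, targets)

    def test_null_type_one_error_rate(self):
        rejections = 0
        for seed in range(20):
            df = self.make_proteomics(bound_shift=0.0, seed=seed)
            targets = TargetSet("t", frozenset(f"b{i}" for i in range(50)))
            rejections += bound_vs_unbound_shift(df, targets).p < 0.05
        assert rejections <= 3


class TestCountDifferential:
    def test_identical_replicates_yield_no_calls(self):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(5)],
                "wt_1": 1.0, "wt_2": 2.0, "wt_3": 3.0,
                "cko_1": 1.0, "cko_2": 2.0, "cko_3": 3.0,
            }
        )
        res = count_differential(df, ["wt_1", "wt_2", "wt_3"], ["cko_1", "cko_2", "cko_3"])
        assert (res.n_down, res.n_up) == (0, 0)

    def test_alpha_one_classifies_every_testable_protein(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                **{f"wt_{r}": rng.normal(10, 1, 20) for r in (1, 2, 3)},
                **{f"cko_{r}": rng.normal(10, 1, 20) for r in (1, 2, 3)},
            }
        )
        res = count_differential(
            df, ["wt_1", "wt_2", "wt_3"], ["cko_1", "cko_2", "cko_3"], alpha=1.0
        )
        assert res.n_down + res.n_up == res.n_tested == 20

    def test_planted_fourfold_decrease_all_detected(self):
        """10 of 100 proteins carry a 4-fold (2 log2 units) decrease with
        sd 0.1: all 10 must be called down; noise-only false downs stay
        within a binomial bound on 90 null tests at alpha 0.05."""
        rng = np.random.default_rng(11)
        n = 100
        base = rng.normal(20, 1, n)
        shift = np.zeros(n)
        shift[:10] = 2.0
        cols = {}
        for r in (1, 2, 3):
            cols[f"wt_{r}"] = base + rng.normal(0, 0.1, n)
            cols[f"cko_{r}"] = base - shift + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)], **cols})
        res = count_differential(df, ["wt_1", "wt_2", "wt_3"], ["cko_1", "cko_2", "cko_3"])
        planted_down = set(res.table.loc[res.table["direction"] == "down", "gene_id"])
        assert {f"g{i}" for i in range(10)} <= planted_down
        assert res.n_down - 10 <= 9  # 3 binomial SDs above 90 * 0.025

    def test_insufficient_replicates_skipped(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "wt_1": [1.0, 1.0], "wt_2": [np.nan, 2.0],
                "cko_1": [1.0, 5.0], "cko_2": [2.0, 6.0],
            }
        )
        res = count_differential(df, ["wt_1", "wt_2"], ["cko_1", "cko_2"])
        assert res.n_skipped == 1
        assert res.n_tested == 1
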