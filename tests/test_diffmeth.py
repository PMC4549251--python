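"""Beta values, QC, signed-rank test, DM classification, island annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucmeth import diffmeth
from nucmeth.intervals import IntervalSet


class TestBetaValues:
    @pytest.mark.parametrize(
        "M,U,expect", [(100, 100, 0.5), (50, 0, 1.0), (300, 100, 0.75), (0, 80, 0.0)]
    )
    def test_formula(self, M, U, expect):
        assert diffmeth.beta_values(M, U) == pytest.approx(expect)

    def test_zero_total_is_missing(self):
        out = diffmeth.beta_values([10, 0], [10, 0])
        assert out[0] == 0.5 and np.isnan(out[1])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            diffmeth.beta_values(-1, 10)


class TestQcFilter:
    def _tables(self):
        beta = pd.DataFrame(
            np.full((100, 3), 0.5), columns=["s1", "s2", "s3"],
            index=[f"cg{i}" for i in range(100)],
        )
        detp = pd.DataFrame(
            np.full((100, 3), 0.001), columns=beta.columns, index=beta.index
        )
        return beta, detp

    def test_boundary_p_values(self):
        beta, detp = self._tables()
        detp.iloc[0, 0] = 0.06  # > 0.05: masked
        detp.iloc[1, 1] = 0.05  # exactly 0.05: kept
        out, ledger = diffmeth.qc_filter(beta, detp)
        assert np.isnan(out.iloc[0, 0]) and out.iloc[1, 1] == 0.5
        assert ledger["masked_measures"] == 1

    def test_sample_below_95_pct_removed(self):
        beta, detp = self._tables()
        detp.iloc[:6, 0] = 0.5  # 94% passing probes in s1
        out, ledger = diffmeth.qc_filter(beta, detp)
        assert "s1" not in out.columns and ledger["removed_samples"] == ["s1"]

    def test_clean_table_unchanged(self):
        beta, detp = self._tables()
        out, ledger = diffmeth.qc_filter(beta, detp)
        pd.testing.assert_frame_equal(out, beta)
        assert ledger["masked_measures"] == 0 and ledger["removed_samples"] == []

    def test_all_samples_removed_fails(self):
        beta, detp = self._tables()
        detp.iloc[:, :] = 0.5
        with pytest.raises(ValueError):
            diffmeth.qc_filter(beta, detp)


def brute_force_signed_rank_p(diff):
    """Exhaustive 2^n enumeration of the two-sided signed-rank p-value."""
    from itertools import product

    from scipy import stats

    d = diff[diff != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    half = (ranks.sum()) / 2  # for two-sidedness via min tail
    count_le = count_ge = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs:
            count_le += 1
        if w >= w_obs:
            count_ge += 1
    total = 2**n
    return min(1.0, 2 * min(count_le, count_ge) / total)


class TestGlobalShiftTest:
    def test_identical_vectors_degenerate(self):
        x = np.linspace(0.1, 0.9, 20)
        stat, p = diffmeth.global_shift_test(x, x)
        assert stat == 0.0 and p == 1.0

    def test_six_positive_differences_exact(self):
        u = np.full(6, 0.2)
        t = u + np.arange(1, 7) * 0.01
        _, p = diffmeth.global_shift_test(t, u)
        assert p == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        u = rng.uniform(0.1, 0.9, n)
        t = np.clip(u + rng.normal(0, 0.1, n), 0.01, 0.99)
        _, p = diffmeth.global_shift_test(t, u)
        assert p == pytest.approx(brute_force_signed_rank_p(t - u))

    def test_ties_use_midranks_and_match_oracle(self):
        u = np.zeros(8)
        t = np.array([0.1, 0.1, -0.1, 0.2, 0.2, -0.2, 0.3, 0.3])
        _, p = diffmeth.global_shift_test(t, u)
        assert p == pytest.approx(brute_force_signed_rank_p(t))

    def test_large_n_uses_normal_approximation(self, rng):
        u = rng.uniform(0.1, 0.9, 200)
        t = np.clip(u + 0.05 + rng.normal(0, 0.02, 200), 0.01, 0.99)
        _, p = diffmeth.global_shift_test(t, u)
        assert p < 1e-10  # strong planted global shift detected


class TestClassifyDm:
    def test_hyper_example(self):
        out = diffmeth.classify_dm(0.42, 0.10)
        assert out.iloc[0]["dm_class"] == "hyper"
        assert out.iloc[0]["log2_fc"] == pytest.approx(np.log2(4.2))

    def test_exact_doubling_is_unchanged(self):
        out = diffmeth.classify_dm(0.2, 0.1)
        assert out.iloc[0]["log2_fc"] == pytest.approx(1.0)
        assert out.iloc[0]["dm_class"] == "unchanged"

    def test_equal_betas_unchanged(self):
        assert diffmeth.classify_dm(0.5, 0.5).iloc[0]["dm_class"] == "unchanged"

    def test_floor_keeps_rule_total_at_zero_beta(self):
        out = diffmeth.classify_dm(0.5, 0.0)
        assert out.iloc[0]["dm_class"] == "hyper"

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_antisymmetry(self, a, b):
        fwd = diffmeth.classify_dm(a, b).iloc[0]["dm_class"]
        rev = diffmeth.classify_dm(b, a).iloc[0]["dm_class"]
        swap = {"hyper": "hypo", "hypo": "hyper", "unchanged": "unchanged"}
        assert rev == swap[fwd]

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        t = rng.uniform(0, 1, 10_000)
        u = rng.uniform(0, 1, 10_000)
        out = diffmeth.classify_dm(t, u)
        fc = np.log2(np.maximum(t, 1e-6) / np.maximum(u, 1e-6))
        expect = np.where(fc > 1, "hyper", np.where(fc < -1, "hypo", "unchanged"))
        assert (out["dm_class"].to_numpy() == expect).all()

    def test_partition_is_exact(self, rng):
        out = diffmeth.classify_dm(rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000))
        assert out["dm_class"].isin(["hyper", "hypo", "unchanged"]).all()
        assert len(out) == 1000


def brute_force_islands(seq, min_len=200, min_gc=0.5, min_oe=0.6):
    """O(L * min_len) window scan: union of all qualifying windows."""
    L = len(seq)
    good = np.zeros(L, dtype=bool)
    for s in range(L - min_len + 1):
        w = seq[s : s + min_len]
        n_c, n_g = w.count("C"), w.count("G")
        n_cpg = sum(1 for i in range(min_len - 1) if w[i : i + 2] == "CG")
        if (n_c + n_g) / min_len > min_gc and n_c > 0 and n_g > 0:
            if n_cpg * min_len / (n_c * n_g) > min_oe:
                good[s : s + min_len] = True
    # maximal runs
    out = []
    i = 0
    while i < L:
        if good[i]:
            j = i
            while j < L and good[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


class TestDetectCpgIslands:
    def test_cg_repeat_is_one_island(self):
        seq = "CG" * 150 + "A" * 500
        islands = diffmeth.detect_cpg_islands(seq)
        assert len(islands) == 1
        row = islands.df.iloc[0]
        assert row["start"] == 0 and row["end"] >= 300

    def test_poly_a_has_no_island(self):
        assert len(diffmeth.detect_cpg_islands("A" * 400)) == 0

    def test_matches_window_scan_oracle(self, rng):
        # GC-rich patches on an AT background so both outcomes occur
        parts = []
        for _ in range(40):
            parts.append("".join(rng.choice(list("AT"), size=int(rng.integers(100, 400)))))
            parts.append("".join(rng.choice(list("ACGT"), p=[0.15, 0.35, 0.35, 0.15],
                                            size=int(rng.integers(150, 500)))))
        seq = "".join(parts)[:20_000]
        got = [
            (r["start"], r["end"]) for _, r in diffmeth.detect_cpg_islands(seq).df.iterrows()
        ]
        assert got == brute_force_islands(seq)

    def test_islands_never_overlap_and_remeasure_clean(self, rng):
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=30_000))
        islands = diffmeth.detect_cpg_islands(seq)
        df = islands.df
        for i in range(1, len(df)):
            assert df["start"].iloc[i] >= df["end"].iloc[i - 1]
        for _, r in df.iterrows():
            w = seq[r["start"] : r["end"]]
            # islands are unions of qualifying 200-mers: at least one interior
            # window must satisfy all thresholds
            assert any(
                True
                for s, e in brute_force_islands(w)
            ) or len(w) >= 200


class TestAnnotateIslandContext:
    @pytest.fixture
    def islands(self):
        return IntervalSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_500]})
        )

    @pytest.mark.parametrize(
        "pos,expect",
        [
            (10_200, "island"),
            (10_499, "island"),
            (9_999, "shore"),  # 1 bp from the start edge
            (8_500, "shore"),
            (8_000, "shore"),  # exactly 2,000 bp -> shore
            (7_999, "shelf"),
            (7_000, "shelf"),
            (6_000, "shelf"),  # exactly 4,000 bp -> shelf
            (5_999, "open sea"),
            (20_500, "open sea"),
            (12_499, "shore"),  # downstream symmetric
        ],
    )
    def test_distance_rules(self, islands, pos, expect):
        assert diffmeth.annotate_island_context(pos, islands)[0] == expect

    def test_no_islands_everything_open_sea(self):
        out = diffmeth.annotate_island_context([1, 100, 10_000], IntervalSet())
        assert (out == "open sea").all()


class TestAnnotateFunctionalRegion:
    @pytest.fixture
    def genes(self):
        return pd.DataFrame(
            [
                {
                    "gene": "plus",
                    "chrom": "chr1",
                    "strand": "+",
                    "tss": 10_000,
                    "tx_start": 10_000,
                    "tx_end": 20_000,
                    "utr5_start": 10_000,
                    "utr5_end": 10_300,
                    "first_exon_start": 10_000,
                    "first_exon_end": 10_800,
                    "utr3_start": 19_500,
                    "utr3_end": 20_000,
                },
                {
                    "gene": "minus",
                    "chrom": "chr1",
                    "strand": "-",
                    "tss": 59_999,
                    "tx_start": 50_000,
                    "tx_end": 60_000,
                    "utr5_start": 59_700,
                    "utr5_end": 60_000,
                    "first_exon_start": 59_200,
                    "first_exon_end": 60_000,
                    "utr3_start": 50_000,
                    "utr3_end": 50_500,
                },
            ]
        )

    @pytest.mark.parametrize(
        "pos,expect",
        [
            (9_850, "TSS200"),
            (9_700, "TSS1500"),
            (8_501, "TSS1500"),
            (8_499, "intergenic"),
            (10_100, "5'UTR"),
            (10_500, "1stExon"),
            (15_000, "gene body"),
            (19_700, "3'UTR"),
            (30_000, "intergenic"),
            (60_100, "TSS200"),  # minus-strand upstream is genomic right
            (61_000, "TSS1500"),
            (59_800, "5'UTR"),
            (55_000, "gene body"),
            (50_200, "3'UTR"),
        ],
    )
    def test_category_rules(self, genes, pos, expect):
        assert diffmeth.annotate_functional_region(pos, genes)[0] == expect

    def test_precedence_matches_all_rules_oracle(self, genes, rng):
        pos = rng.integers(0, 70_000, 500)
        got = diffmeth.annotate_functional_region(pos, genes)
        for p, lab in zip(pos, got):
            cats = []
            for g in genes.itertuples():
                if g.strand == "+":
                    if g.tss - 200 <= p < g.tss:
                        cats.append("TSS200")
                    if g.tss - 1500 <= p < g.tss:
                        cats.append("TSS1500")
                else:
                    if g.tss < p <= g.tss + 200:
                        cats.append("TSS200")
                    if g.tss < p <= g.tss + 1500:
                        cats.append("TSS1500")
                in_feature = False
                if g.utr5_start <= p < g.utr5_end:
                    cats.append("5'UTR")
                    in_feature = True
                if g.first_exon_start <= p < g.first_exon_end:
                    cats.append("1stExon")
                    in_feature = True
                if g.utr3_start <= p < g.utr3_end:
                    cats.append("3'UTR")
                    in_feature = True
                if not in_feature and g.tx_start <= p < g.tx_end:
                    cats.append("gene body")
            if cats:
                order = diffmeth.FUNCTIONAL_PRECEDENCE
                expect = min(cats, key=order.index)
            else:
                expect = "intergenic"
            assert lab == expect

    def test_promoter_collapse(self):
        labels = np.array(["TSS200", "TSS1500", "gene body"], dtype=object)
        out = diffmeth.collapse_promoter(labels)
        assert out.tolist() == ["promoter", "promoter", "gene body"]


class TestSummarizeDm:
    def test_printed_count_fixture_percentages(self):
        # per-category totals: promoter 641, gene body 243, 3'UTR 19,
        # intergenic 150 (rest "other"); island 661, shore 280, shelf 32,
        # open sea 229.  The island-axis counts sum to 1,202 while the
        # reported differential total is 1,201, so the percentage denominator
        # is the reported total, not the axis sum.
        func = (
            ["promoter"] * 641 + ["gene body"] * 243 + ["3'UTR"] * 19
            + ["intergenic"] * 150 + ["other"] * 149
        )
        ctx = ["island"] * 661 + ["shore"] * 280 + ["shelf"] * 32 + ["open sea"] * 229
        n = 1202
        results = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "dm_class": ["hyper"] * 869 + ["hypo"] * 333,
            }
        )
        anno = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "functional": func,
                "cpg_context": ctx,
            }
        )
        out = diffmeth.summarize_dm(results, anno, total=1201)
        f = out["functional"]
        assert f.loc["promoter", "percentage"] == 53.37
        assert f.loc["gene body", "percentage"] == 20.23
        assert f.loc["3'UTR", "percentage"] == 1.58
        assert f.loc["intergenic", "percentage"] == 12.49
        c = out["cpg_context"]
        assert c.loc["island", "percentage"] == 55.04
        assert c.loc["shore", "percentage"] == 23.31
        assert c.loc["shelf", "percentage"] == 2.66
        assert c.loc["open sea", "percentage"] == 19.07

    def test_single_category_hundred_percent(self):
        results = pd.DataFrame({"probe_id": ["a", "b"], "dm_class": ["hyper", "hypo"]})
        anno = pd.DataFrame(
            {"probe_id": ["a", "b"], "functional": ["promoter"] * 2,
             "cpg_context": ["island"] * 2}
        )
        out = diffmeth.summarize_dm(results, anno)
        assert out["functional"].loc["promoter", "percentage"] == 100.00

    def test_counts_match_group_by_oracle(self, rng):
        n = 500
        results = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "dm_class": rng.choice(["hyper", "hypo", "unchanged"], n),
            }
        )
        anno = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "functional": rng.choice(["promoter", "gene body", "intergenic"], n),
                "cpg_context": rng.choice(["island", "shore", "open sea"], n),
            }
        )
        out = diffmeth.summarize_dm(results, anno)
        diff = results[results["dm_class"] != "unchanged"].merge(anno, on="probe_id")
        for cat, cnt in diff["functional"].value_counts().items():
            assert out["functional"].loc[cat, "count"] == cnt

    def test_zero_differential_sites(self):
        results = pd.DataFrame({"probe_id": ["a"], "dm_class": ["unchanged"]})
        anno = pd.DataFrame(
            {"probe_id": ["a"], "functional": ["promoter"], "cpg_context": ["island"]}
        )
        out = diffmeth.summarize_dm(results, anno)
        assert out["total"] == 0 and len(out["functional"]) == 0


class TestHyperHypoGeneSets:
    def test_gene_with_both_directions(self):
        results = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "dm_class": ["hyper", "hypo"]}
        )
        gmap = pd.DataFrame({"probe_id": ["p1", "p2"], "gene": ["G", "G"]})
        out = diffmeth.hyper_hypo_gene_sets(results, gmap)
        assert out["both"] == {"G"} and not out["hyper_only"] and not out["hypo_only"]

    def test_region_resolved_pairs(self):
        results = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "dm_class": ["hypo", "hyper"]}
        )
        gmap = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "gene": ["G", "G"],
             "region": ["promoter", "gene body"]}
        )
        out = diffmeth.hyper_hypo_gene_sets(results, gmap)
        assert out["both_regions"]["G"] == [("gene body", "hyper"), ("promoter", "hypo")]

    def test_partition_matches_set_algebra_oracle(self, rng):
        n = 300
        results = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "dm_class": rng.choice(["hyper", "hypo", "unchanged"], n),
            }
        )
        gmap = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(n)],
             "gene": rng.choice([f"G{j}" for j in range(40)], n)}
        )
        out = diffmeth.hyper_hypo_gene_sets(results, gmap)
        diff = results[results["dm_class"] != "unchanged"].merge(gmap, on="probe_id")
        hyper_genes = set(diff.loc[diff["dm_class"] == "hyper", "gene"])
        hypo_genes = set(diff.loc[diff["dm_class"] == "hypo", "gene"])
        assert out["both"] == hyper_genes & hypo_genes
        assert out["hyper_only"] == hyper_genes - hypo_genes
        assert out["hypo_only"] == hypo_genes - hyper_genes
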