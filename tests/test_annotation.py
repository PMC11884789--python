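"""Feature annotation, observed/expected enrichment, gene-level tables."""

import numpy as np
import pandas as pd
import pytest

from rloopkit.annotation import (
    FeatureMap,
    assign_feature,
    category_proportions,
    classify_tf_peak_proximity,
    expression_tertiles,
    gene_rloop_overlap,
    length_distribution,
    observed_expected,
    tss_tes_profile,
)
from rloopkit.core import GeneModel, GenomicInterval
from rloopkit.simulate import SimConfig, make_genome


class TestAssignFeature:
    # toy_genes: gA plus-strand [10000,20000) with exons, gB minus-strand
    # pseudogene [40000,50000)

    def test_promoter_window_plus_strand(self, toy_genes, toy_sizes):
        # midpoint 1 kb upstream of the plus-strand TSS at 10000
        iv = GenomicInterval("chr1", 8900, 9100)
        assert assign_feature(iv, toy_genes, toy_sizes) == "promoter-TSS"

    def test_downstream_window_plus_strand(self, toy_genes, toy_sizes):
        # midpoint 1 kb past the gene end at 20000
        iv = GenomicInterval("chr1", 20900, 21100)
        assert assign_feature(iv, toy_genes, toy_sizes) == "downstream-TTS"

    def test_far_from_everything_is_intergenic(self, toy_genes, toy_sizes):
        iv = GenomicInterval("chr1", 90000, 90200)
        assert assign_feature(iv, toy_genes, toy_sizes) == "intergenic"

    def test_exon_and_intron(self, toy_genes, toy_sizes):
        fmap = FeatureMap(toy_sizes, toy_genes)
        assert fmap.assign(GenomicInterval("chr1", 10900, 11100)) == "exon"
        assert fmap.assign(GenomicInterval("chr1", 12900, 13100)) == "intron"

    def test_pseudogene_overrides_feature_name(self, toy_genes, toy_sizes):
        # minus-strand pseudogene: promoter window sits at [49500, 52500)
        fmap = FeatureMap(toy_sizes, toy_genes)
        assert fmap.assign(GenomicInterval("chr1", 44900, 45100)) == "pseudogene"
        assert fmap.assign(GenomicInterval("chr1", 50900, 51100)) == "pseudogene"

    def test_minus_strand_promoter_orientation(self, toy_sizes):
        # minus-strand gene [40000, 50000): TSS at 50000, upstream is right
        gene = GeneModel("g", "chr1", "-", 40000, 50000, exons=[(40000, 50000)])
        fmap = FeatureMap(toy_sizes, [gene])
        assert fmap.assign(GenomicInterval("chr1", 51000, 51002)) == "promoter-TSS"
        assert fmap.assign(GenomicInterval("chr1", 39000, 39002)) == "downstream-TTS"

    def test_no_genes_everything_intergenic(self, toy_sizes):
        iv = GenomicInterval("chr1", 100, 200)
        assert assign_feature(iv, [], toy_sizes) == "intergenic"


class TestObservedExpected:
    def test_uniform_midpoints_calibrated(self):
        cfg = SimConfig(genome_length=1_000_000, n_genes=60, seed=5)
        sizes, genes = make_genome(cfg)
        fmap = FeatureMap(sizes, genes)
        rng = np.random.default_rng(6)
        n = 1000
        chroms = list(sizes)
        lens = np.array([sizes[c] for c in chroms], dtype=float)
        idx = rng.choice(len(chroms), size=n, p=lens / lens.sum())
        mids = (rng.random(n) * lens[idx]).astype(int)
        rloops = pd.DataFrame(
            {"chrom": [chroms[i] for i in idx],
             "start": np.maximum(mids - 50, 0), "end": mids + 50}
        )
        rloops["start"] = mids  # midpoint == mids exactly
        rloops["end"] = mids + 1
        tab = observed_expected(rloops, genes, sizes, fmap)
        shares = fmap.genome_shares()
        for _, row in tab.iterrows():
            share = shares[row["feature"]]
            if share == 0:
                continue
            se = np.sqrt(n * share * (1 - share))
            assert abs(row["observed"] - row["expected"]) <= 3 * se + 1e-9, row

    def test_all_promoter_ratio_is_inverse_share(self):
        cfg = SimConfig(genome_length=500_000, n_genes=40, seed=8)
        sizes, genes = make_genome(cfg)
        fmap = FeatureMap(sizes, genes)
        promoter_positions = []
        for chrom, arr in fmap.arrays.items():
            pos = np.flatnonzero(arr == 4)  # promoter code
            promoter_positions += [(chrom, int(p)) for p in pos[:: max(len(pos) // 50, 1)]]
        rloops = pd.DataFrame(
            {"chrom": [c for c, _ in promoter_positions],
             "start": [p for _, p in promoter_positions],
             "end": [p + 1 for _, p in promoter_positions]}
        )
        tab = observed_expected(rloops, genes, sizes, fmap).set_index("feature")
        share = fmap.genome_shares()["promoter-TSS"]
        assert tab.loc["promoter-TSS", "ratio"] == pytest.approx(1 / share, rel=1e-12)

    def test_observed_sums_to_n(self, toy_genes, toy_sizes):
        rloops = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [9000, 15000, 90000],
             "end": [9100, 15100, 90100]}
        )
        tab = observed_expected(rloops, toy_genes, toy_sizes)
        assert tab["observed"].sum() == 3

    def test_zero_rloops_rejected(self, toy_genes, toy_sizes):
        with pytest.raises(ValueError):
            observed_expected(
                pd.DataFrame(columns=["chrom", "start", "end"]), toy_genes, toy_sizes
            )


class TestTssTesProfile:
    def test_centered_on_tss_lands_in_zero_bin(self, toy_genes):
        rl = pd.DataFrame({"chrom": ["chr1"], "start": [9950], "end": [10050]})
        prof = tss_tes_profile(rl, toy_genes, flank=1000, n_bins=10)
        zero_bin = prof[(prof["bin_start"] <= 0) & (prof["bin_end"] > 0)]
        assert zero_bin["tss"].iloc[0] == 1

    def test_minus_strand_orientation_rule(self):
        """For a minus-strand gene, genomic-left of the TSS is downstream,
        so the signed distance is positive."""
        gene = GeneModel("g", "chr1", "-", 40000, 50000, exons=[(40000, 50000)])
        rl = pd.DataFrame({"chrom": ["chr1"], "start": [48999], "end": [49001]})
        prof = tss_tes_profile(rl, [gene], flank=2000, n_bins=4)
        # midpoint 49000 is 1000 bp left of TSS 50000 -> +1000 downstream
        hit = prof[(prof["bin_start"] <= 1000) & (prof["bin_end"] > 1000)]
        assert hit["tss"].iloc[0] == 1
        assert prof[prof["bin_end"] <= 0]["tss"].sum() == 0

    def test_planted_at_tss_mode_at_zero(self):
        cfg = SimConfig(genome_length=500_000, n_genes=40, seed=9)
        sizes, genes = make_genome(cfg)
        rl = pd.DataFrame(
            {"chrom": [g.chrom for g in genes[:20]],
             "start": [g.tss - 1 if g.strand == "-" else g.tss for g in genes[:20]],
             "end": [g.tss + 1 if g.strand == "-" else g.tss + 2 for g in genes[:20]]}
        )
        prof = tss_tes_profile(rl, genes, flank=5000, n_bins=10)
        center = prof[(prof["bin_start"] <= 0) & (prof["bin_end"] > 0)]
        assert center["tss"].iloc[0] == prof["tss"].max() > 0


class TestTfProximity:
    gene = GeneModel("g", "chr1", "+", 10000, 20000, exons=[(10000, 20000)])

    def test_500bp_upstream_is_proximal(self):
        peak = GenomicInterval("chr1", 9400, 9600)
        assert classify_tf_peak_proximity(peak, self.gene) == "proximal"

    def test_5kb_upstream_is_distal(self):
        peak = GenomicInterval("chr1", 4900, 5100)
        assert classify_tf_peak_proximity(peak, self.gene) == "distal"

    def test_inside_gene_body_is_proximal(self):
        peak = GenomicInterval("chr1", 15000, 15200)
        assert classify_tf_peak_proximity(peak, self.gene) == "proximal"

    def test_margin_zero_reduces_to_body_overlap(self):
        peak = GenomicInterval("chr1", 9400, 9600)
        assert classify_tf_peak_proximity(peak, self.gene, margin=0) == "distal"
        touching = GenomicInterval("chr1", 9990, 10010)
        assert classify_tf_peak_proximity(touching, self.gene, margin=0) == "proximal"


class TestExpressionTertiles:
    def test_nine_distinct_cpms_split_3_3_3(self):
        expr = {f"g{i}": float(10 * i) for i in range(1, 10)}
        labels = expression_tertiles(expr)
        counts = pd.Series(labels).value_counts()
        assert counts["low"] == counts["mid"] == counts["high"] == 3
        assert labels["g1"] == "low" and labels["g9"] == "high"

    def test_all_below_threshold_not_expressed(self):
        labels = expression_tertiles({"a": 0.5, "b": 1.0, "c": 0.0})
        assert set(labels.values()) == {"not_expressed"}

    def test_order_invariance(self):
        expr = {f"g{i}": float(v) for i, v in enumerate([5, 3, 9, 2, 7, 8, 4])}
        shuffled = dict(reversed(list(expr.items())))
        assert expression_tertiles(expr) == expression_tertiles(shuffled)

    def test_ties_broken_by_gene_id(self):
        labels = expression_tertiles({"b": 5.0, "a": 5.0, "c": 5.0})
        assert labels == {"a": "low", "b": "mid", "c": "high"}


class _RlSet:
    def __init__(self, stranded, unstranded):
        self.stranded = stranded
        self.unstranded = unstranded


class TestGeneRloopOverlap:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_stranded_only_category(self, toy_genes, toy_sizes):
        rl = _RlSet(self._frame([("chr1", 15000, 15500)]), self._frame([]))
        table = gene_rloop_overlap(rl, toy_genes, toy_sizes)
        assert table.set_index("gene_id").loc["gA", "rloop_category"] == "stranded_only"
        assert table.set_index("gene_id").loc["gB", "rloop_category"] == "none"

    def test_no_rloops_all_none(self, toy_genes, toy_sizes):
        rl = _RlSet(self._frame([]), self._frame([]))
        table = gene_rloop_overlap(rl, toy_genes, toy_sizes)
        assert (table["rloop_category"] == "none").all()

    def test_promoter_rloop_counts_via_extended_span(self, toy_genes, toy_sizes):
        # 2 kb upstream of gA TSS: inside the promoter window extension
        rl = _RlSet(self._frame([]), self._frame([("chr1", 8000, 8200)]))
        table = gene_rloop_overlap(rl, toy_genes, toy_sizes)
        assert table.set_index("gene_id").loc["gA", "rloop_category"] == "unstranded_only"

    def test_categories_match_quadratic_oracle(self):
        cfg = SimConfig(genome_length=500_000, n_genes=40, seed=10)
        sizes, genes = make_genome(cfg)
        rng = np.random.default_rng(11)
        def rand_frame(n):
            chroms = rng.choice(list(sizes), size=n)
            starts = np.array([rng.integers(0, sizes[c] - 500) for c in chroms])
            return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + 500})
        rl = _RlSet(rand_frame(30), rand_frame(30))
        table = gene_rloop_overlap(rl, genes, sizes).set_index("gene_id")
        from rloopkit.annotation import extended_span
        for g in genes:
            lo, hi = extended_span(g, sizes[g.chrom])
            def hits(df):
                return any(
                    (r["chrom"] == g.chrom) and (r["start"] < hi) and (lo < r["end"])
                    for _, r in df.iterrows()
                )
            hs, hu = hits(rl.stranded), hits(rl.unstranded)
            expected = (
                "both" if hs and hu else
                "stranded_only" if hs else
                "unstranded_only" if hu else "none"
            )
            assert table.loc[g.gene_id, "rloop_category"] == expected

    def test_tf_bound_and_proportions(self, toy_genes, toy_sizes):
        rl = _RlSet(self._frame([("chr1", 15000, 15400)]), self._frame([]))
        tf = self._frame([("chr1", 9000, 9100)])
        table = gene_rloop_overlap(
            rl, toy_genes, toy_sizes, tf_peaks=tf, tertiles={"gA": "high", "gB": "low"}
        )
        t = table.set_index("gene_id")
        assert bool(t.loc["gA", "tf_bound"]) and not bool(t.loc["gB", "tf_bound"])
        props = category_proportions(table)
        assert props["proportion"].between(0, 1).all()


class TestLengthDistribution:
    def test_degenerate_equal_lengths(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "length": [1000, 1000],
             "rloop_category": ["none", "stranded_only"],
             "tertile": ["low", "low"]}
        )
        out = length_distribution(table)
        meds = {k: v["median"] for k, v in out.items()}
        assert all(m == pytest.approx(3.0) for m in meds.values())

    def test_rloops_on_long_genes_shift_median(self):
        """Planting R-loops only on the longest genes makes the with-R-loop
        median log-length exceed the without."""
        rng = np.random.default_rng(12)
        lengths = np.sort(rng.lognormal(8, 1, size=100).astype(int) + 500)
        cat = ["none"] * 80 + ["unstranded_only"] * 20  # longest 20%
        table = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(100)], "length": lengths,
             "rloop_category": cat, "tertile": "mid"}
        )
        out = length_distribution(table)
        assert out[("unstranded_only", "mid")]["median"] > out[("none", "mid")]["median"]
        # medians equal a direct recomputation
        expect = float(np.median(np.log10(lengths[80:].astype(float))))
        assert out[("unstranded_only", "mid")]["median"] == pytest.approx(expect)

    def test_empty_group_warns_and_omitted(self):
        table = pd.DataFrame(
            {"gene_id": ["a"], "length": [1000],
             "rloop_category": pd.Categorical(["none"], categories=["none", "both"]),
             "tertile": ["low"]}
        )
        with pytest.warns(UserWarning, match="empty group"):
            out = length_distribution(table)
        assert ("both", "low") not in out
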