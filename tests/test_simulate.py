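"""Synthetic-data generator: determinism, placement, signal contracts."""

import numpy as np
import pandas as pd
import pytest

from rloopkit.annotation import FeatureMap
from rloopkit.core import GenomicInterval
from rloopkit.fragments import read_fragments
from rloopkit.simulate import (
    SimConfig,
    make_genome,
    plant_rloops,
    read_gtf,
    read_truth_bed,
    simulate_dataset,
    simulate_fragments,
    simulate_mark_tracks,
    write_dataset,
)


def small_config(**kw):
    defaults = dict(
        genome_length=500_000,
        n_genes=40,
        n_stranded=6,
        n_unstranded=6,
        depth_per_sample=10_000,
        seed=1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestMakeGenome:
    def test_zero_genes(self):
        sizes, genes = make_genome(small_config(n_genes=0))
        assert genes == []
        assert sum(sizes.values()) == 500_000
        assert len(sizes) == 2

    def test_determinism(self):
        cfg = small_config(n_genes=50)
        a = make_genome(cfg)
        b = make_genome(cfg)
        assert a[0] == b[0]
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype, g.exons) for g in a[1]] == [
            (g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype, g.exons) for g in b[1]
        ]

    def test_nonoverlap_by_pairwise_scan(self):
        _, genes = make_genome(small_config(n_genes=50))
        assert len(genes) == 50
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                assert not (
                    a.chrom == b.chrom and a.start < b.end and b.start < a.end
                ), f"{a.gene_id} overlaps {b.gene_id}"

    def test_both_strands_and_biotypes(self):
        _, genes = make_genome(small_config(n_genes=60))
        strands = {g.strand for g in genes}
        biotypes = {g.biotype for g in genes}
        assert strands == {"+", "-"}
        assert "protein_coding" in biotypes and "pseudogene" in biotypes

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            make_genome(SimConfig(genome_length=5_000, n_genes=100))


class TestPlantRloops:
    def test_count_bookkeeping(self):
        cfg = small_config(n_stranded=10, n_unstranded=20, genome_length=1_000_000)
        sizes, genes = make_genome(cfg)
        truth = plant_rloops(sizes, genes, cfg)
        assert len(truth.rloops) == 30
        stranded = truth.rloops[truth.rloops["klass"].isin(["plus", "minus"])]
        assert len(stranded) == 10

    def test_strand_balance(self):
        cfg = small_config(n_stranded=9)
        sizes, genes = make_genome(cfg)
        truth = plant_rloops(sizes, genes, cfg)
        n_plus = (truth.rloops["klass"] == "plus").sum()
        n_minus = (truth.rloops["klass"] == "minus").sum()
        assert abs(n_plus - n_minus) <= 1

    def test_promoter_placement_verified_by_annotation_oracle(self):
        cfg = small_config(
            promoter_frac=1.0, genebody_frac=0.0, downstream_frac=0.0,
            n_stranded=8, n_unstranded=0,
        )
        sizes, genes = make_genome(cfg)
        truth = plant_rloops(sizes, genes, cfg)
        fmap = FeatureMap(sizes, genes)
        for _, r in truth.rloops.iterrows():
            iv = GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
            assert fmap.assign(iv) == "promoter-TSS"

    def test_mutual_nonoverlap(self):
        cfg = small_config(n_stranded=10, n_unstranded=10, genome_length=1_000_000)
        sizes, genes = make_genome(cfg)
        df = plant_rloops(sizes, genes, cfg).rloops
        for i in range(len(df)):
            for j in range(i + 1, len(df)):
                a, b = df.iloc[i], df.iloc[j]
                assert not (
                    a["chrom"] == b["chrom"]
                    and a["start"] < b["end"]
                    and b["start"] < a["end"]
                )


@pytest.fixture(scope="module")
def truth_cfg():
    cfg = small_config(genome_length=1_000_000, n_stranded=20, n_unstranded=10,
                       depth_per_sample=30_000)
    sizes, genes = make_genome(cfg)
    return plant_rloops(sizes, genes, cfg), cfg


@pytest.fixture(scope="module")
def truth():
    cfg = small_config(genome_length=1_000_000, n_stranded=20, n_unstranded=20)
    sizes, genes = make_genome(cfg)
    return plant_rloops(sizes, genes, cfg)


class TestSimulateFragments:
    def test_exact_depth(self, truth_cfg):
        truth, cfg = truth_cfg
        fs = simulate_fragments(truth, cfg, "treatment", 1)
        assert fs.library_size == 30_000

    def test_determinism(self, truth_cfg):
        truth, cfg = truth_cfg
        a = simulate_fragments(truth, cfg, "treatment", 1)
        b = simulate_fragments(truth, cfg, "treatment", 1)
        pd.testing.assert_frame_equal(a.fragments, b.fragments)

    def test_rnaseh_is_background_only(self, truth_cfg):
        """Control coverage inside planted R-loops is statistically flat."""
        truth, cfg = truth_cfg
        fs = simulate_fragments(truth, cfg, "rnaseh", 1)
        mids = (fs.fragments["start"] + fs.fragments["end"]) // 2
        in_loop = 0
        loop_bp = 0
        for _, r in truth.rloops.iterrows():
            sel = (fs.fragments["chrom"] == r["chrom"]) & (mids >= r["start"]) & (mids < r["end"])
            in_loop += int(sel.sum())
            loop_bp += r["end"] - r["start"]
        genome = sum(truth.chrom_sizes.values())
        expected = fs.library_size * loop_bp / genome
        assert abs(in_loop - expected) <= 3 * np.sqrt(expected)

    def test_asymmetry_ratio_within_3se(self):
        """Plus-class planted fragments split 1/(1+a) : a/(1+a) by strand."""
        cfg = small_config(
            genome_length=2_000_000, n_stranded=60, n_unstranded=0,
            depth_per_sample=100_000, asymmetry=0.1, min_rloop_gap=1000,
        )
        sizes, genes = make_genome(cfg)
        truth = plant_rloops(sizes, genes, cfg)
        fs = simulate_fragments(truth, cfg, "treatment", 1)
        mids = (fs.fragments["start"] + fs.fragments["end"]) // 2
        plus_loops = truth.rloops[truth.rloops["klass"] == "plus"]
        n_plus = n_total = 0
        for _, r in plus_loops.iterrows():
            sel = (
                (fs.fragments["chrom"] == r["chrom"]) & (mids >= r["start"]) & (mids < r["end"])
            )
            n_total += int(sel.sum())
            n_plus += int((fs.fragments.loc[sel, "strand"] == "+").sum())
        # background contributes 50/50; planted fraction inside a loop is
        # (fold-1)/fold of the signal there, so expected plus share is a mix
        fold = cfg.enrichment_fold
        a = cfg.asymmetry
        p_plus = (1 / fold) * 0.5 + (1 - 1 / fold) * (1 / (1 + a))
        se = np.sqrt(p_plus * (1 - p_plus) * n_total)
        assert abs(n_plus - p_plus * n_total) <= 3 * se

    def test_bad_kind_rejected(self, truth_cfg):
        truth, cfg = truth_cfg
        with pytest.raises(ValueError):
            simulate_fragments(truth, cfg, "input", 1)


class TestMarkTracks:
    def test_enriched_at_target_class_only(self, truth):
        tracks = simulate_mark_tracks(truth, {"mA": ("stranded", 5.0)}, seed=3)
        track = tracks["mA"]

        def mean_at(klasses):
            vals = []
            for _, r in truth.rloops[truth.rloops["klass"].isin(klasses)].iterrows():
                mid = (r["start"] + r["end"]) // 2
                vals.append(track.per_bp(r["chrom"])[mid])
            return np.mean(vals)

        at_stranded = mean_at(["plus", "minus"])
        at_unstranded = mean_at(["unstranded"])
        assert at_stranded == pytest.approx(5.0, rel=0.15)
        assert at_unstranded == pytest.approx(1.0, abs=0.15)

    def test_fold_one_is_flat(self, truth):
        track = simulate_mark_tracks(truth, {"m": ("unstranded", 1.0)}, seed=4)["m"]
        vals = np.concatenate([track.per_bp(c) for c in truth.chrom_sizes])
        assert abs(vals.mean() - 1.0) < 0.01
        assert vals.std() < 0.2

    def test_empty_spec(self, truth):
        assert simulate_mark_tracks(truth, {}, seed=0) == {}

    def test_unknown_class_rejected(self, truth):
        with pytest.raises(ValueError, match="unknown target"):
            simulate_mark_tracks(truth, {"m": ("bidirectional", 2.0)}, seed=0)


class TestWriteDataset:
    def test_roundtrip_and_manifest(self, tmp_path):
        cfg = small_config(n_replicates=4)
        ds = simulate_dataset(cfg, mark_spec={"mA": ("stranded", 3.0)})
        manifest = write_dataset(ds, tmp_path)
        assert len(manifest["treatment"]) + len(manifest["rnaseh"]) == 8
        # fragments round-trip losslessly
        fs = ds.treatments[0].sorted()
        back = read_fragments(tmp_path / manifest["treatment"][0], fs.sample_id)
        pd.testing.assert_frame_equal(fs.fragments, back.fragments)
        # truth classes parse back
        truth_back = read_truth_bed(tmp_path / manifest["truth"])
        assert set(truth_back["klass"].unique()) <= {"plus", "minus", "unstranded"}
        assert len(truth_back) == len(ds.truth.rloops)
        # gene models round-trip
        genes_back = read_gtf(tmp_path / manifest["genes"])
        orig = sorted(ds.truth.genes, key=lambda g: (g.chrom, g.start))
        assert [(g.gene_id, g.start, g.end, g.strand, g.biotype, tuple(g.exons)) for g in genes_back] == [
            (g.gene_id, g.start, g.end, g.strand, g.biotype, tuple(sorted(g.exons))) for g in orig
        ]


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(asymmetry=0.0).validate()
    with pytest.raises(ValueError):
        SimConfig(frag_len_mean=0).validate()
    with pytest.raises(ValueError):
        SimConfig(n_genes=-1).validate()
    SimConfig().validate()
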