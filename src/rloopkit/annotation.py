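"""Genomic feature annotation of R-loops against gene models.

Conventions:

- promoter-TSS window: -2.5 kb to +0.5 kb around the TSS, in gene
  orientation;
- downstream-TTS window: -0.5 kb to +2.5 kb around the gene end, in gene
  orientation;
- an R-loop is assigned the feature class of its midpoint, under the
  priority promoter-TSS > downstream-TTS > exon > intron > intergenic;
- when the gene responsible for the winning genic feature is a pseudogene,
  the class becomes "pseudogene";
- the expected model for observed/expected ratios is the bp share of the
  genome each class occupies under the exact same per-base priority
  partition, so classes partition both the R-loop set and the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval
from .intervals import overlaps_any

PROMOTER_UPSTREAM = 2500
PROMOTER_DOWNSTREAM = 500
DOWNSTREAM_UPSTREAM = 500
DOWNSTREAM_DOWNSTREAM = 2500

FEATURE_CLASSES = [
    "promoter-TSS",
    "exon",
    "intron",
    "downstream-TTS",
    "pseudogene",
    "intergenic",
]

_CODE = {name: i for i, name in enumerate(
    ["intergenic", "intron", "exon", "downstream-TTS", "promoter-TSS", "pseudogene"]
)}
_NAME = {i: n for n, i in _CODE.items()}


def promoter_window(
    gene: GeneModel,
    chrom_size: int,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> tuple[int, int]:
    """Strand-aware promoter-TSS window, clipped to the chromosome."""
    if gene.strand == "+":
        s, e = gene.tss - upstream, gene.tss + downstream
    else:
        s, e = gene.tss - downstream, gene.tss + upstream
    return max(s, 0), min(e, chrom_size)


def downstream_window(
    gene: GeneModel,
    chrom_size: int,
    upstream: int = DOWNSTREAM_UPSTREAM,
    downstream: int = DOWNSTREAM_DOWNSTREAM,
) -> tuple[int, int]:
    """Strand-aware downstream-TTS window, clipped to the chromosome."""
    if gene.strand == "+":
        s, e = gene.tes - upstream, gene.tes + downstream
    else:
        s, e = gene.tes - downstream, gene.tes + upstream
    return max(s, 0), min(e, chrom_size)


def extended_span(gene: GeneModel, chrom_size: int) -> tuple[int, int]:
    """Gene body plus promoter and downstream windows (one contiguous span)."""
    ps, pe = promoter_window(gene, chrom_size)
    ds, de = downstream_window(gene, chrom_size)
    return min(ps, ds, gene.start), max(pe, de, gene.end)


@dataclass
class FeatureMap:
    """Per-base feature partition of a genome under the priority rule."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    arrays: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.arrays = {
            chrom: np.zeros(size, dtype=np.int8)
            for chrom, size in self.chrom_sizes.items()
        }
        genes = sorted(self.genes, key=lambda g: g.gene_id)
        # paint lowest priority first; later layers overwrite
        for layer in ("intron", "exon", "downstream", "promoter"):
            for gene in genes:
                arr = self.arrays.get(gene.chrom)
                if arr is None:
                    continue
                size = self.chrom_sizes[gene.chrom]
                if layer == "intron":
                    s, e = gene.start, gene.end
                    code = "intron"
                elif layer == "exon":
                    for xs, xe in gene.exons:
                        self._paint(arr, xs, xe, gene, "exon")
                    continue
                elif layer == "downstream":
                    s, e = downstream_window(gene, size)
                    code = "downstream-TTS"
                else:
                    s, e = promoter_window(gene, size)
                    code = "promoter-TSS"
                self._paint(arr, s, e, gene, code)

    @staticmethod
    def _paint(arr: np.ndarray, s: int, e: int, gene: GeneModel, feature: str) -> None:
        label = "pseudogene" if gene.biotype == "pseudogene" else feature
        arr[max(s, 0): min(e, len(arr))] = _CODE[label]

    def class_at(self, chrom: str, pos: int) -> str:
        return _NAME[int(self.arrays[chrom][pos])]

    def assign(self, interval: GenomicInterval) -> str:
        """Feature class of the interval's midpoint."""
        return self.class_at(interval.chrom, interval.midpoint)

    def genome_shares(self) -> dict[str, float]:
        """Fraction of genome bp occupied by each feature class."""
        total = sum(self.chrom_sizes.values())
        counts = {name: 0 for name in FEATURE_CLASSES}
        for arr in self.arrays.values():
            binc = np.bincount(arr, minlength=len(_CODE))
            for code, n in enumerate(binc):
                counts[_NAME[code]] += int(n)
        return {name: counts[name] / total for name in FEATURE_CLASSES}


def assign_feature(
    rloop: GenomicInterval,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    feature_map: FeatureMap | None = None,
) -> str:
    """Feature class of one R-loop (midpoint rule); intergenic if no genes."""
    fmap = feature_map or FeatureMap(chrom_sizes, genes)
    return fmap.assign(rloop)


def observed_expected(
    rloops: pd.DataFrame,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    feature_map: FeatureMap | None = None,
) -> pd.DataFrame:
    """Observed vs expected feature counts for a set of R-loops.

    expected = |R-loops| x genomic bp share of the class; ratio is NaN for
    classes with zero genomic share (which then must have zero observed).
    """
    if len(rloops) == 0:
        raise ValueError("observed_expected needs at least one R-loop")
    fmap = feature_map or FeatureMap(chrom_sizes, genes)
    mids = ((rloops["start"] + rloops["end"]) // 2).to_numpy()
    classes = [
        _NAME[int(fmap.arrays[c][m])] for c, m in zip(rloops["chrom"], mids)
    ]
    shares = fmap.genome_shares()
    n = len(rloops)
    rows = []
    for name in FEATURE_CLASSES:
        obs = classes.count(name)
        exp = n * shares[name]
        if shares[name] == 0:
            assert obs == 0, f"observed {name} hits but zero genomic share"
            ratio = np.nan
        else:
            ratio = obs / exp
        rows.append((name, obs, exp, ratio))
    out = pd.DataFrame(rows, columns=["feature", "observed", "expected", "ratio"])
    assert int(out["observed"].sum()) == n
    return out


def tss_tes_profile(
    rloops: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 10000,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Histogram of gene-oriented R-loop midpoint distances to TSS and TTS.

    The anchor gene is the one whose body is nearest the midpoint. Sign
    convention: positive = downstream of the anchor in gene orientation, so
    for a minus-strand gene a midpoint genomically left of the TSS is
    *downstream* (+).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    d_tss, d_tes = [], []
    for chrom, sub in rloops.groupby("chrom", sort=False):
        cands = by_chrom.get(chrom, [])
        if not cands:
            continue
        starts = np.array([g.start for g in cands])
        ends = np.array([g.end for g in cands])
        for mid in ((sub["start"] + sub["end"]) // 2).to_numpy():
            dist = np.maximum(starts - mid, 0) + np.maximum(mid - (ends - 1), 0)
            g = cands[int(np.argmin(dist))]
            sign = 1 if g.strand == "+" else -1
            d_tss.append(sign * (mid - g.tss))
            d_tes.append(sign * (mid - g.tes))
    edges = np.linspace(-flank, flank, n_bins + 1)
    h_tss, _ = np.histogram(d_tss, bins=edges)
    h_tes, _ = np.histogram(d_tes, bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1].astype(int),
            "bin_end": edges[1:].astype(int),
            "tss": h_tss,
            "tes": h_tes,
        }
    )


def classify_tf_peak_proximity(
    peak: GenomicInterval, gene: GeneModel, margin: int = 1000
) -> str:
    """'proximal' iff the peak overlaps the gene body extended by +-margin."""
    if peak.chrom != gene.chrom:
        return "distal"
    lo, hi = gene.start - margin, gene.end + margin
    return "proximal" if (peak.start < hi and lo < peak.end) else "distal"


def expression_tertiles(
    expression: dict[str, float], min_cpm: float = 1.0
) -> dict[str, str]:
    """Split expressed genes (CPM > min_cpm) into low/mid/high tertiles.

    Boundaries at ranks ceil(n/3) and ceil(2n/3) of the CPM-ascending order;
    ties broken by gene_id so the labelling is a deterministic function of
    the CPM multiset.
    """
    expressed = sorted(
        (g for g, v in expression.items() if v > min_cpm),
        key=lambda g: (expression[g], g),
    )
    labels = {g: "not_expressed" for g in expression}
    n = len(expressed)
    if n == 0:
        return labels
    b1 = -(-n // 3)
    b2 = -(-2 * n // 3)
    for rank, g in enumerate(expressed, start=1):
        labels[g] = "low" if rank <= b1 else ("mid" if rank <= b2 else "high")
    return labels


def gene_rloop_overlap(
    rlset,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    tf_peaks: pd.DataFrame | None = None,
    tertiles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene R-loop / TF-binding table.

    ``rlset`` needs ``.stranded`` and ``.unstranded`` interval DataFrames.
    A gene "has" an R-loop or TF peak when it overlaps (>= 1 bp) the gene
    span extended by the promoter and downstream windows.
    """
    spans = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [extended_span(g, chrom_sizes[g.chrom])[0] for g in genes],
            "end": [extended_span(g, chrom_sizes[g.chrom])[1] for g in genes],
            "length": [g.length for g in genes],
        }
    )
    has_s = overlaps_any(spans, rlset.stranded)
    has_u = overlaps_any(spans, rlset.unstranded)
    category = np.select(
        [has_s & has_u, has_s, has_u],
        ["both", "stranded_only", "unstranded_only"],
        default="none",
    )
    tf_bound = (
        overlaps_any(spans, tf_peaks)
        if tf_peaks is not None and len(tf_peaks)
        else np.zeros(len(spans), dtype=bool)
    )
    table = pd.DataFrame(
        {
            "gene_id": spans["gene_id"],
            "chrom": spans["chrom"],
            "length": spans["length"],
            "has_stranded": has_s,
            "has_unstranded": has_u,
            "rloop_category": category,
            "tf_bound": tf_bound,
        }
    )
    if tertiles is not None:
        table["tertile"] = table["gene_id"].map(tertiles).fillna("not_expressed")
    else:
        table["tertile"] = "not_expressed"
    return table


def category_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Marginal proportions of R-loop categories within each tertile."""
    out = (
        table.groupby(["tertile", "rloop_category"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = out.groupby("tertile")["count"].transform("sum")
    out["proportion"] = out["count"] / totals
    return out


def length_distribution(table: pd.DataFrame) -> dict[tuple[str, str], dict]:
    """log10 gene-length vectors and medians per (category, tertile) group.

    Empty groups are omitted with a warning.
    """
    if len(table) == 0:
        raise ValueError("empty per-gene table")
    out: dict[tuple[str, str], dict] = {}
    def _levels(col: pd.Series) -> list[str]:
        if isinstance(col.dtype, pd.CategoricalDtype):
            return sorted(col.cat.categories)
        return sorted(col.unique())

    cats = _levels(table["rloop_category"])
    terts = _levels(table["tertile"])
    for cat in cats:
        for tert in terts:
            sub = table[(table["rloop_category"] == cat) & (table["tertile"] == tert)]
            if len(sub) == 0:
                warnings.warn(f"empty group ({cat}, {tert}) omitted", stacklevel=2)
                continue
            logs = np.log10(sub["length"].to_numpy().astype(float))
            out[(cat, tert)] = {"log10_length": logs, "median": float(np.median(logs))}
    return out
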