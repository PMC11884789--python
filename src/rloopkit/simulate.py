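"""Synthetic ssDRIP-seq data with planted, known-truth R-loops.

The generator emulates the statistical structure the downstream analysis
assumes: a small multi-chromosome genome with non-overlapping gene models,
planted R-loops of two kinds (strand-specific and unstranded), strand-
labelled sequencing fragments for treatment replicates and RNase-H control
replicates, and auxiliary chromatin-mark tracks enriched at chosen R-loop
classes.

Signal model. Fragment midpoints are drawn from a mixture: a uniform
background over both strands of the whole genome, plus one extra component
per planted R-loop whose weight corresponds to an ``enrichment_fold``-times
elevated local rate. A plus-class R-loop sends a fraction 1/(1+a) of its
extra fragments to the plus strand and a/(1+a) to the minus strand, where
``a`` is the asymmetry ratio (default 0.1), so the expected majority:minority
ratio is 1/a; unstranded R-loops split 50/50. RNase-H control libraries
contain background only — the enzymatic removal of RNA:DNA hybrids erases
all planted signal. With ``depth_per_sample`` set, the total fragment count
per library is exact (multinomial allocation), which makes CPM arithmetic
exact in tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import FeatureMap, downstream_window, promoter_window
from .core import FRAGMENT_COLUMNS, CoverageTrack, FragmentSet, GeneModel, GenomicInterval
from .fragments import write_bedgraph, write_chrom_sizes, write_fragments

RLOOP_CLASSES = ("plus", "minus", "unstranded")


class PlacementError(RuntimeError):
    """Raised when genes or R-loops cannot be placed without forced overlap."""


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults describe the standard desk-scale study: a 2 Mb two-chromosome
    genome, 4 treatment + 4 RNase-H replicates of ~50k fragments each,
    30 stranded + 30 unstranded planted R-loops at 8x enrichment with
    strand asymmetry 0.1, fragment length ~ Normal(250, 50).
    """

    genome_length: int = 2_000_000
    n_chroms: int = 2
    n_genes: int = 120
    n_stranded: int = 30
    n_unstranded: int = 30
    rloop_len_mean: int = 1000
    rloop_len_sd: int = 200
    frag_len_mean: int = 250
    frag_len_sd: int = 50
    depth_per_sample: int | None = 50_000
    enrichment_fold: float = 8.0
    asymmetry: float = 0.1
    background_rate: float = 0.01  # fragments per bp per strand (Poisson mode)
    n_replicates: int = 4
    subthreshold_frac: float = 0.05
    min_rloop_gap: int = 3000
    # fraction of R-loop midpoints targeted at each feature class
    promoter_frac: float = 0.3
    genebody_frac: float = 0.3
    downstream_frac: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_stranded, self.n_unstranded, self.n_replicates) < 0:
            raise ValueError("counts must be >= 0")
        if not (0 < self.asymmetry <= 1):
            raise ValueError("asymmetry must lie in (0, 1]")
        if self.frag_len_mean <= 0:
            raise ValueError("frag_len_mean must be positive")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.n_chroms < 1:
            raise ValueError("need at least one chromosome")
        if self.promoter_frac + self.genebody_frac + self.downstream_frac > 1 + 1e-9:
            raise ValueError("placement fractions must sum to <= 1")
        needed = self.n_genes * 500 + (
            self.n_stranded + self.n_unstranded
        ) * (self.rloop_len_mean + self.min_rloop_gap)
        if self.genome_length < max(needed, 10_000):
            raise ValueError("genome too small for requested genes and R-loops")


@dataclass
class SyntheticTruth:
    """Planted R-loops with their true class labels; the recovery oracle."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    rloops: pd.DataFrame  # chrom, start, end, klass in {plus, minus, unstranded}
    expression: dict[str, float]

    def __post_init__(self) -> None:
        bad = set(self.rloops["klass"].unique()) - set(RLOOP_CLASSES)
        if bad:
            raise ValueError(f"unknown R-loop classes {sorted(bad)}")


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def _chrom_sizes(config: SimConfig) -> dict[str, int]:
    # slightly uneven split so cross-chromosome indexing bugs surface
    n = config.n_chroms
    weights = np.linspace(1.3, 0.7, n)
    weights /= weights.sum()
    sizes = (weights * config.genome_length).astype(int)
    sizes[-1] += config.genome_length - sizes.sum()
    return {f"chr{i + 1}": int(s) for i, s in enumerate(sizes)}


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    lengths: np.ndarray,
    min_gap: int = 0,
    max_tries: int = 2000,
    accept=None,
) -> list[tuple[str, int, int]]:
    """Greedy rejection placement of intervals with a minimum pairwise gap."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    placed = []
    for length in lengths:
        length = int(length)
        for _ in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            size = chrom_sizes[chrom]
            if size <= length:
                continue
            start = int(rng.integers(0, size - length))
            end = start + length
            if any(
                start < oe + min_gap and os_ - min_gap < end
                for os_, oe in occupied[chrom]
            ):
                continue
            if accept is not None and not accept(chrom, start, end):
                continue
            occupied[chrom].append((start, end))
            placed.append((chrom, start, end))
            break
        else:
            raise PlacementError(
                f"could not place interval of {length} bp after {max_tries} tries"
            )
    return placed


def make_genome(config: SimConfig) -> tuple[dict[str, int], list[GeneModel]]:
    """Toy genome: >= 2 chromosomes with non-overlapping genes on both strands.

    Gene lengths are log-normal (long-tailed) so length stratification is
    testable; biotypes mix protein_coding (85%), pseudogene (10%) and other.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    chrom_sizes = _chrom_sizes(config)
    if config.n_genes == 0:
        return chrom_sizes, []
    lengths = np.clip(
        rng.lognormal(mean=np.log(3000), sigma=0.9, size=config.n_genes),
        500,
        config.genome_length // 20,
    ).astype(int)
    # place longest first so tail genes fit before the genome fills up
    lengths = np.sort(lengths)[::-1]
    placed = _place_nonoverlapping(rng, chrom_sizes, lengths, min_gap=200)
    biotypes = rng.choice(
        ["protein_coding", "pseudogene", "other"],
        size=config.n_genes,
        p=[0.85, 0.10, 0.05],
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = []
    for i, ((chrom, start, end), bio, strand) in enumerate(
        zip(placed, biotypes, strands)
    ):
        n_exons = 1 + int(rng.poisson(2))
        cuts = np.sort(rng.integers(start + 1, end, size=2 * (n_exons - 1))) if n_exons > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[start], cuts, [end]])
        exons = [
            (int(bounds[j]), int(bounds[j + 1]))
            for j in range(0, len(bounds) - 1, 2)
            if bounds[j] < bounds[j + 1]
        ]
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:04d}",
                chrom=chrom,
                strand=str(strand),
                start=start,
                end=end,
                exons=exons,
                biotype=str(bio),
            )
        )
    return chrom_sizes, genes


def _expression(rng: np.random.Generator, genes: list[GeneModel]) -> dict[str, float]:
    """Long-tailed CPM values; ~20% of genes silent."""
    if not genes:
        return {}
    raw = rng.lognormal(mean=2.0, sigma=1.5, size=len(genes))
    raw[rng.random(len(genes)) < 0.2] = 0.0
    total = raw.sum()
    cpm = raw / total * 1e6 if total > 0 else raw
    return {g.gene_id: float(v) for g, v in zip(genes, cpm)}


def plant_rloops(
    chrom_sizes: dict[str, int],
    genes: list[GeneModel],
    config: SimConfig,
) -> SyntheticTruth:
    """Place mutually non-overlapping R-loops with known class labels.

    Strand-specific loops are balanced between plus and minus; midpoints are
    targeted at promoter / gene-body / downstream / intergenic space with
    the configured fractions (verified against the feature map, so planted
    placement agrees with the annotation oracle by construction).
    """
    config.validate()
    rng = _rng(config.seed, 2)
    n_total = config.n_stranded + config.n_unstranded
    if n_total == 0:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "klass"])
        return SyntheticTruth(chrom_sizes, genes, empty, _expression(rng, genes))
    klasses = []
    for i in range(config.n_stranded):
        klasses.append("plus" if i % 2 == 0 else "minus")
    klasses += ["unstranded"] * config.n_unstranded
    lengths = np.clip(
        rng.normal(config.rloop_len_mean, config.rloop_len_sd, size=n_total),
        200,
        None,
    ).astype(int)
    fmap = FeatureMap(chrom_sizes, genes)
    targets = rng.choice(
        ["promoter-TSS", "gene-body", "downstream-TTS", "intergenic"],
        size=n_total,
        p=[
            config.promoter_frac,
            config.genebody_frac,
            config.downstream_frac,
            1 - config.promoter_frac - config.genebody_frac - config.downstream_frac,
        ],
    )

    def accept_factory(target: str):
        def accept(chrom: str, start: int, end: int) -> bool:
            cls = fmap.class_at(chrom, (start + end) // 2)
            if target == "gene-body":
                return cls in ("exon", "intron")
            if target == "intergenic":
                return cls == "intergenic"
            return cls == target

        return accept

    # place per target class so the rejection sampler converges quickly
    rows: list[tuple[str, int, int, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for length, klass, target in zip(lengths, klasses, targets):
        accept = accept_factory(str(target)) if genes else None
        placed = False
        for _ in range(5000):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            size = chrom_sizes[chrom]
            if size <= length:
                continue
            start = int(rng.integers(0, size - length))
            end = start + int(length)
            if any(
                start < oe + config.min_rloop_gap and os_ - config.min_rloop_gap < end
                for os_, oe in occupied[chrom]
            ):
                continue
            if accept is not None and not accept(chrom, start, end):
                continue
            occupied[chrom].append((start, end))
            rows.append((chrom, start, end, klass))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {length} bp R-loop targeting {target}"
            )
    rloops = pd.DataFrame(rows, columns=["chrom", "start", "end", "klass"])
    return SyntheticTruth(chrom_sizes, genes, rloops, _expression(rng, genes))


def simulate_fragments(
    truth: SyntheticTruth,
    config: SimConfig,
    sample_kind: str,
    replicate_id: int,
    seed: int | None = None,
) -> FragmentSet:
    """Draw one library of strand-labelled fragments.

    ``sample_kind`` is "treatment" (background + planted signal) or "rnaseh"
    (background only). With ``depth_per_sample`` set the library size is
    exactly that count; otherwise component counts are Poisson draws at
    ``background_rate`` (and fold-scaled rates inside R-loops).
    """
    if sample_kind not in ("treatment", "rnaseh"):
        raise ValueError("sample_kind must be 'treatment' or 'rnaseh'")
    config.validate()
    stream = 10 if sample_kind == "treatment" else 20
    rng = _rng(config.seed if seed is None else seed, stream, replicate_id)
    chroms = list(truth.chrom_sizes)
    sizes = np.array([truth.chrom_sizes[c] for c in chroms], dtype=float)
    genome_length = sizes.sum()
    loops = truth.rloops
    with_signal = sample_kind == "treatment" and len(loops) > 0
    # component weights: uniform background (both strands) + per-loop extra
    w_bg = 2.0 * genome_length
    w_loops = (
        (config.enrichment_fold - 1.0)
        * 2.0
        * (loops["end"] - loops["start"]).to_numpy().astype(float)
        if with_signal
        else np.array([])
    )
    weights = np.concatenate([[w_bg], w_loops])
    if config.depth_per_sample is not None:
        counts = rng.multinomial(config.depth_per_sample, weights / weights.sum())
    else:
        counts = rng.poisson(config.background_rate * weights)
    parts_chrom, parts_mid, parts_strand = [], [], []
    n_bg = int(counts[0])
    if n_bg:
        ch_idx = rng.choice(len(chroms), size=n_bg, p=sizes / genome_length)
        mids = (rng.random(n_bg) * sizes[ch_idx]).astype(np.int64)
        strands = rng.choice(np.array(["+", "-"]), size=n_bg)
        parts_chrom.append(np.array(chroms, dtype=object)[ch_idx])
        parts_mid.append(mids)
        parts_strand.append(strands)
    if with_signal:
        a = config.asymmetry
        p_plus = {"plus": 1 / (1 + a), "minus": a / (1 + a), "unstranded": 0.5}
        for (_, loop), n in zip(loops.iterrows(), counts[1:]):
            n = int(n)
            if n == 0:
                continue
            mids = rng.integers(loop["start"], loop["end"], size=n)
            strands = np.where(
                rng.random(n) < p_plus[loop["klass"]], "+", "-"
            )
            parts_chrom.append(np.full(n, loop["chrom"], dtype=object))
            parts_mid.append(mids.astype(np.int64))
            parts_strand.append(strands)
    if not parts_chrom:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            FRAGMENT_COLUMNS, [str, np.int64, np.int64, str, np.int64])})
        return FragmentSet(f"{sample_kind}{replicate_id}", df)
    chrom_arr = np.concatenate(parts_chrom)
    mid_arr = np.concatenate(parts_mid)
    strand_arr = np.concatenate(parts_strand)
    n = len(mid_arr)
    frag_len = np.maximum(
        np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, size=n)), 1
    ).astype(np.int64)
    size_of = np.array([truth.chrom_sizes[c] for c in chrom_arr])
    start = np.clip(mid_arr - frag_len // 2, 0, None)
    end = np.minimum(start + frag_len, size_of)
    start = np.minimum(start, end - 1)
    scores = np.where(
        rng.random(n) < config.subthreshold_frac,
        rng.integers(0, 20, size=n),
        rng.integers(20, 61, size=n),
    )
    df = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "start": start,
            "end": end,
            "strand": strand_arr,
            "score": scores,
        }
    )
    return FragmentSet(f"{sample_kind}{replicate_id}", df)


def simulate_mark_tracks(
    truth: SyntheticTruth,
    enrichment_spec: dict[str, tuple[str, float]],
    seed: int = 0,
    baseline: float = 1.0,
    noise_sd: float = 0.1,
    bin_size: int = 10,
) -> dict[str, CoverageTrack]:
    """Chromatin-mark tracks: flat noisy baseline plus bumps at target loops.

    ``enrichment_spec`` maps mark name -> (target class, fold); target class
    is one of plus/minus/unstranded/stranded (stranded = plus + minus). The
    bump is a Gaussian centred on each target R-loop with sd = loop length/4
    and peak height (fold - 1) x baseline.
    """
    valid = set(RLOOP_CLASSES) | {"stranded"}
    tracks: dict[str, CoverageTrack] = {}
    for k, (target, fold) in enrichment_spec.items():
        if target not in valid:
            raise ValueError(f"unknown target class {target!r} for mark {k!r}")
        if fold < 0:
            raise ValueError("fold must be non-negative")
    for mark_i, (mark, (target, fold)) in enumerate(sorted(enrichment_spec.items())):
        rng = _rng(seed, 30, mark_i)
        values: dict[str, np.ndarray] = {}
        for chrom, size in truth.chrom_sizes.items():
            n_bins = -(-size // bin_size)
            centers = np.arange(n_bins) * bin_size + bin_size / 2
            signal = baseline + rng.normal(0.0, noise_sd, size=n_bins)
            sub = truth.rloops[truth.rloops["chrom"] == chrom]
            if target == "stranded":
                sub = sub[sub["klass"].isin(["plus", "minus"])]
            else:
                sub = sub[sub["klass"] == target]
            for _, loop in sub.iterrows():
                mu = (loop["start"] + loop["end"]) / 2
                sd = max((loop["end"] - loop["start"]) / 4, 1.0)
                signal = signal + (fold - 1) * baseline * np.exp(
                    -0.5 * ((centers - mu) / sd) ** 2
                )
            values[chrom] = np.maximum(signal, 0.0) * bin_size
        tracks[mark] = CoverageTrack(
            sample_id=mark,
            strand="both",
            bin_size=bin_size,
            chrom_sizes=dict(truth.chrom_sizes),
            values=values,
        )
    return tracks


@dataclass
class SimulatedDataset:
    """In-memory bundle: truth, libraries and mark tracks for one experiment."""

    config: SimConfig
    truth: SyntheticTruth
    treatments: list[FragmentSet]
    controls: list[FragmentSet]
    marks: dict[str, CoverageTrack] = field(default_factory=dict)


DEFAULT_MARK_SPEC = {
    "markStranded": ("stranded", 5.0),
    "markUnstranded": ("unstranded", 5.0),
}


def simulate_dataset(
    config: SimConfig | None = None,
    mark_spec: dict[str, tuple[str, float]] | None = None,
    null_treatment: bool = False,
) -> SimulatedDataset:
    """Generate the full experiment: genome, truth, N+N libraries, marks.

    ``null_treatment=True`` generates the "treatment" libraries with the
    RNase-H background-only model (used for specificity calibration).
    """
    config = config or SimConfig()
    config.validate()
    chrom_sizes, genes = make_genome(config)
    truth = plant_rloops(chrom_sizes, genes, config)
    treat_kind = "rnaseh" if null_treatment else "treatment"
    treatments = []
    for r in range(1, config.n_replicates + 1):
        fs = simulate_fragments(truth, config, treat_kind, r, seed=config.seed)
        fs.sample_id = f"treatment{r}"
        treatments.append(fs)
    controls = [
        simulate_fragments(truth, config, "rnaseh", r + 100, seed=config.seed)
        for r in range(1, config.n_replicates + 1)
    ]
    for r, fs in enumerate(controls, start=1):
        fs.sample_id = f"rnaseh{r}"
    marks = simulate_mark_tracks(
        truth, DEFAULT_MARK_SPEC if mark_spec is None else mark_spec, seed=config.seed
    )
    return SimulatedDataset(config, truth, treatments, controls, marks)


def write_gtf(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Minimal GTF (1-based inclusive) with gene and exon records."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\trloopkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for xs, xe in g.exons:
                fh.write(
                    f"{g.chrom}\trloopkit\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from the GTF files this package writes."""
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, kind, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in attrs.strip().rstrip(";").split(";")
            )
            gid = fields["gene_id"]
            if kind == "gene":
                genes[gid] = GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=int(start) - 1,
                    end=int(end),
                    biotype=fields.get("gene_biotype", "other"),
                )
            elif kind == "exon":
                exons.setdefault(gid, []).append((int(start) - 1, int(end)))
    for gid, g in genes.items():
        g.exons = sorted(exons.get(gid, []))
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start))


def write_dataset(dataset: SimulatedDataset, out_dir: str | os.PathLike) -> dict:
    """Write the dataset as plain-text files and return the JSON manifest.

    Fragments go out as BED6, genes as GTF, truth as BED with the class in
    the name field, expression as TSV, marks as bedGraph; everything
    round-trips losslessly through this package's readers.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    truth = dataset.truth
    write_chrom_sizes(truth.chrom_sizes, os.path.join(out_dir, "genome.chrom.sizes"))
    write_gtf(truth.genes, os.path.join(out_dir, "genes.gtf"))
    truth_bed = os.path.join(out_dir, "truth.bed")
    with open(truth_bed, "w") as fh:
        for _, r in truth.rloops.sort_values(["chrom", "start"]).iterrows():
            strand = {"plus": "+", "minus": "-", "unstranded": "."}[r["klass"]]
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['klass']}\t0\t{strand}\n"
            )
    expr_path = os.path.join(out_dir, "expression.tsv")
    with open(expr_path, "w") as fh:
        fh.write("gene_id\tcpm\n")
        for gid in sorted(truth.expression):
            fh.write(f"{gid}\t{truth.expression[gid]:.6g}\n")
    manifest = {
        "chrom_sizes": "genome.chrom.sizes",
        "genes": "genes.gtf",
        "truth": "truth.bed",
        "expression": "expression.tsv",
        "treatment": [],
        "rnaseh": [],
        "marks": {},
        "seed": dataset.config.seed,
        "config": asdict(dataset.config),
    }
    for fs in dataset.treatments:
        name = f"{fs.sample_id}.bed"
        write_fragments(fs, os.path.join(out_dir, name))
        manifest["treatment"].append(name)
    for fs in dataset.controls:
        name = f"{fs.sample_id}.bed"
        write_fragments(fs, os.path.join(out_dir, name))
        manifest["rnaseh"].append(name)
    for mark, track in sorted(dataset.marks.items()):
        name = f"{mark}.bedgraph"
        write_bedgraph(track, os.path.join(out_dir, name))
        manifest["marks"][mark] = name
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_truth_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "klass", "score", "strand"],
    )
    return df[["chrom", "start", "end", "klass"]]
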