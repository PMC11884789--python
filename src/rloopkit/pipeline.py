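"""The strand-aware R-loop inference pipeline.

Stages, mirroring the analysis design for ssDRIP-seq:

1. filter fragments (score, blacklist, duplicates);
2. pool the RNase-H control libraries into one background dataset;
3. per treatment replicate, call enrichment of all fragments (both strands)
   against the pooled control, in narrow and broad mode;
4. merge calls reproducible in >= ``min_support`` distinct replicates at
   q <= ``q_threshold`` into the *total* R-loop set (connected-component
   clustering of >= 1 bp overlaps; narrow and broad calls from the same
   replicate count once);
5. per replicate and per strand, call enrichment of one strand's fragments
   against the opposite strand of the same replicate, and apply the same
   reproducibility merge per strand;
6. classify each total R-loop: overlapping plus-asymmetry intervals only ->
   stranded(+); minus only -> stranded(-); neither, or both -> unstranded
   (hybrids on both strands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import call_peaks
from .core import FragmentSet
from .fragments import filter_fragments, strand_split
from .intervals import merge_overlapping, overlaps_any, sort_intervals

TOTAL_COLUMNS = ["chrom", "start", "end", "support"]


@dataclass
class RLoopSet:
    """The merged, classified R-loop catalogue (total = stranded U unstranded)."""

    total: pd.DataFrame  # chrom, start, end, support
    stranded: pd.DataFrame  # + strand column in {+, -}
    unstranded: pd.DataFrame
    q_threshold: float = 0.001
    min_support: int = 3

    def __post_init__(self) -> None:
        n = len(self.stranded) + len(self.unstranded)
        if n != len(self.total):
            raise ValueError("stranded and unstranded must partition total")

    def counts(self) -> dict[str, int]:
        return {
            "total": len(self.total),
            "stranded": len(self.stranded),
            "unstranded": len(self.unstranded),
        }


def pool_controls(controls: list[FragmentSet]) -> FragmentSet:
    """Concatenate the RNase-H libraries into one pooled control dataset."""
    if not controls:
        raise ValueError("need at least one control library")
    df = pd.concat([c.fragments for c in controls], ignore_index=True)
    return FragmentSet("pooled_control", df)


def call_sample_rloops(
    sample: FragmentSet,
    pooled_control: FragmentSet,
    chrom_sizes: dict[str, int],
    q_threshold: float = 0.001,
    window_size: int = 200,
    step: int = 100,
) -> pd.DataFrame:
    """Narrow + broad calls for one replicate, all fragments vs pooled control."""
    return call_peaks(
        sample,
        pooled_control,
        chrom_sizes,
        window_size=window_size,
        step=step,
        q_threshold=q_threshold,
        modes=("narrow", "broad"),
    )


def reproducible_merge(
    per_sample_calls: list[pd.DataFrame],
    min_support: int = 3,
    q_threshold: float = 0.001,
) -> pd.DataFrame:
    """Keep interval clusters supported by >= min_support distinct samples.

    All calls passing q <= q_threshold (already enforced at assembly) are
    clustered by transitive >= 1 bp overlap; a cluster survives iff calls
    from at least ``min_support`` different samples contribute, and its
    interval is the union of its members.
    """
    if len(per_sample_calls) < min_support:
        raise ValueError(
            f"need >= {min_support} samples, got {len(per_sample_calls)}"
        )
    frames = [df for df in per_sample_calls if len(df)]
    if not frames:
        return pd.DataFrame(columns=TOTAL_COLUMNS)
    calls = pd.concat(frames, ignore_index=True)
    calls = calls[calls["summit_q"] <= q_threshold].reset_index(drop=True)
    if len(calls) == 0:
        return pd.DataFrame(columns=TOTAL_COLUMNS)
    clusters = merge_overlapping(calls)
    support = [
        calls.loc[members, "sample_id"].nunique() for members in clusters["members"]
    ]
    clusters["support"] = support
    kept = clusters[clusters["support"] >= min_support]
    return sort_intervals(kept[TOTAL_COLUMNS].reset_index(drop=True))


def call_strand_asymmetry(
    samples: list[FragmentSet],
    chrom_sizes: dict[str, int],
    q_threshold: float = 0.001,
    min_support: int = 3,
    window_size: int = 200,
    step: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strand enrichment vs the opposite strand, reproducibility-merged.

    The opposite strand of the *same* replicate is the control (asymmetry is
    a within-sample contrast); the RNase-H libraries play no role here.
    """
    plus_calls, minus_calls = [], []
    for fs in samples:
        plus, minus = strand_split(fs)
        plus_calls.append(
            call_peaks(plus, minus, chrom_sizes, window_size, step, q_threshold)
        )
        minus_calls.append(
            call_peaks(minus, plus, chrom_sizes, window_size, step, q_threshold)
        )
    plus_asym = reproducible_merge(plus_calls, min_support, q_threshold)
    minus_asym = reproducible_merge(minus_calls, min_support, q_threshold)
    return plus_asym, minus_asym


def classify_strandedness(
    total: pd.DataFrame,
    plus_asym: pd.DataFrame,
    minus_asym: pd.DataFrame,
    q_threshold: float = 0.001,
    min_support: int = 3,
) -> RLoopSet:
    """Intersect total R-loops with per-strand asymmetry intervals.

    Overlap (>= 1 bp) with plus-asymmetry only -> stranded(+); minus only ->
    stranded(-); neither -> unstranded; both -> unstranded (a locus with
    hybrid signal on both strands).
    """
    total = sort_intervals(total.copy())
    hit_p = overlaps_any(total, plus_asym)
    hit_m = overlaps_any(total, minus_asym)
    strand = np.where(hit_p & ~hit_m, "+", np.where(hit_m & ~hit_p, "-", "."))
    stranded = total[strand != "."].copy()
    stranded["strand"] = strand[strand != "."]
    unstranded = total[strand == "."].copy()
    return RLoopSet(
        total=total.reset_index(drop=True),
        stranded=stranded.reset_index(drop=True),
        unstranded=unstranded.reset_index(drop=True),
        q_threshold=q_threshold,
        min_support=min_support,
    )


@dataclass
class PipelineResult:
    rlset: RLoopSet
    plus_asym: pd.DataFrame
    minus_asym: pd.DataFrame
    qc: dict = field(default_factory=dict)


def run_pipeline(
    treatments: list[FragmentSet],
    controls: list[FragmentSet],
    chrom_sizes: dict[str, int],
    blacklist: pd.DataFrame | None = None,
    min_score: int = 20,
    q_threshold: float = 0.001,
    min_support: int = 3,
    window_size: int = 200,
    step: int = 100,
) -> PipelineResult:
    """Execute filter -> pool -> call -> merge -> asymmetry -> classify."""
    if len(treatments) < min_support:
        raise ValueError("fewer treatment samples than min_support")
    qc: dict = {
        "parameters": {
            "min_score": min_score,
            "q_threshold": q_threshold,
            "min_support": min_support,
            "window_size": window_size,
            "step": step,
        },
        "samples": {},
    }
    filt_treat, filt_ctrl = [], []
    for fs in treatments:
        f = filter_fragments(fs, blacklist, min_score=min_score, dedup=True)
        qc["samples"][fs.sample_id] = {
            "role": "treatment",
            "raw": fs.library_size,
            "filtered": f.library_size,
        }
        filt_treat.append(f)
    for fs in controls:
        f = filter_fragments(fs, blacklist, min_score=min_score, dedup=True)
        qc["samples"][fs.sample_id] = {
            "role": "rnaseh",
            "raw": fs.library_size,
            "filtered": f.library_size,
        }
        filt_ctrl.append(f)
    pooled = pool_controls(filt_ctrl)
    qc["pooled_control_size"] = pooled.library_size
    per_sample = [
        call_sample_rloops(
            fs, pooled, chrom_sizes, q_threshold, window_size, step
        )
        for fs in filt_treat
    ]
    qc["per_sample_calls"] = {
        fs.sample_id: len(calls) for fs, calls in zip(filt_treat, per_sample)
    }
    total = reproducible_merge(per_sample, min_support, q_threshold)
    plus_asym, minus_asym = call_strand_asymmetry(
        filt_treat, chrom_sizes, q_threshold, min_support, window_size, step
    )
    rlset = classify_strandedness(
        total, plus_asym, minus_asym, q_threshold, min_support
    )
    qc["counts"] = rlset.counts()
    qc["asymmetry_intervals"] = {"plus": len(plus_asym), "minus": len(minus_asym)}
    return PipelineResult(rlset=rlset, plus_asym=plus_asym, minus_asym=minus_asym, qc=qc)


def write_rloop_beds(result: PipelineResult, out_dir: str) -> dict[str, str]:
    """Emit total.bed, stranded.bed (strand column set) and unstranded.bed."""
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    rlset = result.rlset
    for name, df, strand_col in (
        ("total", rlset.total, None),
        ("stranded", rlset.stranded, "strand"),
        ("unstranded", rlset.unstranded, None),
    ):
        path = os.path.join(out_dir, f"{name}.bed")
        with open(path, "w") as fh:
            for i, row in sort_intervals(df).iterrows():
                strand = row[strand_col] if strand_col else "."
                fh.write(
                    f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                    f"{name}_{i}\t{int(row['support'])}\t{strand}\n"
                )
        paths[name] = path
    qc_path = os.path.join(out_dir, "qc.json")
    with open(qc_path, "w") as fh:
        json.dump(result.qc, fh, indent=2, default=str)
    paths["qc"] = qc_path
    return paths
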