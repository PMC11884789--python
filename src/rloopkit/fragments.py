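"""Fragment I/O, filtering, strand splitting and binned coverage.

Mirrors the preprocessing applied to ssDRIP-seq libraries before peak
calling: drop low-score (multi-mapping) fragments, drop blacklist overlaps,
deduplicate, split by strand, and bin into coverage tracks.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import FRAGMENT_COLUMNS, CoverageTrack, FragmentSet
from .intervals import overlaps_any


class BedParseError(ValueError):
    pass


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column TSV: chrom <TAB> length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_fragments(path: str | os.PathLike, sample_id: str | None = None) -> FragmentSet:
    """Read a BED6 fragment file; strand must be + or -.

    Raises :class:`BedParseError` with the offending line number on malformed
    records (fewer than 6 fields, start >= end, or strand outside {+,-}).
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    rows: list[tuple[str, int, int, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise BedParseError(f"{path}:{lineno}: expected >= 6 BED fields")
            chrom, start_s, end_s, _name, score_s, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
                score = int(float(score_s))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            if strand not in ("+", "-"):
                raise BedParseError(
                    f"{path}:{lineno}: fragment strand must be + or -, got {strand!r}"
                )
            rows.append((chrom, start, end, strand, score))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if len(df) == 0:
        df = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "score": pd.Series(dtype=np.int64),
            }
        )
    return FragmentSet(sample_id, df)


def write_fragments(frags: FragmentSet, path: str | os.PathLike) -> None:
    """Emit BED6 sorted by (chrom, start) for diff-stability."""
    df = frags.sorted().fragments
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": frags.sample_id,
            "score": df["score"],
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_fragments(
    frags: FragmentSet,
    blacklist: pd.DataFrame | None = None,
    min_score: int = 20,
    dedup: bool = True,
) -> FragmentSet:
    """Remove low-score, blacklisted and duplicate fragments.

    - score < ``min_score`` removed (score 19 falls, 20 survives at the
      default threshold, matching the <20 mapping-quality cut);
    - any >= 1 bp overlap with a blacklist interval removes the fragment;
    - duplicates share an identical (chrom, start, end, strand) tuple; one
      representative (the first in input order) is kept.

    Idempotent: filtering an already-filtered set is the identity.
    """
    df = frags.fragments
    keep = df["score"].to_numpy() >= min_score
    if blacklist is not None and len(blacklist):
        keep &= ~overlaps_any(df, blacklist)
    df = df[keep]
    if dedup:
        df = df.drop_duplicates(subset=["chrom", "start", "end", "strand"], keep="first")
    return FragmentSet(frags.sample_id, df.reset_index(drop=True))


def strand_split(frags: FragmentSet) -> tuple[FragmentSet, FragmentSet]:
    """Partition by strand; plus.library_size + minus.library_size is conserved."""
    df = frags.fragments
    plus = df[df["strand"] == "+"].reset_index(drop=True)
    minus = df[df["strand"] == "-"].reset_index(drop=True)
    return (
        FragmentSet(f"{frags.sample_id}.plus", plus),
        FragmentSet(f"{frags.sample_id}.minus", minus),
    )


def swap_strands(frags: FragmentSet) -> FragmentSet:
    """Relabel every fragment's strand (+ <-> -); used for symmetry checks."""
    df = frags.fragments.copy()
    df["strand"] = df["strand"].map({"+": "-", "-": "+"})
    return FragmentSet(frags.sample_id, df)


def compute_coverage(
    frags: FragmentSet, chrom_sizes: dict[str, int], bin_size: int
) -> CoverageTrack:
    """Overlap-bp binned coverage.

    Each fragment contributes its clipped overlap length (in bp) to every bin
    it intersects, so the track total equals the summed clipped fragment
    lengths exactly (integer mass conservation).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = frags.fragments
    unknown = set(df["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragments on unknown chromosomes: {sorted(unknown)}")
    values: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_size)
        sub = df[df["chrom"] == chrom]
        if len(sub) == 0:
            values[chrom] = np.zeros(n_bins)
            continue
        starts = np.clip(sub["start"].to_numpy(), 0, size)
        ends = np.clip(sub["end"].to_numpy(), 0, size)
        # per-base depth via difference array, then fold into bins
        delta = np.zeros(size + 1, dtype=np.int64)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        depth = np.cumsum(delta[:-1])
        pad = n_bins * bin_size - size
        if pad:
            depth = np.concatenate([depth, np.zeros(pad, dtype=np.int64)])
        values[chrom] = depth.reshape(n_bins, bin_size).sum(axis=1).astype(float)
    strands = set(df["strand"].unique())
    strand = strands.pop() if len(strands) == 1 else "both"
    return CoverageTrack(
        sample_id=frags.sample_id,
        strand=strand,
        bin_size=bin_size,
        chrom_sizes=dict(chrom_sizes),
        values=values,
        library_size=frags.library_size,
    )


def cpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale all bin values by 1e6 / library_size."""
    if track.library_size <= 0:
        raise ValueError("cannot CPM-normalise a track with library_size 0")
    factor = 1e6 / track.library_size
    return CoverageTrack(
        sample_id=track.sample_id,
        strand=track.strand,
        bin_size=track.bin_size,
        chrom_sizes=dict(track.chrom_sizes),
        values={c: v * factor for c, v in track.values.items()},
        library_size=track.library_size,
    )


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike, per_bp: bool = True) -> None:
    """Emit a run-length-compressed bedGraph (per-bp values by default)."""
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            size = track.chrom_sizes[chrom]
            vals = track.values[chrom] / (track.bin_size if per_bp else 1)
            b = track.bin_size
            run_val = None
            run_start = 0
            for i, v in enumerate(vals):
                if run_val is None:
                    run_val, run_start = v, i * b
                elif v != run_val:
                    fh.write(f"{chrom}\t{run_start}\t{min(i * b, size)}\t{run_val:g}\n")
                    run_val, run_start = v, i * b
            if run_val is not None:
                fh.write(f"{chrom}\t{run_start}\t{size}\t{run_val:g}\n")


def read_bedgraph(
    path: str | os.PathLike,
    chrom_sizes: dict[str, int],
    bin_size: int = 1,
    sample_id: str = "bedgraph",
) -> CoverageTrack:
    """Read a bedGraph into a per-bin track (values are per-bin totals)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    values: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        per_base = np.zeros(size)
        sub = df[df["chrom"] == chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            per_base[int(s): min(int(e), size)] = v
        n_bins = -(-size // bin_size)
        pad = n_bins * bin_size - size
        if pad:
            per_base = np.concatenate([per_base, np.zeros(pad)])
        values[chrom] = per_base.reshape(n_bins, bin_size).sum(axis=1)
    return CoverageTrack(
        sample_id=sample_id,
        strand="both",
        bin_size=bin_size,
        chrom_sizes=dict(chrom_sizes),
        values=values,
    )
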