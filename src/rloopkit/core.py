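"""Core genomic containers shared across the package.

All coordinates are 0-based half-open (BED convention). A *fragment* is the
sequenced insert of one strand-preserving ssDRIP library molecule; fragments,
not reads, are the atomic unit everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "score"]


@dataclass(frozen=True)
class GenomicInterval:
    """A chrom/start/end/strand record, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class FragmentSet:
    """Aligned, strand-labelled fragments for one sample.

    ``fragments`` is a DataFrame with columns chrom/start/end/strand/score.
    ``library_size`` is always the current number of fragments.
    """

    sample_id: str
    fragments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.fragments
        missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        self.fragments = df[FRAGMENT_COLUMNS].reset_index(drop=True)
        if len(df) and not set(df["strand"].unique()) <= {"+", "-"}:
            bad = sorted(set(df["strand"].unique()) - {"+", "-"})
            raise ValueError(f"fragment strands must be +/-; found {bad}")

    @property
    def library_size(self) -> int:
        return len(self.fragments)

    def sorted(self) -> "FragmentSet":
        df = self.fragments.sort_values(
            ["chrom", "start", "end", "strand"], kind="stable"
        ).reset_index(drop=True)
        return FragmentSet(self.sample_id, df)

    def midpoints(self) -> pd.DataFrame:
        """chrom + integer midpoint of every fragment (floor convention)."""
        df = self.fragments
        return pd.DataFrame(
            {"chrom": df["chrom"], "pos": (df["start"] + df["end"]) // 2}
        )


@dataclass
class CoverageTrack:
    """Binned signal over a genome.

    ``values[chrom]`` holds one float per bin; a bin's value is the *total*
    signal assigned to it (overlap-bp for fragment coverage), so per-bp signal
    is ``values / bin_size``. Vector length is ceil(chrom_length / bin_size).
    """

    sample_id: str
    strand: str  # "+", "-" or "both"
    bin_size: int
    chrom_sizes: dict[str, int]
    values: dict[str, np.ndarray]
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, size in self.chrom_sizes.items():
            n = -(-size // self.bin_size)
            v = np.asarray(self.values[chrom], dtype=float)
            if len(v) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(v)}"
                )
            self.values[chrom] = v

    def per_bp(self, chrom: str) -> np.ndarray:
        """Per-base signal for one chromosome (bin value spread evenly)."""
        size = self.chrom_sizes[chrom]
        return np.repeat(self.values[chrom] / self.bin_size, self.bin_size)[:size]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


@dataclass
class GeneModel:
    """One gene: span, strand, exon structure, biotype, optional expression."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"
    expression_cpm: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span {self.start}-{self.end}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError("exon outside gene span")

    @property
    def tss(self) -> int:
        """5' end of the gene in genomic coordinates."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """3' end (gene end / TTS) in genomic coordinates."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def intervals_to_frame(intervals: list[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "strand": [iv.strand for iv in intervals],
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    strand = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strand)
    ]
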