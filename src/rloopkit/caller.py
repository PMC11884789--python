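"""Windowed Poisson enrichment calling with a local-lambda background.

This is the peak-calling core of the package: treatment fragment midpoints
are counted in sliding windows and tested against a control-derived Poisson
expectation. The background rate for a window is the *maximum* of the global
control rate and the control rates in 1 kb / 5 kb / 10 kb spans centred on
the window (the classic local-lambda construction), scaled by the
treatment:control library-size ratio and floored so it is never zero.
Window p-values are Benjamini-Hochberg adjusted genome-wide and significant
windows are assembled into narrow or broad peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import FragmentSet, GenomicInterval

DEFAULT_OFFSETS = (1000, 5000, 10000)
WINDOW_COLUMNS = ["chrom", "start", "end", "count", "lam", "fold", "p", "q"]
PEAK_COLUMNS = ["chrom", "start", "end", "mode", "sample_id", "summit_q", "max_fold"]


def poisson_upper_tail(count: int, lam: float) -> float:
    """P(X >= count) for X ~ Poisson(lam); exactly 1 for count = 0."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return 1.0
    return float(stats.poisson.sf(count - 1, lam))


def _sorted_midpoints(frags: FragmentSet) -> dict[str, np.ndarray]:
    mids = frags.midpoints()
    return {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in mids.groupby("chrom", sort=False)
    }


def _span_rates(
    mids: np.ndarray, centers: np.ndarray, span: int, chrom_size: int
) -> np.ndarray:
    """Control midpoint rate (per bp) in a span centred on each window."""
    lo = np.clip(centers - span // 2, 0, chrom_size)
    hi = np.clip(centers + span - span // 2, 0, chrom_size)
    counts = np.searchsorted(mids, hi) - np.searchsorted(mids, lo)
    lengths = np.maximum(hi - lo, 1)
    return counts / lengths


def local_lambda(
    control: FragmentSet,
    window: GenomicInterval,
    chrom_sizes: dict[str, int],
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
    scale: float = 1.0,
) -> float:
    """Expected treatment count in ``window`` under the control background.

    lam = scale * window_length * max(global rate, local rates, floor) where
    the floor is one fragment per genome, so lam > 0 even for empty controls.
    """
    if window.chrom not in chrom_sizes:
        raise ValueError(f"window chromosome {window.chrom!r} not in genome")
    chrom_size = chrom_sizes[window.chrom]
    if window.end > chrom_size:
        raise ValueError("window extends past chromosome end")
    genome_length = sum(chrom_sizes.values())
    mids_by_chrom = _sorted_midpoints(control)
    mids = mids_by_chrom.get(window.chrom, np.array([], dtype=int))
    center = np.array([window.midpoint])
    global_rate = control.library_size / genome_length
    rate = max(global_rate, 1.0 / genome_length)
    for span in offsets:
        rate = max(rate, float(_span_rates(mids, center, span, chrom_size)[0]))
    return scale * window.length * rate


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity.

    Ties are broken by original index (stable sort), so the output is a
    deterministic, order-preserving function of the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def scan_windows(
    treat: FragmentSet,
    control: FragmentSet,
    chrom_sizes: dict[str, int],
    window_size: int = 200,
    step: int = 100,
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
    adjust: bool = True,
) -> pd.DataFrame:
    """Slide windows across the genome and test each against local lambda.

    Counts use fragment-midpoint assignment (each fragment lands in exactly
    one window per offset phase, keeping counts Poisson-like). Only windows
    with at least one treatment fragment are tested; BH adjustment is over
    all tested windows genome-wide.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    genome_length = sum(chrom_sizes.values())
    scale = (
        treat.library_size / control.library_size if control.library_size else 1.0
    )
    global_rate = control.library_size / genome_length
    floor_rate = max(global_rate, 1.0 / genome_length)
    treat_mids = _sorted_midpoints(treat)
    ctrl_mids = _sorted_midpoints(control)
    frames = []
    for chrom, size in chrom_sizes.items():
        t_mids = treat_mids.get(chrom)
        if t_mids is None or len(t_mids) == 0:
            continue
        starts = np.arange(0, size, step, dtype=np.int64)
        ends = np.minimum(starts + window_size, size)
        counts = np.searchsorted(t_mids, ends) - np.searchsorted(t_mids, starts)
        keep = counts > 0
        if not keep.any():
            continue
        starts, ends, counts = starts[keep], ends[keep], counts[keep]
        centers = (starts + ends) // 2
        c_mids = ctrl_mids.get(chrom, np.array([], dtype=int))
        rate = np.full(len(starts), floor_rate)
        for span in offsets:
            np.maximum(rate, _span_rates(c_mids, centers, span, size), out=rate)
        lam = scale * (ends - starts) * rate
        p = stats.poisson.sf(counts - 1, lam)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "count": counts,
                    "lam": lam,
                    "fold": counts / lam,
                    "p": p,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    windows = pd.concat(frames, ignore_index=True)
    windows["q"] = bh_adjust(windows["p"].to_numpy()) if adjust else np.nan
    return windows


def assemble_peaks(
    windows: pd.DataFrame,
    q_threshold: float,
    mode: str = "narrow",
    sample_id: str = "sample",
    narrow_gap: int = 0,
    broad_linking_q: float = 0.1,
    broad_gap: int = 1000,
) -> pd.DataFrame:
    """Merge significant windows into peaks.

    narrow: windows with q <= q_threshold merged when overlapping or within
    ``narrow_gap`` bp. broad: the same seeds, extended through flanking
    windows with q <= ``broad_linking_q`` and merged across gaps up to
    ``broad_gap`` bp; regions without a seed window are dropped. Broad peaks
    therefore always contain every narrow peak they overlap.
    """
    if mode not in ("narrow", "broad"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(windows) == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    if mode == "narrow":
        material = windows[windows["q"] <= q_threshold]
        gap = narrow_gap
    else:
        material = windows[windows["q"] <= broad_linking_q]
        gap = broad_gap
    if len(material) == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    material = material.sort_values(["chrom", "start"], kind="stable")
    rows = []
    for chrom, sub in material.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        qs = sub["q"].to_numpy()
        folds = sub["fold"].to_numpy()
        cur = [starts[0], ends[0], qs[0], folds[0]]
        for s, e, q, f in zip(starts[1:], ends[1:], qs[1:], folds[1:]):
            if s <= cur[1] + gap:
                cur[1] = max(cur[1], e)
                cur[2] = min(cur[2], q)
                cur[3] = max(cur[3], f)
            else:
                rows.append((chrom, *cur))
                cur = [s, e, q, f]
        rows.append((chrom, *cur))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit_q", "max_fold"])
    # broad regions must contain at least one truly significant seed
    peaks = peaks[peaks["summit_q"] <= q_threshold]
    peaks["mode"] = mode
    peaks["sample_id"] = sample_id
    return (
        peaks[PEAK_COLUMNS]
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def call_peaks(
    treat: FragmentSet,
    control: FragmentSet,
    chrom_sizes: dict[str, int],
    window_size: int = 200,
    step: int = 100,
    q_threshold: float = 0.001,
    modes: tuple[str, ...] = ("narrow", "broad"),
) -> pd.DataFrame:
    """Scan, adjust, and assemble peaks in the requested modes."""
    windows = scan_windows(treat, control, chrom_sizes, window_size, step)
    parts = [
        assemble_peaks(windows, q_threshold, mode=m, sample_id=treat.sample_id)
        for m in modes
    ]
    if not parts:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """narrowPeak-style BED6+: name, score = int(-10 log10 q) capped at 1000."""
    df = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    with open(path, "w") as fh:
        for i, row in df.iterrows():
            q = max(row["summit_q"], 1e-300)
            score = min(int(round(-10 * np.log10(q))), 1000)
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                f"{row['sample_id']}_{row['mode']}_{i}\t{score}\t.\t"
                f"{row['max_fold']:.4f}\t{-np.log10(max(row['summit_q'], 1e-300)):.4f}\n"
            )
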