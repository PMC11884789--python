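"""Metaplots around interval centers and binned-coverage PCA for sample QC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import CoverageTrack
from .fragments import cpm_normalize


@dataclass
class ProfileMatrix:
    """Per-center signal profile in a window around interval midpoints.

    ``matrix`` is centers x bins of mean per-bp signal; rows clipped at a
    chromosome edge carry NaN in bins with no covered bp and are averaged
    over covered bp only. ``aggregate``/``se`` are per-bin column summaries.
    """

    centers: pd.DataFrame
    flank: int
    n_bins: int
    matrix: np.ndarray
    aggregate: np.ndarray
    se: np.ndarray
    n_clipped: int = 0


def metaplot(
    track: CoverageTrack,
    centers: pd.DataFrame,
    flank: int = 5000,
    n_bins: int = 100,
) -> ProfileMatrix:
    """Mean per-bp signal in [mid - flank, mid + flank), rebinned to n_bins.

    Requires 2 * flank to be a multiple of n_bins. Invariant to the order of
    ``centers``; a constant track yields a constant aggregate exactly.
    """
    if len(centers) == 0:
        raise ValueError("metaplot needs at least one center")
    if flank <= 0 or (2 * flank) % n_bins != 0:
        raise ValueError("2 * flank must be a positive multiple of n_bins")
    bin_width = 2 * flank // n_bins
    per_bp_cache: dict[str, np.ndarray] = {}
    matrix = np.full((len(centers), n_bins), np.nan)
    n_clipped = 0
    for row_i, (_, c) in enumerate(centers.iterrows()):
        chrom = c["chrom"]
        if chrom not in per_bp_cache:
            per_bp_cache[chrom] = track.per_bp(chrom)
        sig = per_bp_cache[chrom]
        size = len(sig)
        mid = (int(c["start"]) + int(c["end"])) // 2
        lo, hi = mid - flank, mid + flank
        window = np.full(2 * flank, np.nan)
        s, e = max(lo, 0), min(hi, size)
        if s < e:
            window[s - lo: e - lo] = sig[s:e]
        if lo < 0 or hi > size:
            n_clipped += 1
        cells = window.reshape(n_bins, bin_width)
        covered = np.sum(~np.isnan(cells), axis=1)
        with np.errstate(invalid="ignore"):
            matrix[row_i] = np.where(
                covered > 0, np.nansum(cells, axis=1) / np.maximum(covered, 1), np.nan
            )
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # columns where every center is edge-clipped are legitimately NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        aggregate = np.nanmean(matrix, axis=0)
        n_rows = np.sum(~np.isnan(matrix), axis=0)
        sd = np.nanstd(matrix, axis=0, ddof=1) if len(centers) > 1 else np.zeros(n_bins)
        se = np.where(n_rows > 1, sd / np.sqrt(np.maximum(n_rows, 1)), 0.0)
    return ProfileMatrix(
        centers=centers.reset_index(drop=True),
        flank=flank,
        n_bins=n_bins,
        matrix=matrix,
        aggregate=aggregate,
        se=se,
        n_clipped=n_clipped,
    )


@dataclass
class PcaResult:
    """Sample coordinates on principal components and variance fractions."""

    coordinates: pd.DataFrame  # index: sample_id; columns: PC1..PCk
    variance_ratio: np.ndarray
    n_bins_used: int
    n_bins_dropped: int


def binned_pca(
    tracks: list[CoverageTrack], scale: bool = True
) -> PcaResult:
    """PCA of samples on their binned, CPM-normalised coverage.

    Bins are z-scored across samples when ``scale`` (the prcomp scale=TRUE
    convention); zero-variance bins are dropped and counted. Requires >= 3
    samples with identical binning.
    """
    if len(tracks) < 3:
        raise ValueError("binned_pca needs at least 3 samples")
    ref = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != ref.bin_size or t.chrom_sizes != ref.chrom_sizes:
            raise ValueError("all tracks must share binning and genome")
    rows = []
    for t in tracks:
        t = cpm_normalize(t) if t.library_size > 0 else t
        rows.append(np.concatenate([t.values[c] for c in ref.chrom_sizes]))
    X = np.vstack(rows)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("degenerate input: every bin has zero variance")
    X = X[:, keep]
    if scale:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    n_comp = min(len(tracks) - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    coordinates = pd.DataFrame(
        coords,
        index=[t.sample_id for t in tracks],
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return PcaResult(
        coordinates=coordinates,
        variance_ratio=pca.explained_variance_ratio_,
        n_bins_used=int(keep.sum()),
        n_bins_dropped=n_dropped,
    )


def central_flank_test(
    profile: ProfileMatrix, central_frac: float = 0.2, flank_frac: float = 0.25
) -> tuple[float, float]:
    """One-sided paired test: central bins above flank bins across centers.

    Returns (mean difference, one-sided p) from a paired t-test of each
    center's mean central signal against its mean flank signal.
    """
    from scipy import stats

    n = profile.n_bins
    c_lo = int(n * (0.5 - central_frac / 2))
    c_hi = int(n * (0.5 + central_frac / 2))
    f_n = int(n * flank_frac / 2)
    central = np.nanmean(profile.matrix[:, c_lo:c_hi], axis=1)
    flank = np.nanmean(
        np.concatenate([profile.matrix[:, :f_n], profile.matrix[:, n - f_n:]], axis=1),
        axis=1,
    )
    ok = ~(np.isnan(central) | np.isnan(flank))
    diff = central[ok] - flank[ok]
    if len(diff) < 2 or np.allclose(diff.std(ddof=1), 0):
        return float(np.mean(diff) if len(diff) else np.nan), 1.0
    t, p = stats.ttest_1samp(diff, 0.0, alternative="greater")
    return float(np.mean(diff)), float(p)
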