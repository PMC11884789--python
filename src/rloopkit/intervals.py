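"""Vectorised interval arithmetic on sorted arrays.

These helpers back the filter, merge and annotation steps. Overlap is always
"share >= 1 bp": half-open intervals [a, b) and [b, c) do NOT overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _require_cols(df: pd.DataFrame, name: str) -> None:
    for c in ("chrom", "start", "end"):
        if c not in df.columns:
            raise ValueError(f"{name} needs chrom/start/end columns")


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap >= 1 bp of any subject interval?

    O((n+m) log m) via per-chromosome sorted scan with a running max of ends.
    """
    _require_cols(query, "query")
    _require_cols(subject, "subject")
    out = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return out
    q_idx = np.arange(len(query))
    for chrom, sub in subject.groupby("chrom", sort=False):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        s_start = sub["start"].to_numpy()[order]
        s_end = sub["end"].to_numpy()[order]
        # prefix max of ends: subjects [0:i) reach at most run_end[i-1]
        run_end = np.maximum.accumulate(s_end)
        qs = query["start"].to_numpy()[mask]
        qe = query["end"].to_numpy()[mask]
        # candidates: subjects with start < query end
        idx = np.searchsorted(s_start, qe, side="left")
        hit = np.zeros(len(qs), dtype=bool)
        nz = idx > 0
        hit[nz] = run_end[idx[nz] - 1] > qs[nz]
        out[q_idx[mask]] = hit
    return out


def merge_overlapping(df: pd.DataFrame) -> pd.DataFrame:
    """Merge intervals that overlap by >= 1 bp (touching ones stay apart).

    Returns sorted chrom/start/end with a ``members`` column listing the
    original row indices of each cluster. Transitive: this is exactly the
    connected components of the >=1 bp overlap graph.
    """
    _require_cols(df, "df")
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "members"])
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        orig = sub.index.to_numpy()[order]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        members = [orig[0]]
        for s, e, i in zip(starts[1:], ends[1:], orig[1:]):
            if s < cur_e:  # >= 1 bp overlap with the running cluster
                cur_e = max(cur_e, int(e))
                members.append(i)
            else:
                rows.append((chrom, cur_s, cur_e, members))
                cur_s, cur_e, members = int(s), int(e), [i]
        rows.append((chrom, cur_s, cur_e, members))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "members"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
        drop=True
    )
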