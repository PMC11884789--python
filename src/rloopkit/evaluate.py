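"""Recovery scoring of pipeline output against planted truth.

A planted R-loop is *recovered* when some called total interval matches it
with Jaccard >= the threshold (intersection over union of the two
intervals). Class agreement compares the planted label (plus / minus /
unstranded) with the called classification. A called interval matching no
planted R-loop at the threshold is a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import RLoopSet


def jaccard(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = max(0, min(a_end, b_end) - max(a_start, b_start))
    union = (a_end - a_start) + (b_end - b_start) - inter
    return inter / union if union else 0.0


@dataclass
class RecoveryReport:
    sensitivity: float
    class_accuracy: float
    false_positives: int
    n_truth: int
    n_recovered: int
    confusion: pd.DataFrame  # planted class x called class counts


def _called_class(rlset: RLoopSet) -> pd.DataFrame:
    """Flatten an RLoopSet into intervals with a called-class column."""
    parts = []
    if len(rlset.stranded):
        s = rlset.stranded.copy()
        s["called"] = np.where(s["strand"] == "+", "plus", "minus")
        parts.append(s[["chrom", "start", "end", "called"]])
    if len(rlset.unstranded):
        u = rlset.unstranded.copy()
        u["called"] = "unstranded"
        parts.append(u[["chrom", "start", "end", "called"]])
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end", "called"])
    return pd.concat(parts, ignore_index=True)


def score_recovery(
    rlset: RLoopSet, truth_rloops: pd.DataFrame, min_jaccard: float = 0.5
) -> RecoveryReport:
    """Match called total R-loops to planted truth and score the result."""
    called = _called_class(rlset)
    classes = ["plus", "minus", "unstranded"]
    confusion = pd.DataFrame(
        0, index=classes, columns=classes + ["missed"], dtype=int
    )
    matched_called: set[int] = set()
    n_recovered = 0
    n_class_ok = 0
    for _, t in truth_rloops.iterrows():
        best_j, best_i = 0.0, None
        sub = called[called["chrom"] == t["chrom"]]
        for i, c in sub.iterrows():
            j = jaccard(t["start"], t["end"], c["start"], c["end"])
            if j > best_j:
                best_j, best_i = j, i
        if best_i is not None and best_j >= min_jaccard:
            n_recovered += 1
            matched_called.add(best_i)
            called_cls = called.loc[best_i, "called"]
            confusion.loc[t["klass"], called_cls] += 1
            if called_cls == t["klass"]:
                n_class_ok += 1
        else:
            confusion.loc[t["klass"], "missed"] += 1
    # false positives: called intervals matching no truth at the threshold
    fp = 0
    for i, c in called.iterrows():
        sub = truth_rloops[truth_rloops["chrom"] == c["chrom"]]
        best = max(
            (jaccard(t["start"], t["end"], c["start"], c["end"]) for _, t in sub.iterrows()),
            default=0.0,
        )
        if best < min_jaccard:
            fp += 1
    n_truth = len(truth_rloops)
    return RecoveryReport(
        sensitivity=n_recovered / n_truth if n_truth else float("nan"),
        class_accuracy=n_class_ok / n_recovered if n_recovered else float("nan"),
        false_positives=fp,
        n_truth=n_truth,
        n_recovered=n_recovered,
        confusion=confusion,
    )
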