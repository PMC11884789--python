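"""Protein-interactor prioritization and R-loop-proteome enrichment stats.

Implements the screening arithmetic used to nominate RNA-binding-protein
interactors of a transcription factor from pull-down mass spectrometry:

- abundance filter: > min_fold mean enrichment over controls AND a one-sided
  Welch t-test p < alpha on log-transformed, pseudocounted abundances (the
  pseudocount handles proteins undetected in every control);
- PSM filter: combined peptide-spectrum-match count strictly greater than
  min_psm AND fold enrichment >= min_fold;
- high-confidence R-loop proteome: exact intersection of independent R-loop
  proteome sets (case-normalised symbols);
- overlap enrichment: one-sided Fisher's exact test of interactors against
  an R-loop protein set over a stated background universe, computed as an
  exact hypergeometric upper tail in rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: overlap / interactors-only / set-only / neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


def hypergeom_upper_tail(table: ContingencyTable2x2) -> float:
    """Exact P(X >= a) for X ~ Hypergeom(N, a+b, a+c), in rational arithmetic."""
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    K = a + b  # interactors
    n = a + c  # R-loop set
    denom = comb(N, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), denom)
    return float(min(total, Fraction(1)))


def welch_log_ttest(
    exp: np.ndarray, ctrl: np.ndarray, pseudocount: float
) -> float:
    """One-sided Welch t-test p for log(exp + pc) > log(ctrl + pc)."""
    import warnings

    with warnings.catch_warnings():
        # all-zero controls (the common case here) trigger scipy's
        # constant-input precision warning; the Welch statistic is still valid
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            np.log(np.asarray(exp, dtype=float) + pseudocount),
            np.log(np.asarray(ctrl, dtype=float) + pseudocount),
            equal_var=False,
            alternative="greater",
        )
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def fold_enrichment(
    exp: np.ndarray, ctrl: np.ndarray, pseudocount: float
) -> float:
    return float(
        (np.mean(exp) + pseudocount) / (np.mean(ctrl) + pseudocount)
    )


def filter_enriched_interactors(
    table: pd.DataFrame,
    exp_cols: list[str],
    ctrl_cols: list[str],
    min_fold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    test=welch_log_ttest,
) -> set[str]:
    """Proteins with > min_fold pseudocounted mean enrichment AND p < alpha.

    ``table`` is indexed by protein id with per-replicate abundance columns.
    The significance test is pluggable; the default is a one-sided Welch
    t-test on log-pseudocounted abundances.
    """
    if len(exp_cols) < 2 or len(ctrl_cols) < 1:
        raise ValueError("need >= 2 experimental and >= 1 control replicates")
    kept = set()
    for pid, row in table.iterrows():
        exp = row[exp_cols].to_numpy(dtype=float)
        ctrl = row[ctrl_cols].to_numpy(dtype=float)
        if np.any(exp < 0) or np.any(ctrl < 0):
            raise ValueError(f"negative abundance for {pid}")
        fold = fold_enrichment(exp, ctrl, pseudocount)
        if fold > min_fold and test(exp, ctrl, pseudocount) < alpha:
            kept.add(str(pid))
    return kept


def prioritize_by_psm(
    table: pd.DataFrame,
    psm_cols: list[str],
    exp_cols: list[str],
    ctrl_cols: list[str],
    min_psm: int = 10,
    min_fold: float = 2.0,
    pseudocount: float = 0.5,
) -> set[str]:
    """Combined PSM strictly > min_psm AND fold enrichment >= min_fold."""
    kept = set()
    for pid, row in table.iterrows():
        psm = float(row[psm_cols].to_numpy(dtype=float).sum())
        fold = fold_enrichment(
            row[exp_cols].to_numpy(dtype=float),
            row[ctrl_cols].to_numpy(dtype=float),
            pseudocount,
        )
        if psm > min_psm and fold >= min_fold:
            kept.add(str(pid))
    return kept


def highconfidence_rloop_proteome(proteomes: list[set[str]]) -> set[str]:
    """Proteins shared by every input proteome (case-normalised symbols)."""
    if len(proteomes) < 2:
        raise ValueError("need at least two proteome sets to intersect")
    normed = [{p.upper() for p in s} for s in proteomes]
    out = normed[0]
    for s in normed[1:]:
        out = out & s
    return out


def rloop_overlap_enrichment(
    interactors: set[str],
    rloop_set: set[str],
    background_size: int,
) -> tuple[ContingencyTable2x2, float, float]:
    """2x2 table, odds ratio and one-sided (greater) Fisher exact p.

    ``background_size`` is the size of the protein universe (e.g. the
    catalogue of retina-expressed nuclear RNA-binding proteins); it must be
    at least the size of the union of the two sets.
    """
    inter = {p.upper() for p in interactors}
    rset = {p.upper() for p in rloop_set}
    a = len(inter & rset)
    b = len(inter - rset)
    c = len(rset - inter)
    d = background_size - a - b - c
    if d < 0:
        raise ValueError(
            f"background_size {background_size} smaller than set union {a + b + c}"
        )
    table = ContingencyTable2x2(a, b, c, d)
    return table, table.odds_ratio(), hypergeom_upper_tail(table)
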