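"""Interactor screening: abundance/PSM filters and Fisher overlap enrichment.

Filters a small pull-down quantification table, intersects independent
R-loop proteomes into a high-confidence set, and tests whether the retained
interactors are enriched for R-loop proteins over a background universe of
1534 retina-expressed nuclear RNA-binding proteins.
"""

import pandas as pd

from rloopkit.interactome import (
    filter_enriched_interactors,
    highconfidence_rloop_proteome,
    prioritize_by_psm,
    rloop_overlap_enrichment,
)

table = pd.DataFrame(
    {
        "e1": [10, 5, 0.5, 40], "e2": [12, 6, 0.4, 35], "e3": [11, 5, 0.6, 42],
        "c1": [1, 5, 0.5, 2], "c2": [1, 4, 0.5, 3], "c3": [1, 5, 0.4, 2],
        "psm": [15, 8, 2, 30],
    },
    index=["DHX9", "ACTB", "GAPDH", "HNRNPU"],
)
kept = filter_enriched_interactors(table, ["e1", "e2", "e3"], ["c1", "c2", "c3"])
print("enriched (>2-fold, p<0.05):", sorted(kept))
psm_kept = prioritize_by_psm(table, ["psm"], ["e1", "e2", "e3"], ["c1", "c2", "c3"])
print("PSM>10 and >=2-fold:", sorted(psm_kept))

proteomes = [
    {"DHX9", "HNRNPU", "DDX5", "SFPQ"},
    {"DHX9", "HNRNPU", "DDX5"},
    {"DHX9", "HNRNPU", "MATR3", "DDX5"},
    {"DHX9", "HNRNPU", "DDX5", "XRN2"},
]
highconf = highconfidence_rloop_proteome(proteomes)
print("high-confidence R-loop proteins (in all 4 studies):", sorted(highconf))

tab, oddsr, p = rloop_overlap_enrichment(kept, highconf, background_size=1534)
print(f"overlap {tab.a}/{tab.a + tab.b}, odds ratio {oddsr:.1f}, "
      f"one-sided Fisher p = {p:.2e}")
# A small p means the interactor set shares far more proteins with the
# R-loop proteome than a random draw from the background would.
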