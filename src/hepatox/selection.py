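"""Candidate stress-gene selection.

Reproduces the three-way filter used to pick follow-up genes: a gene must
(1) be cluster-central (kME strictly above a threshold, default 0.65) in one
of the target co-expression modules, (2) show a significantly increasing
concentration response (positive slope with adjusted p below ``de_alpha``)
for at least one chemical, and (3) appear on a curated literature-evidence
list.  The selection is the intersection of the three independently
computable filters.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression import ModuleAssignment

__all__ = ["SelectionCriteria", "select_candidates"]


@dataclasses.dataclass
class SelectionCriteria:
    target_modules: Sequence[str]
    evidence_list: Sequence[str]
    de_tables: Mapping[str, pd.DataFrame]  # chemical -> run_de output
    kme_threshold: float = 0.65
    de_alpha: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.kme_threshold <= 1.0):
            raise ValueError("kme_threshold must lie in (0, 1]")
        if not self.target_modules:
            raise ValueError("target_modules is empty")


def select_candidates(
    assignment: ModuleAssignment,
    criteria: SelectionCriteria,
    secondary: ModuleAssignment | None = None,
) -> pd.DataFrame:
    """Apply the centrality / induction / evidence filters and rank.

    ``secondary`` optionally imposes the centrality filter in a second
    dataset's module assignment as well (a gene must pass kME >
    threshold in both).  Returns a table (gene, module, kME,
    best_chemical, p_adj) ranked by descending kME, ties by ascending best
    adjusted p then gene id.
    """
    labels, kme_vals = assignment.labels, assignment.kme
    central = set(labels.index[
        labels.isin(list(criteria.target_modules))
        & (kme_vals > criteria.kme_threshold)
    ])
    if secondary is not None:
        central &= set(secondary.labels.index[
            secondary.kme > criteria.kme_threshold
        ])

    best: dict[str, tuple] = {}  # gene -> (p_adj, chemical)
    for chem, table in criteria.de_tables.items():
        hits = table[(table["p_adj"] < criteria.de_alpha) & (table["beta"] > 0)]
        for gene, p_adj in zip(hits["gene"], hits["p_adj"]):
            if gene not in best or p_adj < best[gene][0]:
                best[gene] = (float(p_adj), chem)

    evidence = set(criteria.evidence_list)
    selected = sorted(central & set(best) & evidence)
    rows = [
        {
            "gene": g,
            "module": labels[g],
            "kME": float(kme_vals[g]),
            "best_chemical": best[g][1],
            "p_adj": best[g][0],
        }
        for g in selected
    ]
    out = pd.DataFrame(rows, columns=["gene", "module", "kME",
                                      "best_chemical", "p_adj"])
    if len(out):
        out = (out.assign(_negk=lambda d: -d["kME"])
               .sort_values(["_negk", "p_adj", "gene"], kind="stable")
               .drop(columns="_negk").reset_index(drop=True))
    return out
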