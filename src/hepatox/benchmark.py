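"""Cross-model fold-change concordance benchmarking.

Given per-model log2 fold-change tables for the same treatment and a
reference ("gold standard") table, the gene spaces are harmonised (ortholog
mapping, intersection, restriction to the gold DE set) and each gene gets a
similarity

    Si = log2FC_model / log2FC_gold,

so Si = 1 means the model reproduces the reference induction exactly, and
negative Si a direction mismatch.  A recovery curve counts, for a grid of
thresholds t, the gold DE genes with Si >= t; the count at t = 1 is the
headline "recovered at equal-or-higher magnitude" summary.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "harmonize",
    "similarity",
    "recovery_curve",
    "recovered_at_one",
    "RecoveryCurve",
    "benchmark_models",
]

DEFAULT_GRID = np.round(np.arange(0.0, 2.0001, 0.05), 10)


def _dedup_map(ortholog_map: pd.DataFrame) -> dict:
    """Ortholog table to a dict, dropping one-to-many rows in either
    direction (ambiguous mappings are never arbitrarily resolved)."""
    m = ortholog_map.dropna()
    dup_src = m["source_symbol"].duplicated(keep=False)
    dup_dst = m["human_symbol"].duplicated(keep=False)
    bad = dup_src | dup_dst
    if bad.any():
        logger.warning("dropping %d ambiguous ortholog rows", int(bad.sum()))
    m = m[~bad]
    return dict(zip(m["source_symbol"], m["human_symbol"]))


def harmonize(
    gold: pd.DataFrame,
    models: Mapping[str, pd.DataFrame],
    ortholog_map: pd.DataFrame | None = None,
    map_models: tuple = (),
    gold_de_alpha: float = 0.05,
):
    """Map, intersect and restrict fold-change tables to the gold DE set.

    Model tables named in ``map_models`` have their symbols translated
    through the ortholog table (unmapped genes dropped with a warning).  The
    output universe is the intersection of gene ids across gold and all
    models, restricted to gold DE genes (``de_flag`` column if present, else
    ``p_adj`` < ``gold_de_alpha``).  Returns ``(gold_sub, model_subs)`` with
    identically ordered gene indices.
    """
    if not len(gold) or any(not len(t) for t in models.values()):
        raise ValueError("empty fold-change table")
    mapping = _dedup_map(ortholog_map) if ortholog_map is not None else {}

    mapped: dict[str, pd.DataFrame] = {}
    for name, table in models.items():
        t = table.copy()
        if name in map_models:
            t["gene"] = t["gene"].map(mapping)
            dropped = t["gene"].isna().sum()
            if dropped:
                logger.warning("%s: %d symbols without ortholog dropped", name, dropped)
            t = t.dropna(subset=["gene"])
        if t["gene"].duplicated().any():
            raise ValueError(f"duplicate gene ids in model table {name!r}")
        mapped[name] = t.set_index("gene")

    if "de_flag" in gold.columns:
        de = set(gold.loc[gold["de_flag"].astype(bool), "gene"])
    elif "p_adj" in gold.columns:
        de = set(gold.loc[gold["p_adj"] < gold_de_alpha, "gene"])
    else:
        raise ValueError("gold table needs a de_flag or p_adj column")

    universe = set(gold["gene"]) & de
    for t in mapped.values():
        universe &= set(t.index)
    if not universe:
        raise ValueError("empty gene universe after harmonisation")
    genes = sorted(universe)
    gold_sub = gold.set_index("gene").loc[genes]
    model_subs = {name: t.loc[genes] for name, t in mapped.items()}
    return gold_sub, model_subs


def similarity(fc_model, fc_gold):
    """Per-gene similarity Si = fc_model / fc_gold (log2 scale).

    Zero gold fold changes (excluded upstream by the gold-DE restriction)
    yield NaN with a warning rather than an exception.
    """
    fm = np.asarray(fc_model, dtype=float)
    fg = np.asarray(fc_gold, dtype=float)
    scalar = fm.ndim == 0
    fm, fg = np.atleast_1d(fm), np.atleast_1d(fg)
    if (fg == 0).any():
        logger.warning("zero gold fold change: Si flagged NaN for %d genes",
                       int((fg == 0).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.where(fg != 0, fm / fg, np.nan)
    return float(si[0]) if scalar else si


@dataclasses.dataclass
class RecoveryCurve:
    thresholds: np.ndarray
    counts: np.ndarray
    universe_size: int

    def fraction(self) -> np.ndarray:
        return self.counts / self.universe_size

    def at(self, threshold: float) -> int:
        idx = np.flatnonzero(np.isclose(self.thresholds, threshold))
        if idx.size == 0:
            raise KeyError(f"threshold {threshold} not on the grid")
        return int(self.counts[idx[0]])


def recovery_curve(si_values, thresholds=DEFAULT_GRID) -> RecoveryCurve:
    """Counts of genes with Si >= t over an ascending threshold grid."""
    si = np.asarray(si_values, dtype=float)
    si = si[~np.isnan(si)]
    if si.size == 0:
        raise ValueError("empty similarity set")
    t = np.asarray(thresholds, dtype=float)
    if (np.diff(t) < 0).any():
        raise ValueError("thresholds must be sorted ascending")
    counts = (si[None, :] >= t[:, None]).sum(axis=1)
    return RecoveryCurve(thresholds=t, counts=counts.astype(int),
                         universe_size=int(si.size))


def recovered_at_one(si_values) -> int:
    """Number of genes whose induction is recovered at equal or higher
    magnitude (Si >= 1)."""
    si = np.asarray(si_values, dtype=float)
    return int(np.sum(si[~np.isnan(si)] >= 1.0))


def benchmark_models(
    gold: pd.DataFrame,
    models: Mapping[str, pd.DataFrame],
    ortholog_map: pd.DataFrame | None = None,
    map_models: tuple = (),
    thresholds=DEFAULT_GRID,
    gold_de_alpha: float = 0.05,
) -> dict:
    """Full benchmark: harmonise, score Si per gene, build recovery curves.

    Returns per model a dict with the Si table, :class:`RecoveryCurve`, and
    the Si >= 1 count.
    """
    gold_sub, model_subs = harmonize(gold, models, ortholog_map,
                                     map_models=map_models,
                                     gold_de_alpha=gold_de_alpha)
    out = {}
    for name, table in model_subs.items():
        si = similarity(table["log2fc"].to_numpy(), gold_sub["log2fc"].to_numpy())
        records = pd.DataFrame({
            "gene": gold_sub.index,
            "fc_model": table["log2fc"].to_numpy(),
            "fc_gold": gold_sub["log2fc"].to_numpy(),
            "si": si,
        })
        curve = recovery_curve(si, thresholds)
        out[name] = {
            "similarity": records,
            "curve": curve,
            "recovered_at_one": recovered_at_one(si),
        }
    return out
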