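"""Stress-pathway overrepresentation z-scores.

For a probe universe of size N with R differentially expressed probes, a
pathway annotating n probes of which r are differentially expressed gets

    z = (r - n*R/N) / sqrt( n * (R/N) * (1 - R/N) * (1 - (n-1)/(N-1)) )

i.e. the observed overlap standardised by the mean and variance of the
hypergeometric null (drawing n probes without replacement from a universe
with R successes).  Positive z means the pathway is overrepresented among
the DE probes, negative z depleted; |z| >= 1.96 is the conventional 5%
two-sided significance threshold.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import run_de

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "enrichment_zscore",
    "enrich_pathways",
    "enrichment_profile",
    "read_gmt",
    "write_gmt",
]


@dataclasses.dataclass
class EnrichmentRecord:
    pathway: str
    N: int
    R: int
    n: int
    r: int
    z: float
    significant: bool
    direction: int  # sign(r - n*R/N); 0 at the null expectation
    degenerate: bool = False


def enrichment_zscore(N: int, R: int, r: int, n: int) -> float:
    """Hypergeometric-variance overrepresentation z-score.

    Returns NaN for degenerate configurations with zero null variance
    (R = 0, R = N, n = 0, or n = N).
    """
    for name, v in (("N", N), ("R", R), ("r", r), ("n", n)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    N, R, r, n = int(N), int(R), int(r), int(n)
    if N < 2:
        raise ValueError("universe size N must be >= 2")
    if not (r <= n <= N and r <= R <= N):
        raise ValueError("require 0 <= r <= min(n, R) and n, R <= N")
    p = R / N
    var = n * p * (1.0 - p) * (1.0 - (n - 1) / (N - 1))
    if var <= 0:
        return math.nan
    return (r - n * p) / math.sqrt(var)


def enrich_pathways(
    de_flags: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    threshold: float = 1.96,
    two_sided: bool = True,
) -> list:
    """Overrepresentation records for each pathway against a DE flag vector.

    ``de_flags`` is a boolean Series over the full assayed probe universe.
    Gene sets are intersected with the universe; sets with no probe in the
    universe are skipped with a warning.  Significance is |z| >= threshold
    when ``two_sided`` (default), else z >= threshold.
    """
    if de_flags.empty:
        raise ValueError("empty probe universe")
    universe = set(de_flags.index)
    de = set(de_flags.index[de_flags.astype(bool)])
    N, R = len(universe), len(de)

    records = []
    for pathway in gene_sets:
        members = set(gene_sets[pathway]) & universe
        n = len(members)
        if n == 0:
            logger.warning("pathway %s has no probe in the universe; skipped", pathway)
            continue
        r = len(members & de)
        z = enrichment_zscore(N, R, r, n)
        expected = n * R / N
        records.append(EnrichmentRecord(
            pathway=pathway, N=N, R=R, n=n, r=r, z=z,
            significant=bool(not math.isnan(z) and
                             ((abs(z) if two_sided else z) >= threshold)),
            direction=int(np.sign(r - expected)),
            degenerate=math.isnan(z),
        ))
    return records


def enrichment_profile(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    chemical: str,
    gene_sets: Mapping[str, Sequence[str]],
    de_alpha: float = 0.05,
    adjusted: bool = False,
    threshold: float = 1.96,
) -> pd.DataFrame:
    """Pathway x concentration matrix of enrichment z-scores for one chemical.

    For each positive concentration, DE flags are recomputed from the
    vehicle-vs-that-concentration contrast (unadjusted p < ``de_alpha`` by
    default, matching the overrepresentation statistic's own DE definition;
    set ``adjusted`` for BH-adjusted flags) and scored per pathway.
    """
    chem_design = design[design["chemical"] == chemical]
    if chem_design.empty:
        raise KeyError(f"chemical {chemical!r} absent from design")
    levels = sorted(chem_design["concentration_uM"].unique())
    if 0.0 not in levels:
        raise ValueError("design must include a vehicle (0) concentration")
    positive = [c for c in levels if c > 0]
    if not positive:
        raise ValueError("need at least one positive concentration")

    cols = {}
    for conc in positive:
        contrast = chem_design[chem_design["concentration_uM"].isin([0.0, conc])]
        table = run_de(counts, contrast, chemical, alpha=de_alpha)
        pcol = "p_adj" if adjusted else "p"
        flags = pd.Series(False, index=counts.index)
        de = table.loc[(table[pcol] < de_alpha) & (table["status"] == "ok"), "gene"]
        flags[de] = True
        records = enrich_pathways(flags, gene_sets, threshold=threshold)
        cols[conc] = {rec.pathway: rec.z for rec in records}

    prof = pd.DataFrame(cols)
    prof.index.name = "pathway"
    prof.columns.name = "concentration_uM"
    return prof


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Parse a GMT gene-set file: name, description, then tab-separated ids."""
    sets: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in gene_sets:
            desc = descriptions.get(name, name)
            fh.write("\t".join([name, desc, *gene_sets[name]]) + "\n")
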