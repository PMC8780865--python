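"""Concentration-response differential expression.

Counts are normalised with median-of-ratios size factors, expressed as
log2 counts-per-million for visualisation and network construction, and
tested per gene with a negative-binomial GLM of the form

    log mu = b0 + beta * concentration + log(size factor)

(i.e. expression modelled as a linear function of treatment concentration).
Significance is a Wald test on beta with Benjamini-Hochberg adjustment
across genes.  Dispersion is a per-gene method-of-moments estimate pooled
across concentration groups, with no cross-gene shrinkage — a deliberate,
documented simplification relative to shrinkage-based DE packages.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "log2cpm",
    "bh_adjust",
    "estimate_dispersion",
    "fit_gene_glm",
    "ConcentrationResponseDE",
    "run_de",
    "top_gene_zscore_matrix",
]

LN2 = float(np.log(2.0))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, computed on
    genes with no zero count; each sample's factor is the median ratio of
    its counts to the reference.  If no zero-free gene exists, falls back to
    total-count ratios (with a logged warning).
    """
    x = counts.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("counts must be a gene x sample matrix")
    if x.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    zero_free = (x > 0).all(axis=1)
    if zero_free.any():
        sub = x[zero_free]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    else:
        logger.warning("no zero-free gene; falling back to total-count size factors")
        factors = x.sum(axis=0)
        if (factors <= 0).any():
            raise ValueError("sample with zero total counts")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2cpm(counts: pd.DataFrame, size_factors: pd.Series | None = None,
            pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 counts-per-million: log2(1e6 * count / library + pseudocount).

    Library size is the column sum.  If ``size_factors`` is given, counts are
    first divided by them (so depth-normalised CPMs are returned); the CPM
    scale itself is already depth-invariant, so this only matters jointly
    with compositional differences.
    """
    x = counts.to_numpy(dtype=float)
    if size_factors is not None:
        x = x / np.asarray(size_factors, dtype=float)[None, :]
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    cpm = 1e6 * x / lib[None, :]
    return pd.DataFrame(np.log2(cpm + pseudocount), index=counts.index,
                        columns=counts.columns)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    Sorted p-values are scaled by m/rank, a running minimum from the largest
    rank down enforces monotonicity, and results are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def estimate_dispersion(y: np.ndarray, groups: np.ndarray,
                        sf: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled across concentration groups.

    On size-factor-normalised counts, the within-group variance s^2 (pooled
    with df weights) and grand mean m give alpha = max(0, (s^2 - m) / m^2).
    Groups with a single sample contribute no degrees of freedom.
    """
    z = y / sf
    num = 0.0
    df = 0
    for g in np.unique(groups):
        zg = z[groups == g]
        if zg.size >= 2:
            num += zg.var(ddof=1) * (zg.size - 1)
            df += zg.size - 1
    if df == 0:
        return 0.0
    s2 = num / df
    m = z.mean()
    if m <= 0:
        return 0.0
    return max(0.0, (s2 - m) / (m * m))


def fit_gene_glm(gene_counts, concentrations, size_factors=None,
                 dispersion: float | None = None) -> dict:
    """NB GLM of one gene's counts on treatment concentration.

    Log-link GLM with intercept + concentration and a log size-factor
    offset; the slope is reported as log2 fold change per concentration
    unit.  ``dispersion`` overrides the pooled method-of-moments estimate
    (0 selects the Poisson limit).  Returns a dict record with keys beta,
    se, wald, p, mean_expr, dispersion, status.
    """
    y = np.asarray(gene_counts, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if y.size != conc.size:
        raise ValueError("counts and concentrations have mismatched lengths")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    sf = np.ones_like(y) if size_factors is None else np.asarray(size_factors, float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    # normalise to geometric mean 1 so a common rescaling is inert
    sf = sf / np.exp(np.mean(np.log(sf)))

    record = {"beta": 0.0, "se": np.nan, "wald": np.nan, "p": 1.0,
              "mean_expr": float((y / sf).mean()), "dispersion": 0.0,
              "status": "ok"}
    if (y == 0).all():
        record["status"] = "untestable"
        return record

    alpha = (estimate_dispersion(y, conc, sf) if dispersion is None
             else float(dispersion))
    record["dispersion"] = alpha
    family = (sm.families.NegativeBinomial(alpha=alpha) if alpha > 0
              else sm.families.Poisson())
    X = sm.add_constant(conc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=family, offset=np.log(sf)).fit(maxiter=200)
        if not res.converged:
            record["status"] = "nonconverged"
            return record
    except (np.linalg.LinAlgError, ValueError, PerfectSeparationError):
        record["status"] = "nonconverged"
        return record

    beta_nat, se_nat = float(res.params[1]), float(res.bse[1])
    record["beta"] = beta_nat / LN2
    record["se"] = se_nat / LN2
    if se_nat > 0 and np.isfinite(se_nat):
        wald = beta_nat / se_nat
        record["wald"] = wald
        record["p"] = float(2.0 * stats.norm.sf(abs(wald)))
    else:
        record["status"] = "untestable"
        record["p"] = 1.0
    return record


class ConcentrationResponseDE(BaseEstimator):
    """Per-gene concentration-response differential expression.

    Fits ``log mu = b0 + beta*conc + log(sf)`` NB GLMs for every gene of one
    chemical's dose series and assembles a BH-adjusted Wald-test table.

    Parameters
    ----------
    alpha : float
        Adjusted-p threshold defining the DE set.
    log_conc : bool
        Use log10(concentration + log_conc_pseudo) as the covariate instead
        of the raw micromolar values (off by default; the linear covariate
        matches the modelled form).
    log_conc_pseudo : float
        Pseudo-concentration for the optional log covariate.
    dispersion : float or None
        Fixed NB dispersion for all genes; None estimates per gene.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-gene table (gene, beta, se, wald, p, p_adj, mean_expr, status)
        sorted by adjusted p.
    size_factors_ : pandas.Series
    de_genes_ : list of str
    """

    def __init__(self, alpha: float = 0.05, log_conc: bool = False,
                 log_conc_pseudo: float = 1.0, dispersion: float | None = None):
        self.alpha = alpha
        self.log_conc = log_conc
        self.log_conc_pseudo = log_conc_pseudo
        self.dispersion = dispersion

    def fit(self, counts: pd.DataFrame, design: pd.DataFrame,
            chemical: str | None = None):
        if chemical is not None:
            if chemical not in set(design["chemical"]):
                raise KeyError(f"chemical {chemical!r} absent from design")
            design = design[design["chemical"] == chemical]
        design = design.set_index("sample_id").loc[
            [s for s in counts.columns if s in set(design["sample_id"])]
        ]
        if design.shape[0] < 3:
            raise ValueError("need at least 3 samples for the chemical")
        conc = design["concentration_uM"].to_numpy(float)
        if np.unique(conc).size < 2:
            raise ValueError("need at least 2 distinct concentrations")
        sub = counts[design.index.tolist()]
        sf = size_factors(sub)
        cov = np.log10(conc + self.log_conc_pseudo) if self.log_conc else conc

        records = []
        sf_arr = sf.to_numpy()
        for gene, row in zip(sub.index, sub.to_numpy(dtype=float)):
            rec = fit_gene_glm(row, cov, sf_arr, dispersion=self.dispersion)
            rec["gene"] = gene
            records.append(rec)
        table = pd.DataFrame.from_records(records)
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table = table[["gene", "beta", "se", "wald", "p", "p_adj",
                       "mean_expr", "dispersion", "status"]]
        table = table.sort_values(["p_adj", "p", "gene"],
                                  kind="stable").reset_index(drop=True)
        self.results_ = table
        self.size_factors_ = sf
        self.de_genes_ = table.loc[table["p_adj"] < self.alpha, "gene"].tolist()
        self.chemical_ = chemical
        return self


def run_de(counts: pd.DataFrame, design: pd.DataFrame, chemical: str,
           alpha: float = 0.05, **kwargs) -> pd.DataFrame:
    """Fit the per-gene concentration-response GLM for one chemical and
    return the full DE table sorted by adjusted p (DE set: p_adj < alpha)."""
    est = ConcentrationResponseDE(alpha=alpha, **kwargs)
    est.fit(counts, design, chemical=chemical)
    return est.results_


def top_gene_zscore_matrix(de_table: pd.DataFrame, expr: pd.DataFrame,
                           design: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Z-scored expression profile of the top DE genes, for heatmaps.

    Selects the ``k`` smallest adjusted p-values (ties by larger \\|beta\\|
    then gene id), averages each gene's log2CPM over replicate samples per
    concentration, and standardises each gene's row to mean 0, SD 1 across
    concentrations.
    """
    testable = de_table[de_table["status"] != "untestable"].copy()
    if len(testable) < k:
        raise ValueError(f"fewer than k={k} testable genes")
    testable["absbeta"] = -testable["beta"].abs()
    top = (testable.sort_values(["p_adj", "absbeta", "gene"], kind="stable")
           .head(k)["gene"].tolist())

    meta = design.set_index("sample_id")
    cols = [s for s in expr.columns if s in meta.index]
    conc = meta.loc[cols, "concentration_uM"]
    levels = sorted(conc.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 concentrations to standardise rows")
    prof = pd.DataFrame(
        {lv: expr.loc[top, [c for c in cols if conc[c] == lv]].mean(axis=1)
         for lv in levels}
    )
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=1)
    if (sd == 0).any():
        sd = sd.replace(0.0, np.nan)
    z = prof.sub(mu, axis=0).div(sd, axis=0)
    z.index.name = "gene"
    z.columns.name = "concentration_uM"
    return z
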