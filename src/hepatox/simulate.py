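"""Ground-truthed synthetic data for every pipeline stage.

Emulates the inputs of a targeted-RNA-seq (TempO-Seq-style) toxicogenomics
study on hepatocyte-like cells: LDH plate absorbances driven by known 4PL
curves, negative-binomial count matrices with planted co-expression modules
and concentration-dependent stress-pathway effects, GMT gene-set
annotations, and paired model/gold fold-change tables with controlled
concordance.  Every generator takes an explicit integer seed and is
bit-reproducible under it.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytotox import four_param_logistic

__all__ = [
    "PlateTruth",
    "CountTruth",
    "BenchmarkTruth",
    "generate_plate",
    "generate_counts",
    "generate_benchmark",
    "default_plate_truths",
    "default_count_truth",
    "default_design",
]


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlateTruth:
    """True 4PL cytotoxicity curve and plate noise for one chemical.

    ``b, c, d, e`` are the hill slope, lower/upper asymptotes (% cytotoxicity)
    and inflection concentration (uM); ``nc_abs``/``pc_abs`` the negative- and
    positive-control absorbance levels (AU); ``noise_sd`` the absorbance-scale
    Gaussian noise SD.
    """

    chemical: str
    b: float = 2.0
    c: float = 0.0
    d: float = 100.0
    e: float = 50.0
    noise_sd: float = 0.02
    nc_abs: float = 0.2
    pc_abs: float = 1.0

    def __post_init__(self):
        if self.e <= 0:
            raise ValueError("inflection concentration e must be > 0")
        if self.nc_abs >= self.pc_abs:
            raise ValueError("nc_abs must be below pc_abs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass
class CountTruth:
    """Generative truth behind a probe x sample count matrix.

    ``module_assignment`` maps every gene to exactly one module label;
    ``pathway_sets`` are GMT-style gene sets; ``effect_profile`` maps
    (gene, chemical) to the log2 fold change per unit concentration (uM);
    ``dispersion`` holds per-gene NB dispersions alpha (variance =
    mu + alpha*mu^2, alpha = 0 degenerates to Poisson); ``baseline_mean`` the
    untreated expected counts; ``library_size`` optional per-sample relative
    sequencing depth (defaults to 1); ``module_latent_sd`` the SD of the
    shared log-normal module factor inducing within-module correlation.
    """

    module_assignment: Mapping[str, str]
    pathway_sets: Mapping[str, Sequence[str]]
    effect_profile: Mapping[tuple, float]
    dispersion: Mapping[str, float]
    baseline_mean: Mapping[str, float]
    library_size: Mapping[str, float] | None = None
    module_latent_sd: float = 0.0

    def __post_init__(self):
        genes = list(self.module_assignment)
        if not genes:
            raise ValueError("empty gene universe")
        for g in genes:
            a = self.dispersion.get(g, 0.0)
            if not np.isfinite(a) or a < 0:
                raise ValueError(f"dispersion for {g} must be finite and >= 0")
            if self.baseline_mean.get(g, 0.0) <= 0:
                raise ValueError(f"baseline mean for {g} must be > 0")

    @property
    def genes(self) -> list:
        return list(self.module_assignment)

    @property
    def chemicals(self) -> set:
        return {chem for (_, chem) in self.effect_profile}


@dataclasses.dataclass
class BenchmarkTruth:
    """Truth for the cross-model fold-change concordance benchmark.

    ``gold_log2fc`` is the reference (gold-standard) log2 fold change per
    gene; ``concordance`` maps each model name to (scale, noise_sd) so that
    model_log2fc = scale * gold + N(0, noise_sd); ``gold_de_set`` flags the
    genes considered differentially expressed in the gold standard;
    ``foreign_symbols`` optionally maps a model name to a human->foreign
    symbol renaming, emulating a non-human dataset that needs an ortholog
    table.
    """

    gold_log2fc: Mapping[str, float]
    concordance: Mapping[str, tuple]
    gold_de_set: Sequence[str]
    foreign_symbols: Mapping[str, Mapping[str, str]] | None = None

    def __post_init__(self):
        if not self.gold_log2fc:
            raise ValueError("empty gene universe")
        for model, (scale, noise) in self.concordance.items():
            if not (np.isfinite(scale) and np.isfinite(noise)):
                raise ValueError(f"non-finite concordance for {model}")
        bad = [g for g in self.gold_de_set if self.gold_log2fc.get(g, 0.0) == 0.0]
        if bad:
            raise ValueError(f"gold DE genes with zero fold change: {bad[:5]}")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_plate(
    truth: PlateTruth,
    concentrations: Sequence[float],
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate LDH absorbances for one chemical's dose series.

    Sample wells read ``nc_abs + (pc_abs - nc_abs) * f4PL(conc)/100`` plus
    Gaussian noise; NC and PC control wells (with the same noise) are
    appended.  Returns a table with columns well_id, chemical,
    concentration_uM, role, absorbance.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conc = np.asarray(list(concentrations), dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    span = truth.pc_abs - truth.nc_abs

    rows = []
    for c_i in conc:
        resp = float(four_param_logistic(c_i, truth.b, truth.c, truth.d, truth.e))
        mean_abs = truth.nc_abs + span * resp / 100.0
        for r in range(replicates):
            noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
            rows.append((f"{truth.chemical}_c{c_i:g}_r{r + 1}", truth.chemical,
                         c_i, "sample", mean_abs + noise))
    for role, level in (("NC", truth.nc_abs), ("PC", truth.pc_abs)):
        for r in range(replicates):
            noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
            rows.append((f"{truth.chemical}_{role}_r{r + 1}", truth.chemical,
                         0.0, role, level + noise))
    return pd.DataFrame(rows, columns=["well_id", "chemical", "concentration_uM",
                                       "role", "absorbance"])


def generate_counts(truth: CountTruth, design: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw an NB probe x sample count matrix from a :class:`CountTruth`.

    Per gene g and sample s the expected count is
    ``lib_s * base_g * 2^(effect[g, chem_s] * conc_s) * latent[mod_g, s]``
    where the latent module factor is log-normal with unit mean
    (``exp(sd*z - sd^2/2)``), shared by all genes of a module within a
    sample; counts are NB with variance mu + alpha*mu^2.
    """
    required = {"sample_id", "chemical", "concentration_uM"}
    if not required <= set(design.columns):
        raise ValueError(f"design must contain columns {sorted(required)}")
    if (design["concentration_uM"] < 0).any():
        raise ValueError("design concentrations must be >= 0")
    known = truth.chemicals
    unknown = set(design["chemical"]) - known
    if known and unknown:
        raise ValueError(f"chemicals absent from effect profile: {sorted(unknown)}")

    genes = truth.genes
    samples = design["sample_id"].tolist()
    modules = sorted(set(truth.module_assignment.values()))
    rng = np.random.default_rng(seed)

    sd = truth.module_latent_sd
    if sd > 0:
        latent = {
            (m, s): float(np.exp(sd * rng.standard_normal() - 0.5 * sd * sd))
            for m in modules for s in samples
        }
    else:
        latent = {}

    lib = truth.library_size or {}
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for j, (_, row) in enumerate(design.iterrows()):
        s, chem, conc = row["sample_id"], row["chemical"], float(row["concentration_uM"])
        sf = float(lib.get(s, 1.0))
        for i, g in enumerate(genes):
            eff = truth.effect_profile.get((g, chem), 0.0)
            mu = sf * truth.baseline_mean[g] * 2.0 ** (eff * conc)
            if sd > 0:
                mu *= latent[(truth.module_assignment[g], s)]
            alpha = truth.dispersion.get(g, 0.0)
            if alpha > 0:
                n_param = 1.0 / alpha
                p_param = n_param / (n_param + mu)
                counts[i, j] = rng.negative_binomial(n_param, p_param)
            else:
                counts[i, j] = rng.poisson(mu)
    out = pd.DataFrame(counts, index=pd.Index(genes, name="probe_id"), columns=samples)
    return out


def generate_benchmark(truth: BenchmarkTruth, seed: int):
    """Produce gold/model fold-change tables and an ortholog map.

    Returns ``(gold, models, ortholog_map)``: gold is a DataFrame (gene,
    log2fc, de_flag); ``models`` maps model name to a DataFrame (gene,
    log2fc) with ``model = scale * gold + N(0, noise_sd)``; the ortholog map
    (source_symbol, human_symbol) covers any foreign-symbol models and is
    empty otherwise.
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.gold_log2fc)
    gold_fc = np.array([truth.gold_log2fc[g] for g in genes], dtype=float)
    de = set(truth.gold_de_set)
    gold = pd.DataFrame({
        "gene": genes,
        "log2fc": gold_fc,
        "de_flag": [int(g in de) for g in genes],
    })

    models: dict[str, pd.DataFrame] = {}
    map_rows = []
    foreign = truth.foreign_symbols or {}
    for model in truth.concordance:
        scale, noise = truth.concordance[model]
        fc = scale * gold_fc
        if noise > 0:
            fc = fc + rng.normal(0.0, noise, size=len(genes))
        names = genes
        if model in foreign:
            rename = foreign[model]
            names = [rename.get(g, g) for g in genes]
            map_rows += [(rename[g], g) for g in rename]
        models[model] = pd.DataFrame({"gene": names, "log2fc": fc})
    ortholog_map = pd.DataFrame(sorted(set(map_rows)),
                                columns=["source_symbol", "human_symbol"])
    return gold, models, ortholog_map


# ---------------------------------------------------------------------------
# study-scale defaults
# ---------------------------------------------------------------------------

#: The 14 screened chemicals; the first four are the known acute
#: hepatotoxicants with dose-dependent LDH release.
ACUTE_CHEMICALS = ("amiodarone", "paraquat", "diclofenac", "clozapine")
FLAT_CHEMICALS = (
    "gentamicin", "lead_chloride", "ceria_nanoparticles", "busulfan",
    "doxorubicin", "cyclosporine_a", "pamidronate", "ibuprofen",
    "olanzapine", "valproic_acid",
)

#: Chemicals profiled by targeted RNA-seq at sub-IC10 concentrations.
SEQUENCED_CHEMICALS = (
    "amiodarone", "paraquat", "clozapine", "diclofenac",
    "gentamicin", "olanzapine", "ibuprofen",
)

STRESS_PATHWAYS = ("ATF4", "XBP1", "NRF2", "HIF1A", "PPARG", "AHR", "P53", "NFKB")


def default_plate_truths(seed: int = 0) -> list:
    """The study-like plate panel: 4 responsive + 10 flat chemicals.

    Responsive chemicals get an ascending 4PL (d near 80-100%); flat
    chemicals have c = d (no dose response).  Curve parameters vary mildly
    across chemicals via the seed.
    """
    rng = np.random.default_rng(seed)
    truths = []
    for chem in ACUTE_CHEMICALS:
        truths.append(PlateTruth(
            chemical=chem,
            b=float(rng.uniform(1.5, 3.0)),
            c=0.0,
            d=float(rng.uniform(70.0, 100.0)),
            e=float(rng.uniform(20.0, 80.0)),
            noise_sd=0.02,
        ))
    for chem in FLAT_CHEMICALS:
        truths.append(PlateTruth(chemical=chem, b=1.0, c=0.0, d=0.0,
                                 e=50.0, noise_sd=0.02))
    return truths


def default_design(
    chemicals: Sequence[str] = SEQUENCED_CHEMICALS,
    concentrations: Sequence[float] = (0.0, 2.5, 5.0, 10.0, 20.0),
    replicates: int = 2,
    time_h: float = 24.0,
) -> pd.DataFrame:
    """Sample design emulating the study: per chemical, a 5-point
    concentration series (vehicle included) with replicate differentiations."""
    rows = []
    for chem in chemicals:
        for conc in concentrations:
            for r in range(1, replicates + 1):
                rows.append((f"{chem}_c{conc:g}_r{r}", chem, float(conc),
                             float(time_h), r))
    return pd.DataFrame(rows, columns=["sample_id", "chemical",
                                       "concentration_uM", "time_h", "replicate"])


def default_count_truth(
    n_genes: int = 600,
    n_modules: int = 6,
    responsive_per_pathway: int = 25,
    effect_log2fc_per_uM: float = 0.05,
    dispersion_range: tuple = (0.01, 0.2),
    baseline_range: tuple = (50.0, 2000.0),
    module_latent_sd: float = 0.3,
    library_cv: float = 0.2,
    chemicals: Sequence[str] = SEQUENCED_CHEMICALS,
    design: pd.DataFrame | None = None,
    seed: int = 0,
) -> CountTruth:
    """A study-scale :class:`CountTruth` with planted modules and pathways.

    Genes ``G0001..`` are split evenly over ``n_modules`` modules.  The first
    two pathways (ATF4- and XBP1-branch stress responses) are planted inside
    the first module and respond to the cytotoxic chemicals with
    ``effect_log2fc_per_uM`` log2FC per uM; remaining pathways are random
    gene sets with no planted effect.  Dispersions are log-uniform in
    ``dispersion_range`` and baselines log-uniform in ``baseline_range``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    modules = {g: f"M{i % n_modules + 1}" for i, g in enumerate(genes)}
    by_module: dict[str, list] = {}
    for g, m in modules.items():
        by_module.setdefault(m, []).append(g)

    pathway_sets: dict[str, list] = {}
    planted = [p for p in STRESS_PATHWAYS[:2]]
    m1 = by_module["M1"]
    for i, p in enumerate(planted):
        block = m1[i * responsive_per_pathway:(i + 1) * responsive_per_pathway]
        pathway_sets[p] = list(block)
    for p in STRESS_PATHWAYS[2:]:
        pathway_sets[p] = sorted(rng.choice(genes, size=responsive_per_pathway,
                                            replace=False).tolist())

    responders = {chem: set() for chem in chemicals}
    effect: dict[tuple, float] = {}
    for chem in chemicals:
        if chem in ACUTE_CHEMICALS or chem == "ibuprofen":
            for p in planted:
                for g in pathway_sets[p]:
                    effect[(g, chem)] = effect_log2fc_per_uM
                    responders[chem].add(g)
        else:
            for g in genes:  # chemicals with no transcriptomic response
                effect.setdefault((g, chem), 0.0)
    # make the effect-profile domain cover every chemical for every gene
    for chem in chemicals:
        for g in genes:
            effect.setdefault((g, chem), 0.0)

    lo_a, hi_a = dispersion_range
    lo_b, hi_b = baseline_range
    dispersion = {g: float(np.exp(rng.uniform(np.log(lo_a), np.log(hi_a))))
                  for g in genes}
    baseline = {g: float(np.exp(rng.uniform(np.log(lo_b), np.log(hi_b))))
                for g in genes}

    library = None
    if design is not None and library_cv > 0:
        sigma = float(np.sqrt(np.log(1.0 + library_cv ** 2)))
        library = {
            s: float(np.exp(sigma * rng.standard_normal() - 0.5 * sigma * sigma))
            for s in design["sample_id"]
        }

    return CountTruth(
        module_assignment=modules,
        pathway_sets=pathway_sets,
        effect_profile=effect,
        dispersion=dispersion,
        baseline_mean=baseline,
        library_size=library,
        module_latent_sd=module_latent_sd,
    )
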