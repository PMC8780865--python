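"""End-to-end orchestration with reproducible run manifests.

``run_all`` executes simulate (optional) -> cytotox -> differential
expression (per chemical) -> pathway enrichment -> co-expression modules ->
candidate-gene selection -> benchmark, from a single flat configuration,
and writes a manifest recording the package version, parameters, seed and
SHA-256 hashes of every output file.  Two runs with the same configuration
and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .benchmark import benchmark_models
from .coexpression import CoexpressionNetwork
from .cytotox import classify_acute
from .diffexpr import log2cpm, run_de, top_gene_zscore_matrix
from .enrichment import enrichment_profile, read_gmt, write_gmt
from .selection import SelectionCriteria, select_candidates
from .simulate import (
    default_count_truth,
    default_design,
    default_plate_truths,
    BenchmarkTruth,
    generate_benchmark,
    generate_counts,
    generate_plate,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Flat run configuration (YAML file of scalar keys; CLI flags override).

    With ``simulate`` true all inputs are generated from the seed; otherwise
    the file paths must point at existing inputs.
    """

    out_dir: str = "hepatox_run"
    seed: int = 0
    simulate: bool = True
    # input paths (required when simulate is false)
    counts: str | None = None
    design: str | None = None
    gmt: str | None = None
    plates: str | None = None
    gold: str | None = None
    models: Sequence[str] = ()
    ortholog_map: str | None = None
    evidence: str | None = None
    # stage parameters
    n_genes: int = 300
    de_alpha: float = 0.05
    enrich_threshold: float = 1.96
    kme_threshold: float = 0.65
    power: object = "auto"
    min_module_size: int = 20
    icx_levels: Sequence[float] = (10.0, 50.0)
    threshold_grid: Sequence[float] = tuple(np.round(np.arange(0, 2.0001, 0.05), 10))

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("config field 'seed' must be an integer")
        if not (0 < self.de_alpha < 1):
            raise ValueError("config field 'de_alpha' must lie in (0, 1)")
        if not (0 < self.kme_threshold <= 1):
            raise ValueError("config field 'kme_threshold' must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("config field 'min_module_size' must be >= 2")
        if not self.simulate:
            for field in ("counts", "design", "gmt", "plates"):
                path = getattr(self, field)
                if path is None:
                    raise ValueError(f"config field '{field}' is required when "
                                     f"simulate is false")
                if not Path(path).exists():
                    raise FileNotFoundError(f"config field '{field}': no such "
                                            f"file {path!r}")


def load_config(path, **overrides) -> RunConfig:
    """Read a flat YAML config file; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def _child_seeds(seed: int, n: int) -> list:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate_stage(config: RunConfig, out: Path) -> dict:
    seeds = _child_seeds(config.seed, 5)
    sim = out / "simulated"
    design = default_design()
    truth = default_count_truth(n_genes=config.n_genes, design=design,
                                seed=seeds[0])
    counts = generate_counts(truth, design, seed=seeds[1])

    plates = []
    for i, pt in enumerate(default_plate_truths(seed=seeds[0])):
        plates.append(generate_plate(pt, concentrations=(0, 6.25, 12.5, 25, 50, 100),
                                     replicates=3, seed=seeds[2] + i))
    plate = pd.concat(plates, ignore_index=True)

    n_bench = 60
    rng = np.random.default_rng(seeds[3])
    bench_genes = [f"G{i + 1:04d}" for i in range(n_bench)]
    gold_fc = rng.normal(0.0, 2.0, size=n_bench)
    gold_fc[gold_fc == 0] = 0.5
    de_mask = np.abs(gold_fc) > 0.5
    btruth = BenchmarkTruth(
        gold_log2fc=dict(zip(bench_genes, gold_fc)),
        concordance={"hlc_tempoSeq": (1.0, 0.2), "hepaRG": (0.7, 0.3),
                     "rat_hepatocytes": (0.4, 0.3)},
        gold_de_set=[g for g, m in zip(bench_genes, de_mask) if m],
        foreign_symbols={"rat_hepatocytes": {g: g.replace("G", "Rat") for g in bench_genes}},
    )
    gold, models, ortho = generate_benchmark(btruth, seed=seeds[4])

    io.write_counts(counts, sim / "counts.tsv")
    io.write_tsv(design, sim / "design.tsv")
    io.write_tsv(plate, sim / "plates.tsv")
    write_gmt(truth.pathway_sets, sim / "pathways.gmt")
    io.write_tsv(gold, sim / "gold_fc.tsv")
    for name, table in models.items():
        io.write_tsv(table, sim / f"model_{name}.tsv")
    io.write_tsv(ortho, sim / "ortholog_map.tsv")
    evidence = sorted({g for (g, _), eff in truth.effect_profile.items() if eff != 0})
    (sim / "evidence.txt").write_text("\n".join(evidence) + "\n")
    io.write_json(
        {
            "modules": dict(truth.module_assignment),
            "responsive_genes": evidence,
            "gold_de_set": list(btruth.gold_de_set),
        },
        sim / "truth.json",
    )
    return {
        "counts": counts, "design": design, "plate": plate,
        "gene_sets": dict(truth.pathway_sets),
        "gold": gold, "models": models, "ortholog_map": ortho,
        "map_models": ("rat_hepatocytes",), "evidence": evidence,
    }


@_stage("load-inputs")
def _load_stage(config: RunConfig) -> dict:
    counts = io.read_counts(config.counts)
    design = io.read_design(config.design)
    plate = io.read_plate(config.plates)
    gene_sets = read_gmt(config.gmt)
    data = {"counts": counts, "design": design, "plate": plate,
            "gene_sets": gene_sets, "gold": None, "models": {},
            "ortholog_map": None, "map_models": (), "evidence": []}
    if config.gold:
        data["gold"] = io.read_fold_changes(config.gold)
        data["models"] = {Path(p).stem: io.read_fold_changes(p)
                          for p in config.models}
    if config.ortholog_map:
        data["ortholog_map"] = pd.read_csv(config.ortholog_map, sep="\t")
    if config.evidence:
        data["evidence"] = io.read_evidence_list(config.evidence)
    return data


@_stage("cytotox")
def _cytotox_stage(config: RunConfig, data: dict, out: Path) -> dict:
    result = classify_acute(data["plate"], icx_levels=config.icx_levels)
    payload = {
        chem: {
            "cytotoxic": cls.cytotoxic,
            "f_pvalue": cls.f_pvalue,
            "max_response": cls.max_response,
            "params": {"b": cls.fit.b, "c": cls.fit.c, "d": cls.fit.d,
                       "e": cls.fit.e},
            "icx": {f"IC{level:g}": (None if math.isnan(v) else v)
                    for level, v in cls.fit.icx.items()},
            "converged": cls.fit.converged,
        }
        for chem, cls in result.items()
    }
    io.write_json(payload, out / "cytotox" / "classification.json")
    return {chem: cls for chem, cls in result.items()}


@_stage("de")
def _de_stage(config: RunConfig, data: dict, out: Path) -> dict:
    counts, design = data["counts"], data["design"]
    expr = log2cpm(counts)
    tables = {}
    for chem in sorted(design["chemical"].unique()):
        table = run_de(counts, design, chem, alpha=config.de_alpha)
        tables[chem] = table
        io.write_tsv(table, out / "de" / f"{chem}.tsv")
        k = min(20, int((table["status"] != "untestable").sum()))
        if k >= 2:
            sub_design = design[design["chemical"] == chem]
            z = top_gene_zscore_matrix(table, expr, sub_design, k=k)
            io.write_tsv(z.reset_index(), out / "de" / f"heatmap_{chem}.tsv")
    return {"tables": tables, "expr": expr}


@_stage("enrich")
def _enrich_stage(config: RunConfig, data: dict, out: Path) -> dict:
    profiles = {}
    for chem in sorted(data["design"]["chemical"].unique()):
        prof = enrichment_profile(data["counts"], data["design"], chem,
                                  data["gene_sets"],
                                  threshold=config.enrich_threshold)
        profiles[chem] = prof
        io.write_tsv(prof.reset_index(), out / "enrich" / f"{chem}.tsv")
    return profiles


@_stage("modules")
def _modules_stage(config: RunConfig, data: dict, expr: pd.DataFrame,
                   out: Path) -> CoexpressionNetwork:
    net = CoexpressionNetwork(power=config.power,
                              min_module_size=config.min_module_size)
    net.fit(expr)
    activity = net.transform(expr)
    assignment = pd.DataFrame({
        "gene": net.labels_.index,
        "module": net.labels_.to_numpy(),
        "kME": net.kme_.to_numpy(),
    })
    io.write_tsv(assignment, out / "modules" / "assignment.tsv")
    io.write_tsv(net.eigengenes_.reset_index(), out / "modules" / "eigengenes.tsv")
    io.write_tsv(activity.reset_index(), out / "modules" / "activity.tsv")
    return net


@_stage("select-genes")
def _selection_stage(config: RunConfig, data: dict, net: CoexpressionNetwork,
                     de_tables: dict, out: Path) -> pd.DataFrame:
    evidence = data["evidence"]
    labels = net.labels_
    overlap = {}
    for module in sorted(set(labels) - {"unassigned"}):
        genes = set(labels.index[labels == module])
        overlap[module] = len(genes & set(evidence))
    target = [max(overlap, key=lambda m: (overlap[m], m))] if overlap else []
    if not target or overlap[target[0]] == 0:
        io.write_tsv(pd.DataFrame(columns=["gene", "module", "kME",
                                           "best_chemical", "p_adj"]),
                     out / "selection" / "candidates.tsv")
        return pd.DataFrame()
    criteria = SelectionCriteria(
        target_modules=target,
        evidence_list=evidence,
        de_tables=de_tables,
        kme_threshold=config.kme_threshold,
        de_alpha=config.de_alpha,
    )
    candidates = select_candidates(net.assignment_, criteria)
    io.write_tsv(candidates, out / "selection" / "candidates.tsv")
    return candidates


@_stage("benchmark")
def _benchmark_stage(config: RunConfig, data: dict, out: Path) -> dict:
    if data["gold"] is None:
        return {}
    results = benchmark_models(
        data["gold"], data["models"], data["ortholog_map"],
        map_models=data["map_models"],
        thresholds=np.asarray(config.threshold_grid, dtype=float),
    )
    rows = []
    summary = {}
    for name, res in sorted(results.items()):
        curve = res["curve"]
        for t, c in zip(curve.thresholds, curve.counts):
            rows.append((name, float(t), int(c), curve.universe_size))
        summary[name] = {
            "recovered_at_one": res["recovered_at_one"],
            "universe_size": curve.universe_size,
            "recovered_fraction_at_one": res["recovered_at_one"] / curve.universe_size,
        }
    io.write_tsv(pd.DataFrame(rows, columns=["model", "threshold", "count",
                                             "universe_size"]),
                 out / "benchmark" / "curves.tsv")
    io.write_json(summary, out / "benchmark" / "summary.json")
    return results


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the run manifest.

    Returns a dict of in-memory stage results (classification, de tables,
    enrichment profiles, fitted network, candidates, benchmark results).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data = _simulate_stage(config, out) if config.simulate else _load_stage(config)
    classes = _cytotox_stage(config, data, out)
    de = _de_stage(config, data, out)
    profiles = _enrich_stage(config, data, out)
    net = _modules_stage(config, data, de["expr"], out)
    candidates = _selection_stage(config, data, net, de["tables"], out)
    bench = _benchmark_stage(config, data, out)

    manifest = {
        "package": "hepatox",
        "version": __version__,
        "seed": int(config.seed),
        "parameters": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    io.write_json(manifest, out / "manifest.json")
    return {
        "classification": classes,
        "de_tables": de["tables"],
        "enrichment_profiles": profiles,
        "network": net,
        "candidates": candidates,
        "benchmark": bench,
        "manifest": manifest,
    }
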