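"""End-to-end runner: simulate/load -> preprocess -> learn -> enrich -> scan.

One pipeline run processes a study of replicate datasets sharing a
genotype matrix.  For each configured pooling unit (a list of replicate
indices) it pools the replicates, drops monomorphic SNPs, quartile-bins
Age, learns a network over SNPs + Sex + Smoke + Age + Affected,
extracts the DA/MBA/CA subsets, evaluates their causal enrichment, and
runs the Bonferroni logistic-scan comparison on the same pooled sample.
Everything is reproducible from the config and its seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (GenotypeMatrix, PhenotypeTable, filter_monomorphic,
                      pool_datasets, read_genotypes, read_phenotypes)
from .enrichment import EnrichmentResult, evaluate_network_subsets, format_p
from .graph import to_dot, write_adjacency
from .regression import bonferroni_evaluate, snp_scan, write_scan
from .scoring import DiscreteData
from .search import ScoredNetwork, SearchConfig, learn_structure
from .synthetic import SimConfig, generate_study

log = logging.getLogger("bnsnp")

COVARIATE_NODES = ("Sex", "Smoke", "Age")
OUTCOME_NODE = "Affected"


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs, pooling plan, search, outputs.

    Exactly one of ``sim`` (a SimConfig) or ``genotype_path`` +
    ``phenotype_paths`` (+ optional ``truth_path``) must be provided.
    ``pooling_plan`` lists replicate-index groups analysed as pooled
    units; default is one unit pooling every replicate.
    """

    seed: int
    sim: SimConfig | None = None
    genotype_path: str | None = None
    phenotype_paths: list[str] = field(default_factory=list)
    truth_path: str | None = None
    pooling_plan: list[list[int]] | None = None
    search: SearchConfig | None = None
    scan_alpha: float = 0.05
    outdir: str = "bnsnp_out"

    def __post_init__(self):
        has_sim = self.sim is not None
        has_files = self.genotype_path is not None
        if has_sim == has_files:
            raise ValueError("provide exactly one of a simulation block or input paths")
        if has_files and not self.phenotype_paths:
            raise ValueError("input-path mode needs at least one phenotype file")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError(f"{path}: config must state a seed explicitly")
        sim = SimConfig(**raw["sim"]) if "sim" in raw else None
        search = SearchConfig(**raw["search"]) if "search" in raw else None
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"{path}: unknown config keys {sorted(extra)}")
        kwargs = {k: v for k, v in raw.items() if k not in ("sim", "search")}
        return cls(sim=sim, search=search, **kwargs)


@dataclass
class UnitResult:
    """All results for one pooled analysis unit."""

    replicates: list[int]
    N: int
    m: int
    removed_snps: list[str]
    network: ScoredNetwork
    subset_results: list[EnrichmentResult]
    scan_result: EnrichmentResult


@dataclass
class RunReport:
    version: str
    seed: int
    units: list[UnitResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for unit in self.units:
            label = _replicate_label(unit.replicates)
            for res in unit.subset_results + [unit.scan_result]:
                rows.append({
                    "replicate_set": label, "method": res.method,
                    "k": res.k, "n": res.n, "N": res.N, "m": res.m,
                    "p_display": format_p(res.p_tail), "p_tail": res.p_tail,
                })
        return pd.DataFrame(rows)


def _replicate_label(reps: list[int]) -> str:
    return "+".join(str(r) for r in reps)


def build_discrete_data(g: GenotypeMatrix, ph: PhenotypeTable) -> tuple[DiscreteData, dict[str, str]]:
    """Assemble the categorical analysis table and the node role map.

    SNPs enter as 3-level dosages; Sex/Smoke/Affected as binaries; Age
    as its quartile bin (computed here if absent).
    """
    if ph.age_quartile is None:
        ph = ph.with_age_quartiles()
    names = list(g.snp_ids) + list(COVARIATE_NODES) + [OUTCOME_NODE]
    table = np.column_stack([
        g.dosages.astype(np.int64),
        ph.sex, ph.smoke, ph.age_quartile, ph.affected,
    ])
    cards = [3] * g.n_snps + [2, 2, 4, 2]
    roles = {s: "snp" for s in g.snp_ids}
    roles.update({c: "covariate" for c in COVARIATE_NODES})
    roles[OUTCOME_NODE] = "outcome"
    return DiscreteData(table, names, cards), roles


def analyze_pooled_unit(g: GenotypeMatrix, ph: PhenotypeTable, replicates: list[int],
                        search: SearchConfig, scan_alpha: float) -> UnitResult:
    """Preprocess, learn and evaluate one pooled sample."""
    filtered, removed = filter_monomorphic(g)
    ph = ph.with_age_quartiles()
    N = filtered.n_snps
    truth = frozenset(filtered.causal_snp_ids())
    m = len(truth)
    log.info("unit %s: N=%d polymorphic SNPs (m=%d causal), %d removed",
             _replicate_label(replicates), N, m, len(removed))
    data, roles = build_discrete_data(filtered, ph)
    network = learn_structure(data, search, roles)
    log.info("unit %s: learned %d-edge network, %s score %.3f",
             _replicate_label(replicates), network.dag.n_edges,
             network.score_type, network.score)
    subset_results = evaluate_network_subsets(network.dag, truth, N, m)
    scan = snp_scan(filtered, ph, covariates=("age", "sex"))
    scan_result = bonferroni_evaluate(scan, scan_alpha, truth, N, m)
    return UnitResult(replicates, N, m, removed, network, subset_results, scan_result)


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> RunReport:
    """Execute the full pipeline; optionally write all output artifacts."""
    stage = "load"
    try:
        if cfg.sim is not None:
            stage = "simulate"
            sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
            reps = generate_study(sim)
        else:
            g = read_genotypes(cfg.genotype_path, truth_path=cfg.truth_path)
            reps = [(g, read_phenotypes(p)) for p in cfg.phenotype_paths]
        plan = cfg.pooling_plan or [list(range(len(reps)))]
        for unit in plan:
            bad = [r for r in unit if not 0 <= r < len(reps)]
            if bad:
                raise ValueError(f"pooling plan references missing replicates {bad}")
        search = cfg.search or SearchConfig(seed=cfg.seed)
        if cfg.search is not None and cfg.search.seed != cfg.seed:
            search = dataclasses.replace(cfg.search, seed=cfg.seed)
        units = []
        outdir = Path(cfg.outdir)
        if write:
            outdir.mkdir(parents=True, exist_ok=True)
        for unit_reps in plan:
            stage = f"analyze unit {_replicate_label(unit_reps)}"
            g, ph = pool_datasets([reps[r] for r in unit_reps])
            unit = analyze_pooled_unit(g, ph, unit_reps, search, cfg.scan_alpha)
            units.append(unit)
            if write:
                label = _replicate_label(unit_reps)
                write_adjacency(unit.network.dag, outdir / f"structure_{label}.tsv")
                (outdir / f"structure_{label}.dot").write_text(to_dot(unit.network.dag))
                filtered, _ = filter_monomorphic(g)
                write_scan(snp_scan(filtered, ph.with_age_quartiles(),
                                    covariates=("age", "sex")),
                           outdir / f"scan_{label}.tsv")
        report = RunReport(__version__, cfg.seed, units)
        if write:
            stage = "report"
            write_report(report, outdir / "report.tsv")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def write_report(report: RunReport, path) -> None:
    """TSV report: display p (3 sig figs) plus full-precision column.

    The header comments document software version, seed and the (N, m)
    accounting per analysis unit, so every row's p_tail is recomputable
    from its own fields.
    """
    frame = report.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# bnsnp {report.version}, seed={report.seed}\n")
        for unit in report.units:
            fh.write(f"# unit {_replicate_label(unit.replicates)}: "
                     f"N={unit.N} m={unit.m}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
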