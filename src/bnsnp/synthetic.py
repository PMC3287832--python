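"""Simulation of GAW17-like rare-variant case-control studies.

The mini-exome design this module emulates has a distinctive replicate
structure: one fixed genotype matrix with a strongly rare-skewed allele
frequency spectrum and a planted subset of causal SNPs, reused across
every replicate, while the binary Affected outcome is re-drawn per
replicate from a logistic liability model on causal dosages and the
covariates Sex, Smoke and Age.  Sex and Age (and by default Smoke) are
fixed per individual across replicates, like genotypes.

Defaults mirror the Asian-pool scale of the emulated study: a few
hundred individuals, ~300 SNPs of which ~30% are causal, minor-allele
frequencies drawn from a truncated Beta(0.2, 2.0) so most variants are
rare, and an intercept/covariate combination giving roughly 30%
prevalence.  All randomness flows from a single root seed through fixed
per-purpose streams, so any replicate is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_io import GenotypeMatrix, PhenotypeTable, write_genotypes, write_phenotypes, write_truth


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    ``causal_effect_size`` is the per-alt-allele log-odds applied to
    every causal SNP (a sequence gives per-SNP effects);
    ``covariate_effects`` are log-odds for sex and smoke indicators and
    per-year of age.  ``seed`` fixes the complete output.
    """

    n_individuals: int = 400
    n_snps: int = 300
    n_causal: int = 90
    maf_beta: tuple[float, float] = (0.2, 2.0)
    causal_effect_size: float | tuple[float, ...] = 0.5
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.3, "smoke": 0.5, "age": 0.02})
    intercept: float = -2.2
    n_replicates: int = 10
    seed: int = 0
    smoke_fixed: bool = True

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_snps < 1 or self.n_replicates < 1:
            raise ValueError("n_snps and n_replicates must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("require 0 <= n_causal <= n_snps")
        if isinstance(self.causal_effect_size, (tuple, list)):
            if len(self.causal_effect_size) != self.n_causal:
                raise ValueError("need one causal effect size per causal SNP")

    def causal_betas(self) -> np.ndarray:
        if isinstance(self.causal_effect_size, (tuple, list)):
            return np.asarray(self.causal_effect_size, dtype=float)
        return np.full(self.n_causal, float(self.causal_effect_size))


def _stream(cfg: SimConfig, *key: int) -> np.random.Generator:
    # fixed per-purpose child streams of the root seed
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, *key]))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw the fixed genotype backbone.

    Per-SNP MAFs come from Beta(*cfg.maf_beta*) truncated by rejection
    to [1/(2 n), 0.5]; genotypes are Hardy-Weinberg binomial draws;
    ``n_causal`` SNPs are flagged causal uniformly at random.
    """
    rng = _stream(cfg, 0)
    lo = 1.0 / (2.0 * cfg.n_individuals)
    a, b = cfg.maf_beta
    mafs = np.empty(cfg.n_snps)
    filled = 0
    while filled < cfg.n_snps:
        draw = rng.beta(a, b, size=2 * (cfg.n_snps - filled))
        ok = draw[(draw >= lo) & (draw <= 0.5)]
        take = min(len(ok), cfg.n_snps - filled)
        mafs[filled:filled + take] = ok[:take]
        filled += take
    dosages = rng.binomial(2, mafs, size=(cfg.n_individuals, cfg.n_snps)).astype(np.int8)
    causal = np.zeros(cfg.n_snps, dtype=bool)
    causal[rng.choice(cfg.n_snps, size=cfg.n_causal, replace=False)] = True
    width = len(str(cfg.n_snps))
    snp_ids = [f"S{j + 1:0{width}d}" for j in range(cfg.n_snps)]
    sample_ids = [f"I{i + 1:04d}" for i in range(cfg.n_individuals)]
    return GenotypeMatrix(sample_ids, snp_ids, dosages, causal)


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig, replicate: int) -> PhenotypeTable:
    """Draw one replicate's phenotype table for the fixed genotypes.

    Sex, Smoke ~ Bernoulli(0.5) and Age ~ Uniform(20, 80) are fixed per
    individual across replicates (Smoke can instead be re-drawn per
    replicate with ``smoke_fixed=False``); Affected is a fresh logistic
    draw per replicate:

        logit P(affected) = intercept + sum_j beta_j dosage_j
                            + b_sex sex + b_smoke smoke + b_age age
    """
    if not 0 <= replicate < cfg.n_replicates:
        raise ValueError(
            f"replicate index {replicate} out of range [0, {cfg.n_replicates})")
    n = g.n_samples
    fixed = _stream(cfg, 1)
    sex = fixed.integers(0, 2, size=n)
    age = fixed.uniform(20.0, 80.0, size=n)
    smoke_fixed_draw = fixed.integers(0, 2, size=n)
    if cfg.smoke_fixed:
        smoke = smoke_fixed_draw
    else:
        smoke = _stream(cfg, 3, replicate).integers(0, 2, size=n)
    betas = cfg.causal_betas()
    causal_cols = g.dosages[:, g.causal_flags] if g.causal_flags is not None else None
    eta = np.full(n, cfg.intercept, dtype=float)
    if causal_cols is not None and causal_cols.shape[1]:
        eta += causal_cols @ betas
    ce = cfg.covariate_effects
    eta += ce.get("sex", 0.0) * sex + ce.get("smoke", 0.0) * smoke + ce.get("age", 0.0) * age
    prob = 1.0 / (1.0 + np.exp(-eta))
    affected = (_stream(cfg, 2, replicate).random(n) < prob).astype(np.int8)
    return PhenotypeTable(list(g.sample_ids), affected, sex, smoke, age)


def generate_study(cfg: SimConfig, outdir: str | Path | None = None
                   ) -> list[tuple[GenotypeMatrix, PhenotypeTable]]:
    """Generate all replicates; optionally write the TSV study files.

    Writes ``genotypes.tsv``, ``truth.tsv``, one
    ``phenotypes_rep<k>.tsv`` per replicate and a ``simconfig.yaml``
    provenance echo when ``outdir`` is given.
    """
    g = simulate_genotypes(cfg)
    reps = [(g, simulate_phenotypes(g, cfg, k)) for k in range(cfg.n_replicates)]
    if outdir is not None:
        outdir = Path(outdir)
        try:
            outdir.mkdir(parents=True, exist_ok=True)
            write_genotypes(g, outdir / "genotypes.tsv")
            write_truth(g, outdir / "truth.tsv")
            for k, (_, ph) in enumerate(reps):
                write_phenotypes(ph, outdir / f"phenotypes_rep{k}.tsv")
            blob = dataclasses.asdict(cfg)
            blob["causal_effect_size"] = (
                list(cfg.causal_effect_size)
                if isinstance(cfg.causal_effect_size, (tuple, list))
                else cfg.causal_effect_size)
            blob["maf_beta"] = list(cfg.maf_beta)
            with open(outdir / "simconfig.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump({"simconfig": blob}, fh, sort_keys=True)
        except OSError as exc:
            raise OSError(f"failed writing study files under {outdir}: {exc}") from exc
    return reps
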