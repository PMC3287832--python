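"""Genotype/phenotype containers, file formats and preprocessing.

The analysis operates on a complete (no missing calls) individuals-by-
SNPs dosage matrix coded 0/1/2 alt-allele copies, with per-SNP causal
truth flags when the study design provides them, plus a phenotype table
carrying the binary Affected outcome and the covariates Sex, Smoke and
Age.  Preprocessing mirrors the study protocol: pool subpopulation /
replicate datasets by row concatenation, drop SNPs monomorphic in the
pooled sample, and bin Age into sample quartiles for the discrete
network.

Formats
-------
Genotype TSV   header ``sample_id\\t<snp1>\\t<snp2>...``, cells 0|1|2.
Phenotype TSV  columns ``sample_id, affected, sex, smoke, age``.
Truth TSV      columns ``snp_id, causal`` (0/1).
VCF            read-only convenience, biallelic GT fields only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Individuals-by-SNPs alt-allele dosage matrix.

    ``dosages`` is ``(n_samples, n_snps)`` with entries in {0, 1, 2};
    ``causal_flags`` (optional) marks SNPs that are true causal variants
    in a simulated or benchmark study.  Sample ids may repeat after
    pooling replicates (identical genotypes recur); SNP ids are unique.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    causal_flags: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if self.dosages.size and not np.isin(self.dosages, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.dosages, (0, 1, 2)))[0]
            raise ValueError(
                f"dosage at sample {self.sample_ids[bad[0]]!r}, "
                f"SNP {self.snp_ids[bad[1]]!r} is not in {{0, 1, 2}}"
            )
        self.dosages = self.dosages.astype(np.int8)
        if self.causal_flags is not None:
            self.causal_flags = np.asarray(self.causal_flags, dtype=bool)
            if self.causal_flags.shape != (len(self.snp_ids),):
                raise ValueError("causal_flags must have one entry per SNP")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise ValueError(f"unknown SNP id {snp_id!r}") from None

    def dosage_column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def causal_snp_ids(self) -> list[str]:
        if self.causal_flags is None:
            return []
        return [s for s, c in zip(self.snp_ids, self.causal_flags) if c]


@dataclass
class PhenotypeTable:
    """Per-individual phenotype records aligned to a GenotypeMatrix.

    ``affected``/``sex``/``smoke`` are 0/1; ``age`` is in years;
    ``age_quartile`` appears only after :func:`bin_age_quartiles` has
    been applied (via :meth:`with_age_quartiles`).
    """

    sample_ids: list[str]
    affected: np.ndarray
    sex: np.ndarray
    smoke: np.ndarray
    age: np.ndarray
    age_quartile: np.ndarray | None = field(default=None)

    def __post_init__(self):
        n = len(self.sample_ids)
        for name in ("affected", "sex", "smoke"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per sample")
            if arr.size and not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be binary 0/1")
            setattr(self, name, arr.astype(np.int8))
        self.age = np.asarray(self.age, dtype=float)
        if self.age.shape != (n,):
            raise ValueError("age must have one entry per sample")
        if self.age.size and (not np.isfinite(self.age).all() or (self.age < 0).any()):
            raise ValueError("ages must be finite and non-negative")
        if self.age_quartile is not None:
            self.age_quartile = np.asarray(self.age_quartile, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_age_quartiles(self) -> "PhenotypeTable":
        return replace(self, age_quartile=bin_age_quartiles(self.age))


# ---------------------------------------------------------------------
# readers / writers

def read_genotypes(path, format: str = "tsv", truth_path=None) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or VCF.

    TSV: header row of SNP ids, first column the sample id, cells 0/1/2.
    VCF: biallelic records only; GT converted to alt-allele dosage
    (multi-allelic sites are an error, never silently dropped).  If
    ``truth_path`` is given, causal flags are attached from a truth TSV.
    """
    if format == "tsv":
        g = _read_genotypes_tsv(path)
    elif format == "vcf":
        g = _read_genotypes_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if truth_path is not None:
        g = attach_truth(g, read_truth(truth_path))
    return g


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sample_id":
            raise ValueError(f"{path}: first header column must be 'sample_id'")
        snp_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}")
            sample_ids.append(cells[0])
            row = []
            for j, cell in enumerate(cells[1:]):
                if cell not in ("0", "1", "2"):
                    raise ValueError(
                        f"{path}:{lineno}: malformed dosage {cell!r} in column {snp_ids[j]!r}"
                    )
                row.append(int(cell))
            rows.append(row)
    return GenotypeMatrix(sample_ids, snp_ids,
                          np.array(rows, dtype=np.int8).reshape(len(rows), len(snp_ids)))


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF support requires cyvcf2 (install bnsnp[vcf])") from exc
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic site {rec.CHROM}:{rec.POS} is not supported"
            )
        gts = np.asarray(rec.genotype.array())[:, :2]
        if (gts < 0).any():
            raise ValueError(f"{path}: missing genotype at {rec.CHROM}:{rec.POS}")
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        columns.append(gts.sum(axis=1).astype(np.int8))
    dosages = (np.column_stack(columns) if columns
               else np.zeros((len(sample_ids), 0), dtype=np.int8))
    return GenotypeMatrix(sample_ids, snp_ids, dosages)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(g.snp_ids) + "\n")
        for sid, row in zip(g.sample_ids, g.dosages):
            fh.write(sid + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "affected", "sex", "smoke", "age"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    return PhenotypeTable(
        list(df["sample_id"]),
        df["affected"].to_numpy(), df["sex"].to_numpy(),
        df["smoke"].to_numpy(), df["age"].to_numpy(),
    )


def write_phenotypes(ph: PhenotypeTable, path) -> None:
    df = pd.DataFrame({
        "sample_id": ph.sample_ids,
        "affected": ph.affected, "sex": ph.sex,
        "smoke": ph.smoke, "age": ph.age,
    })
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if not {"snp_id", "causal"} <= set(df.columns):
        raise ValueError(f"{path}: truth TSV needs columns snp_id, causal")
    return {s: bool(c) for s, c in zip(df["snp_id"], df["causal"])}


def write_truth(g: GenotypeMatrix, path) -> None:
    if g.causal_flags is None:
        raise ValueError("genotype matrix carries no causal flags")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\tcausal\n")
        for snp, flag in zip(g.snp_ids, g.causal_flags):
            fh.write(f"{snp}\t{int(flag)}\n")


def attach_truth(g: GenotypeMatrix, truth: dict[str, bool]) -> GenotypeMatrix:
    missing = [s for s in g.snp_ids if s not in truth]
    if missing:
        raise ValueError(f"truth labels missing for SNPs: {missing[:5]}...")
    flags = np.array([truth[s] for s in g.snp_ids], dtype=bool)
    return GenotypeMatrix(g.sample_ids, g.snp_ids, g.dosages, flags)


# ---------------------------------------------------------------------
# preprocessing

def filter_monomorphic(g: GenotypeMatrix,
                       sample_subset: Sequence[str] | None = None
                       ) -> tuple[GenotypeMatrix, list[str]]:
    """Drop SNPs showing a single dosage value within ``sample_subset``.

    Returns the filtered matrix (restricted to the subset's rows) and
    the removed SNP ids.  The retained SNP count and retained causal
    count become the N and m of downstream enrichment arithmetic.
    """
    if sample_subset is None:
        rows = np.arange(g.n_samples)
    else:
        sample_subset = list(sample_subset)
        if not sample_subset:
            raise ValueError("sample subset must be non-empty")
        pos: dict[str, list[int]] = {}
        for i, sid in enumerate(g.sample_ids):
            pos.setdefault(sid, []).append(i)
        unknown = [s for s in set(sample_subset) if s not in pos]
        if unknown:
            raise ValueError(f"samples not in matrix: {sorted(unknown)}")
        rows = np.array(sorted({i for s in sample_subset for i in pos[s]}))
    sub = g.dosages[rows]
    poly = np.array([len(np.unique(sub[:, j])) >= 2 for j in range(g.n_snps)])
    removed = [s for s, keep in zip(g.snp_ids, poly) if not keep]
    kept_ids = [s for s, keep in zip(g.snp_ids, poly) if keep]
    flags = g.causal_flags[poly] if g.causal_flags is not None else None
    filtered = GenotypeMatrix([g.sample_ids[i] for i in rows], kept_ids,
                              sub[:, poly], flags)
    return filtered, removed


def bin_age_quartiles(ages: Iterable[float]) -> np.ndarray:
    """Map ages to quartile bins {0, 1, 2, 3} by sample quantiles.

    Boundaries are the 25/50/75 empirical percentiles (linear
    interpolation); values <= Q1 -> 0, <= Q2 -> 1, <= Q3 -> 2, else 3.
    An all-equal input collapses to bin 0.
    """
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    if not np.isfinite(ages).all():
        raise ValueError("ages must be finite")
    q1, q2, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
    bins = np.full(ages.shape, 3, dtype=np.int8)
    bins[ages <= q3] = 2
    bins[ages <= q2] = 1
    bins[ages <= q1] = 0
    return bins


def pool_datasets(parts: Sequence[tuple[GenotypeMatrix, PhenotypeTable]]
                  ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Row-concatenate aligned (genotype, phenotype) datasets.

    All parts must share an identical SNP id list; duplicate sample ids
    are permitted (replicates repeat genotypes with re-drawn outcomes).
    """
    if not parts:
        raise ValueError("no datasets to pool")
    ref = parts[0][0].snp_ids
    for g, ph in parts:
        if g.snp_ids != ref:
            diff = sorted(set(g.snp_ids) ^ set(ref))
            raise ValueError(f"SNP id mismatch across parts; symmetric difference: {diff}")
        if g.n_samples != ph.n_samples:
            raise ValueError("genotype and phenotype row counts differ within a part")
    sample_ids = [s for g, _ in parts for s in g.sample_ids]
    dosages = np.vstack([g.dosages for g, _ in parts])
    flags = parts[0][0].causal_flags
    pooled_g = GenotypeMatrix(sample_ids, list(ref), dosages, flags)
    pooled_ph = PhenotypeTable(
        [s for _, ph in parts for s in ph.sample_ids],
        np.concatenate([ph.affected for _, ph in parts]),
        np.concatenate([ph.sex for _, ph in parts]),
        np.concatenate([ph.smoke for _, ph in parts]),
        np.concatenate([ph.age for _, ph in parts]),
    )
    return pooled_g, pooled_ph


# ---------------------------------------------------------------------
# linkage disequilibrium

@dataclass(frozen=True)
class LdResult:
    """Pairwise LD between two SNPs: r^2 and |D'| (both in [0, 1])."""

    snp_a: str
    snp_b: str
    r2: float
    d_prime: float


def ld_pairwise(g: GenotypeMatrix, snp_a: str, snp_b: str,
                max_iter: int = 100, tol: float = 1e-8) -> LdResult:
    """Two-locus LD from unphased dosages via EM haplotype estimation.

    The only phase-ambiguous configuration is the double heterozygote;
    EM splits its mass between the coupling and repulsion haplotype
    pairs at each iteration.  r^2 = D^2 / (pA pa pB pb) and
    D' = |D| / Dmax on the EM haplotype frequencies.  Monomorphic input
    SNPs are an error.
    """
    a = g.dosage_column(snp_a).astype(float)
    b = g.dosage_column(snp_b).astype(float)
    for name, col in ((snp_a, a), (snp_b, b)):
        if np.unique(col).size < 2:
            raise ValueError(f"SNP {name!r} is monomorphic; LD undefined")
    n_hap = 2.0 * len(a)
    pA = a.sum() / n_hap   # alt-allele frequency at locus a
    pB = b.sum() / n_hap
    # known haplotype counts from unambiguous genotype cells
    dh = (a == 1) & (b == 1)
    n_dh = float(dh.sum())
    # unambiguous haplotype contributions: min(a, b) alt-alt copies per
    # individual except the phase-ambiguous double heterozygote
    known_11 = float(np.minimum(a, b)[~dh].sum())
    known_10 = float(np.maximum(a - b, 0)[~dh].sum())
    known_01 = float(np.maximum(b - a, 0)[~dh].sum())
    known_00 = n_hap - 2 * n_dh - known_11 - known_10 - known_01
    # init at linkage equilibrium
    f11, f10, f01, f00 = pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)
    for _ in range(max_iter):
        denom = f11 * f00 + f10 * f01
        coupling = (f11 * f00 / denom) if denom > 0 else 0.5
        e11 = known_11 + n_dh * coupling
        e00 = known_00 + n_dh * coupling
        e10 = known_10 + n_dh * (1 - coupling)
        e01 = known_01 + n_dh * (1 - coupling)
        new = (e11 / n_hap, e10 / n_hap, e01 / n_hap, e00 / n_hap)
        delta = max(abs(x - y) for x, y in zip(new, (f11, f10, f01, f00)))
        f11, f10, f01, f00 = new
        if delta < tol:
            break
    D = f11 - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if dmax > 0 else 1.0
    return LdResult(snp_a, snp_b, min(r2, 1.0), min(d_prime, 1.0))
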