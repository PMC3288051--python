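"""Readers and writers: VCF / TSV genotypes, phenotype tables, result TSVs.

Genotypes are additively coded as the count of the VCF ALT allele (0/1/2,
missing as NaN); all joins between genotype and phenotype tables are keyed on
sample id, never on row order.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scan import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "read_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotypes",
    "align_samples",
    "load_config",
    "config_hash",
]

logger = logging.getLogger("regionpls")

PHENO_TRAITS = ("waist", "hip", "bmi")
PHENO_COVARIATES = ("sex", "age")


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF (`.vcf`) or a dosage TSV."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT fields into ALT-allele dosages (missing GT -> NaN).

    Multi-allelic records are skipped with a logged warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    dosages: list[np.ndarray] = []
    ids: list[str] = []
    positions: list[int] = []
    chrom: str | None = None
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            logger.warning("skipping multi-allelic record %s at %s:%d",
                           variant.ID, variant.CHROM, variant.POS)
            continue
        if chrom is None:
            chrom = variant.CHROM
        gts = variant.genotypes  # [allele1, allele2, phased] per sample
        row = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            row[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        dosages.append(row)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        positions.append(variant.POS)
    vcf.close()
    if not dosages:
        raise ValueError(f"no usable biallelic records in {path}")
    if n_skipped:
        logger.warning("skipped %d multi-allelic record(s)", n_skipped)
    return GenotypeMatrix(np.array(dosages).T, tuple(ids),
                          np.array(positions), chrom or ".", samples)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the TSV dosage layout written by :func:`write_dosage_tsv`.

    Columns: snp_id, chrom, pos, then one column per sample; missing dosages
    empty or NA.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"dosage TSV must contain columns {sorted(required)}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ValueError("dosage TSV has no sample columns")
    dosages = df[sample_cols].to_numpy(dtype=float).T
    chrom = df["chrom"].iloc[0]
    return GenotypeMatrix(dosages, tuple(df["snp_id"]),
                          df["pos"].to_numpy(), str(chrom), tuple(sample_cols))


def write_dosage_tsv(path: str | Path, genotypes: GenotypeMatrix) -> None:
    samples = genotypes.sample_ids or tuple(
        f"s{i + 1}" for i in range(genotypes.n))
    df = pd.DataFrame({
        "snp_id": genotypes.snp_ids,
        "chrom": genotypes.chromosome,
        "pos": genotypes.positions,
    })
    for i, s in enumerate(samples):
        df[s] = genotypes.dosages[i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype TSV (id, waist, hip, bmi and optional sex, age).

    Rows missing any trait value are dropped with a logged count; duplicate
    ids raise.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "id" not in df.columns:
        raise ValueError("phenotype table must have an 'id' column")
    missing = [t for t in PHENO_TRAITS if t not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks trait column(s): {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in phenotype table: {dupes[:5]}")
    df["id"] = df["id"].astype(str)
    complete = df[list(PHENO_TRAITS)].notna().all(axis=1)
    if (~complete).any():
        logger.warning("dropping %d individual(s) with missing trait values",
                       int((~complete).sum()))
    return df[complete].reset_index(drop=True)


def align_samples(
    genotypes: GenotypeMatrix, phenotypes: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Inner-join genotypes and phenotypes on sample id (order from genotypes).

    Individuals absent from either side are dropped with a logged count.
    """
    if genotypes.sample_ids is None:
        raise ValueError("genotype matrix carries no sample ids to join on")
    geno_ids = [str(s) for s in genotypes.sample_ids]
    pheno_ids = set(phenotypes["id"])
    keep = [i for i, s in enumerate(geno_ids) if s in pheno_ids]
    dropped = genotypes.n - len(keep) + len(pheno_ids - set(geno_ids))
    if dropped:
        logger.warning("dropping %d individual(s) absent from one side of the "
                       "genotype/phenotype join", dropped)
    if not keep:
        raise ValueError("no overlapping sample ids")
    sub = GenotypeMatrix(
        genotypes.dosages[keep],
        genotypes.snp_ids,
        genotypes.positions,
        genotypes.chromosome,
        tuple(geno_ids[i] for i in keep),
    )
    pheno = (phenotypes.set_index("id")
             .loc[[geno_ids[i] for i in keep]]
             .reset_index())
    return sub, pheno


def pheno_arrays(pheno: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None]:
    """Split a phenotype frame into the trait matrix and covariate matrix."""
    traits = pheno[list(PHENO_TRAITS)].to_numpy(dtype=float)
    cov_cols = [c for c in PHENO_COVARIATES if c in pheno.columns]
    if not cov_cols:
        return traits, None
    cov = pheno[cov_cols].copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"].str.lower()
                      .map({"male": 1.0, "m": 1.0, "female": 0.0, "f": 0.0}))
    return traits, cov.to_numpy(dtype=float)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration (for provenance lines)."""
    canon = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:12]
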