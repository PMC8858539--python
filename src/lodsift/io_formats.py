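"""Readers/writers for the standard file formats plus genotype-level QC.

QC at load time: multi-allelic and non-PASS variants are dropped, genotypes
with depth below 10x are set missing (when DP is present in the VCF),
individuals under 18 or with missing BP/covariates are excluded, and an
optional imputation-quality filter keeps variants with r2 above a threshold
(default 0.3).  These filters are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    InputError,
    PedigreeSet,
    validate_genetic_map,
    variant_key,
)

log = logging.getLogger("lodsift")

PHENO_REQUIRED = ("iid", "sbp", "dbp", "med", "age", "sex", "bmi", "study",
                  "center", "ancestry")


@dataclass(frozen=True)
class QcOptions:
    min_depth: int | None = 10
    require_pass: bool = True
    biallelic_only: bool = True
    min_age: float = 18.0
    r2_min: float | None = None     # e.g. 0.3 for imputed data


def read_vcf(path, qc: QcOptions = QcOptions()) -> GenotypeMatrix:
    """Read a VCF v4.2 into a GenotypeMatrix, applying variant/genotype QC."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosages, depths = [], [], []
    has_depth = False
    for v in vcf:
        if qc.biallelic_only and len(v.ALT) != 1:
            continue
        if qc.require_pass and v.FILTER is not None:  # None == PASS in cyvcf2
            continue
        if qc.r2_min is not None:
            r2 = v.INFO.get("R2")
            if r2 is not None and not float(r2) > qc.r2_min:
                continue
        dos = v.gt_types.astype(float)  # gts012: 0,1,2, 3=missing
        dos[dos == 3] = np.nan
        dp = None
        try:
            dp_arr = v.format("DP")
        except Exception:
            dp_arr = None
        if dp_arr is not None:
            dp = dp_arr.astype(float).reshape(-1)
            dp[dp < 0] = np.nan
            has_depth = True
            if qc.min_depth is not None:
                dos[~(dp >= qc.min_depth)] = np.nan
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        dosages.append(dos)
        depths.append(dp if dp is not None else np.full(len(samples), np.nan))
    if not rows:
        raise InputError(f"no variants pass QC in {path}")
    if qc.min_depth is not None and not has_depth:
        log.warning("VCF has no DP field; depth filter skipped")
    var = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    var["filter"] = "PASS"
    var.index = [variant_key(c, p, r, a) for c, p, r, a in rows]
    dosage = np.column_stack(dosages)
    depth = np.column_stack(depths) if has_depth else None
    return GenotypeMatrix(samples, var, dosage, depth)


def read_phenotypes(path, qc: QcOptions = QcOptions()) -> pd.DataFrame:
    pheno = pd.read_csv(path)
    missing = [c for c in PHENO_REQUIRED if c not in pheno.columns]
    if missing:
        raise InputError(f"phenotype file missing columns: {missing}")
    pheno["iid"] = pheno["iid"].astype(str)
    n0 = len(pheno)
    keep = (
        (pheno["age"] >= qc.min_age)
        & pheno["sbp"].notna() & pheno["dbp"].notna()
        & pheno["age"].notna() & pheno["bmi"].notna() & pheno["med"].notna()
        & (pheno["sbp"] > pheno["dbp"])
    )
    dropped = n0 - int(keep.sum())
    if dropped:
        log.info("phenotype QC excluded %d of %d individuals", dropped, n0)
    return pheno[keep].reset_index(drop=True)


def load_dataset(vcf_path, ped_path, pheno_path, map_path, anno_path,
                 qc: QcOptions = QcOptions()):
    """Load and QC the five standard inputs with a consistent sample order.

    Returns ``(genotypes, pedigrees, phenotypes, gmap, annotation)``.
    Genotype, pedigree and phenotype sample sets are intersected; phenotyped
    individuals absent from the VCF raise a keyed error.
    """
    genotypes = read_vcf(vcf_path, qc)
    pedigrees = PedigreeSet.from_ped(ped_path)
    pheno = read_phenotypes(pheno_path, qc)
    gmap = validate_genetic_map(
        pd.read_csv(map_path, sep="\t").rename(columns=str.lower))
    anno = pd.read_csv(anno_path, sep="\t")
    anno.columns = [c.lower() for c in anno.columns]

    vcf_ids = set(genotypes.samples)
    ped_ids = set(pedigrees.individuals)
    missing = sorted(ped_ids - vcf_ids)
    if missing:
        raise KeyError(f"pedigree individuals absent from VCF: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    pheno = pheno[pheno["iid"].isin(vcf_ids & ped_ids)].reset_index(drop=True)
    # order phenotypes by VCF sample order
    order = {s: i for i, s in enumerate(genotypes.samples)}
    pheno = pheno.sort_values("iid", key=lambda s: s.map(order)).reset_index(drop=True)
    return genotypes, pedigrees, pheno, gmap, anno


def write_results(results: pd.DataFrame, path) -> None:
    """Tab-separated association/meta report; p columns in scientific notation."""
    if results is None or len(results) == 0:
        raise InputError("no results to write")
    out = results.copy()
    for col in out.columns:
        if col == "p" or col.endswith("_p") or col.startswith("p_"):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{float(v):.6e}")
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def qc_summary(genotypes: GenotypeMatrix, pedigrees: PedigreeSet,
               pheno: pd.DataFrame) -> dict:
    """Counts a `lodsift load --check` run prints."""
    maf = genotypes.maf()
    return {
        "n_samples_vcf": genotypes.n_samples,
        "n_individuals_ped": len(pedigrees.individuals),
        "n_families": len(pedigrees.family_ids),
        "n_phenotyped": int(len(pheno)),
        "n_variants": genotypes.n_variants,
        "n_rare_maf_lt_5pct": int(np.sum(maf < 0.05)),
        "missing_genotype_rate": float(np.isnan(genotypes.dosage).mean()),
    }
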