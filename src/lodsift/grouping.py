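"""Per-gene variant sets from consequence annotations and frequencies.

Set 1: coding-consequence variants with MAF < 5%.  Set 2: the remaining
variants (synonymous included) within the gene body plus a 10 kb flank, with
MAF < 1%.  Set 3: set 1 plus the set-2 variants predicted functional
(CADD-phred > 10 or fathmmXF > 0.5).  MAF is computed on the analysis
sample of the current stratum; boundaries are strict.  Variants annotated to
several overlapping genes are retained in each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

CODING_CONSEQUENCES = frozenset({
    "splice_region_variant",
    "splice_acceptor_variant",
    "start_lost",
    "stop_lost",
    "stop_gained",
    "missense_variant",
    "inframe_deletion",
    "inframe_insertion",
    "exon_loss_variant",
    "frameshift_variant",
    "initiator_codon_variant",
})


@dataclass
class VariantSet:
    gene: str
    set_id: int                 # 1 coding, 2 non-coding, 3 combined
    keys: list[str]
    maf: pd.Series

    def __len__(self) -> int:
        return len(self.keys)


def is_coding(consequence) -> bool:
    if pd.isna(consequence):
        return False
    return str(consequence) in CODING_CONSEQUENCES


def build_variant_sets(selected_keys, annotation: pd.DataFrame,
                       genotypes: GenotypeMatrix, sample_ids=None,
                       flank_bp: int = 10_000, maf_coding: float = 0.05,
                       maf_noncoding: float = 0.01, cadd_min: float = 10.0,
                       fathmm_min: float = 0.5) -> dict[str, dict[int, VariantSet]]:
    """Assemble sets 1-3 for every annotated gene.

    ``annotation`` columns: key, gene, consequence, cadd_phred, fathmm_xf,
    gene_chrom, gene_start, gene_end (one row per variant x gene).  Variants
    missing from the annotation are treated as non-coding with missing
    scores (excluded from set 3's score branch) and logged.
    """
    selected = list(dict.fromkeys(selected_keys))
    sample_idx = (None if sample_ids is None
                  else genotypes.sample_indices(sample_ids))
    maf = pd.Series(genotypes.maf(sample_idx=sample_idx), index=genotypes.keys)

    anno = annotation[annotation["key"].isin(selected)].copy()
    missing = [k for k in selected if k not in set(anno["key"])]
    if missing:
        warnings.warn(f"{len(missing)} selected variants lack annotation; "
                      "treated as non-coding with missing scores")
        genes = anno[["gene", "gene_chrom", "gene_start", "gene_end"]].drop_duplicates()
        extra = []
        for k in missing:
            chrom, pos = k.split(":")[0], int(k.split(":")[1])
            for _, g in genes.iterrows():
                if (str(g["gene_chrom"]) == chrom
                        and g["gene_start"] - flank_bp <= pos - 1 < g["gene_end"] + flank_bp):
                    extra.append((k, g["gene"], np.nan, np.nan, np.nan,
                                  g["gene_chrom"], g["gene_start"], g["gene_end"]))
        if extra:
            anno = pd.concat([anno, pd.DataFrame(
                extra, columns=["key", "gene", "consequence", "cadd_phred",
                                "fathmm_xf", "gene_chrom", "gene_start",
                                "gene_end"])], ignore_index=True)

    out: dict[str, dict[int, VariantSet]] = {}
    for gene, sub in anno.groupby("gene", sort=True):
        sub = sub.sort_values("key", kind="stable")
        g0 = sub.iloc[0]
        lo = float(g0["gene_start"]) - flank_bp
        hi = float(g0["gene_end"]) + flank_bp
        set1, set2, set3 = [], [], []
        for _, row in sub.iterrows():
            k = row["key"]
            if k not in maf.index:
                continue
            pos0 = int(k.split(":")[1]) - 1  # 0-based
            m = maf[k]
            coding = is_coding(row["consequence"])
            if coding and m < maf_coding:
                set1.append(k)
                set3.append(k)
            elif not coding and m < maf_noncoding and lo <= pos0 < hi:
                set2.append(k)
                cadd, fx = row["cadd_phred"], row["fathmm_xf"]
                functional = ((not pd.isna(cadd) and cadd > cadd_min)
                              or (not pd.isna(fx) and fx > fathmm_min))
                if functional:
                    set3.append(k)
        sets = {}
        for sid, keys in ((1, set1), (2, set2), (3, set3)):
            keys = list(dict.fromkeys(keys))
            if keys:
                sets[sid] = VariantSet(gene, sid, keys, maf[keys])
        if sets:
            out[gene] = sets
    return out


def sets_manifest(sets: dict[str, dict[int, VariantSet]],
                  annotation: pd.DataFrame) -> pd.DataFrame:
    """Flat per-(gene, set, variant) table for reporting."""
    lookup = annotation.set_index(["key", "gene"])
    rows = []
    for gene, by_id in sets.items():
        for sid, vs in by_id.items():
            for k in vs.keys:
                try:
                    a = lookup.loc[(k, gene)]
                    cons, cadd, fx = a["consequence"], a["cadd_phred"], a["fathmm_xf"]
                except KeyError:
                    cons, cadd, fx = np.nan, np.nan, np.nan
                rows.append((gene, sid, k, cons, vs.maf[k], cadd, fx))
    return pd.DataFrame(rows, columns=["gene", "set", "variant", "consequence",
                                       "maf", "cadd_phred", "fathmm_xf"])
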