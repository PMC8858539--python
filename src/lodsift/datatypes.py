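"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Variant keys are strings ``"chrom:pos:ref:alt"`` with 1-based VCF positions.
  Internal interval arithmetic (gene flanks, BED output) is 0-based half-open;
  conversions happen at the container boundary, nowhere else.
* Genotypes are stored as dosages of the ALT allele in {0, 1, 2}, ``nan`` for
  missing.
* Sex coding follows PED: 1 = male, 2 = female.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Invalid configuration (bad simulation spec, thresholds, modes)."""


class PedigreeError(ValueError):
    """Structurally invalid pedigree (cycles, missing/invalid parents)."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


SEX_MALE = 1
SEX_FEMALE = 2

PED_COLUMNS = ["fid", "iid", "father", "mother", "sex"]


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


@dataclass
class PedigreeSet:
    """Family structures: one row per individual.

    ``table`` columns: fid, iid, father, mother, sex.  Founders have empty
    string parents.  Individual ids are globally unique.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table.reset_index(drop=True).copy()
        for col in PED_COLUMNS:
            if col not in t.columns:
                raise PedigreeError(f"pedigree table missing column {col!r}")
        t["father"] = t["father"].fillna("").astype(str).replace("0", "")
        t["mother"] = t["mother"].fillna("").astype(str).replace("0", "")
        t["iid"] = t["iid"].astype(str)
        t["fid"] = t["fid"].astype(str)
        self.table = t[PED_COLUMNS]
        self._validate()

    def _validate(self) -> None:
        t = self.table
        if t["iid"].duplicated().any():
            dups = t.loc[t["iid"].duplicated(), "iid"].tolist()
            raise PedigreeError(f"duplicate individual ids: {dups}")
        sex = dict(zip(t["iid"], t["sex"]))
        fam = dict(zip(t["iid"], t["fid"]))
        for _, row in t.iterrows():
            for parent, want_sex in ((row["father"], SEX_MALE), (row["mother"], SEX_FEMALE)):
                if parent == "":
                    continue
                if parent not in sex:
                    raise PedigreeError(
                        f"{row['iid']}: parent {parent} not in pedigree"
                    )
                if fam[parent] != row["fid"]:
                    raise PedigreeError(
                        f"{row['iid']}: parent {parent} in different family"
                    )
                if int(sex[parent]) != want_sex:
                    raise PedigreeError(
                        f"{row['iid']}: parent {parent} has inconsistent sex"
                    )
        # single recorded parents are allowed (the other is an implicit,
        # unrelated, ungenotyped founder); see complete_parents()
        # acyclicity: every family must topologically sort
        for fid in self.family_ids:
            self.topological_order(fid)

    @property
    def individuals(self) -> list[str]:
        return self.table["iid"].tolist()

    @property
    def family_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["fid"]))

    def members(self, fid: str) -> pd.DataFrame:
        return self.table[self.table["fid"] == fid]

    def complete_parents(self) -> "PedigreeSet":
        """Return a pedigree where every single recorded parent is paired
        with a phantom unrelated founder (ids suffixed ``__ph``)."""
        t = self.table.copy()
        extra = []
        for i, row in t.iterrows():
            if (row["father"] == "") != (row["mother"] == ""):
                phantom = f"{row['iid']}__ph"
                extra.append((row["fid"], phantom, "", "",
                              SEX_MALE if row["father"] == "" else SEX_FEMALE))
                col = "father" if row["father"] == "" else "mother"
                t.loc[i, col] = phantom
        if not extra:
            return self
        add = pd.DataFrame(extra, columns=PED_COLUMNS)
        return PedigreeSet(pd.concat([t, add], ignore_index=True))

    def is_founder(self, iid: str) -> bool:
        row = self.table[self.table["iid"] == iid].iloc[0]
        return row["father"] == "" and row["mother"] == ""

    def founders(self, fid: str | None = None) -> list[str]:
        t = self.table if fid is None else self.members(fid)
        mask = (t["father"] == "") & (t["mother"] == "")
        return t.loc[mask, "iid"].tolist()

    def topological_order(self, fid: str) -> list[str]:
        """Members of a family ordered parents-before-offspring."""
        t = self.members(fid)
        parents = {r["iid"]: (r["father"], r["mother"]) for _, r in t.iterrows()}
        order: list[str] = []
        placed: set[str] = set()
        pending = list(parents)
        guard = 0
        while pending:
            guard += 1
            if guard > len(parents) ** 2 + 10:
                raise PedigreeError(f"family {fid}: pedigree graph has a cycle")
            iid = pending.pop(0)
            fa, mo = parents[iid]
            if all(p == "" or p in placed for p in (fa, mo)):
                order.append(iid)
                placed.add(iid)
            else:
                pending.append(iid)
        return order

    def trios(self):
        """Yield (child, father, mother) for every non-founder."""
        for _, row in self.table.iterrows():
            if row["father"] != "":
                yield row["iid"], row["father"], row["mother"]

    def to_ped(self, path) -> None:
        out = self.table.copy()
        out["father"] = out["father"].replace("", "0")
        out["mother"] = out["mother"].replace("", "0")
        out["phe"] = -9
        out.to_csv(path, sep="\t", header=False, index=False,
                   columns=["fid", "iid", "father", "mother", "sex", "phe"])

    @classmethod
    def from_ped(cls, path) -> "PedigreeSet":
        try:
            t = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        except Exception as exc:  # pragma: no cover - parser detail
            raise InputError(f"cannot parse PED file {path}: {exc}") from exc
        if t.shape[1] < 5:
            raise InputError(f"PED file {path}: expected >= 5 columns")
        t = t.iloc[:, :5]
        t.columns = PED_COLUMNS
        t["sex"] = t["sex"].astype(int)
        return cls(t)


@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata.

    ``variants`` is indexed by variant key with columns chrom, pos, ref, alt,
    filter and (optionally) r2.  ``dosage`` is ``(n_samples, n_variants)``
    float with values in {0, 1, 2, nan}.  ``depth`` is an optional
    same-shape integer array of per-genotype sequencing depths.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.samples = [str(s) for s in self.samples]
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise InputError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.depth is not None and self.depth.shape != self.dosage.shape:
            raise InputError("depth array shape differs from dosage shape")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise InputError("dosages must be in {0,1,2} or missing")
        if self.variants.index.duplicated().any():
            raise InputError("variant keys must be unique")

    @property
    def keys(self) -> list[str]:
        return self.variants.index.tolist()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_indices(self, samples) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:10]}")
        return np.array([pos[s] for s in samples], dtype=int)

    def subset(self, samples=None, variant_keys=None) -> "GenotypeMatrix":
        rows = slice(None) if samples is None else self.sample_indices(samples)
        if variant_keys is None:
            cols = slice(None)
            var = self.variants
        else:
            idx = {k: i for i, k in enumerate(self.variants.index)}
            missing = [k for k in variant_keys if k not in idx]
            if missing:
                raise KeyError(f"variants not in matrix: {missing[:10]}")
            cols = np.array([idx[k] for k in variant_keys], dtype=int)
            var = self.variants.iloc[cols]
        dosage = self.dosage[rows][:, cols]
        depth = None if self.depth is None else self.depth[rows][:, cols]
        out_samples = self.samples if samples is None else list(samples)
        return GenotypeMatrix(out_samples, var.copy(), dosage.copy(), depth)

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self, sample_idx=None) -> np.ndarray:
        af = self.alt_freq(sample_idx)
        return np.minimum(af, 1.0 - af)

    def mean_imputed(self, sample_idx=None) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean."""
        d = (self.dosage if sample_idx is None else self.dosage[sample_idx]).copy()
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(d, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        nan_rows, nan_cols = np.where(np.isnan(d))
        d[nan_rows, nan_cols] = mean[nan_cols]
        return d


def validate_genetic_map(gmap: pd.DataFrame) -> pd.DataFrame:
    """Check marker map: columns marker, chrom, bp, cM; cM monotone in bp."""
    for col in ("marker", "chrom", "bp", "cm"):
        if col not in gmap.columns:
            raise InputError(f"genetic map missing column {col!r}")
    for chrom, sub in gmap.groupby("chrom"):
        sub = sub.sort_values("bp")
        if not np.all(np.diff(sub["cm"].to_numpy()) >= -1e-12):
            raise InputError(f"genetic map: cM not monotone in bp on {chrom}")
    return gmap


def interpolate_bp(gmap: pd.DataFrame, chrom, cm_values) -> np.ndarray:
    """Map cM positions back to bp by linear interpolation within a chromosome."""
    sub = gmap[gmap["chrom"].astype(str) == str(chrom)].sort_values("cm")
    if len(sub) < 2:
        raise InputError(f"genetic map has < 2 markers on chromosome {chrom}")
    return np.interp(np.asarray(cm_values, dtype=float),
                     sub["cm"].to_numpy(dtype=float),
                     sub["bp"].to_numpy(dtype=float))
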