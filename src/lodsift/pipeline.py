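"""End-to-end orchestration: simulate -> linkage -> select -> group ->
transform -> test -> meta, with a manifest recording seeds, thresholds and
output hashes so identical configs reproduce identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import association, grouping, io_formats, linkage, meta, selection, transform
from .kinship import pedigree_kinship, sparsify_kinship
from .simulate import SimulationConfig, simulate_dataset, write_dataset

#: the four followed-up linkage regions, by cytogenetic band
REGION_PRESETS = {
    "1q31": ("chr1", 188_765_880, 202_026_147),
    "1q42": ("chr1", 232_963_435, 240_632_149),
    "19q13.11": ("chr19", 22_332_449, 36_438_656),
    "19q13.33": ("chr19", 41_978_814, 53_404_335),
}


@dataclass
class PipelineConfig:
    """All thresholds default to the analysis' published operating points."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    traits: tuple[str, ...] = ("sbp", "dbp")
    linkage_trait: str = "sbp"
    lod_min: float = 0.1
    lod_drop: float = 2.0
    grid_step_cm: float = 2.0
    prune_maf_min: float = 0.2
    prune_r2_max: float = 0.1
    maf_coding: float = 0.05
    maf_noncoding: float = 0.01
    cadd_min: float = 10.0
    fathmm_min: float = 0.5
    flank_bp: int = 10_000
    kinship_degree: int = 4
    selection_mode: str = "union"
    count_mode: str = "total"
    alpha: float = 0.05
    seed: int = 17

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sim"]["studies"] = [list(dataclasses.astuple(s)) for s in self.sim.studies]
        d["sim"]["medication_model"] = list(
            dataclasses.astuple(self.sim.medication_model))
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(d), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("sim", {})
        from .simulate import MedicationModel, StudySpec
        if "studies" in sim:
            sim["studies"] = tuple(
                StudySpec(s[0], s[1], float(s[2]), tuple(s[3]))
                for s in sim["studies"])
        if "medication_model" in sim:
            sim["medication_model"] = MedicationModel(*sim["medication_model"])
        for key in ("family_structure", "rare_maf_range", "covariate_effects"):
            if key in sim:
                sim[key] = tuple(tuple(x) if isinstance(x, list) else x
                                 for x in sim[key]) if key == "family_structure" \
                    else tuple(sim[key])
        for key in ("traits",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(sim=SimulationConfig(**sim), **d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir) -> dict:
    ds = simulate_dataset(config.sim)
    paths = write_dataset(ds, os.path.join(outdir, "data"))
    return paths


def _load(outdir):
    d = os.path.join(outdir, "data")
    return io_formats.load_dataset(
        os.path.join(d, "genotypes.vcf"), os.path.join(d, "families.ped"),
        os.path.join(d, "phenotypes.csv"), os.path.join(d, "genetic_map.tsv"),
        os.path.join(d, "annotation.tsv"))


def linkage_residuals(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Study-specific medication-adjusted residuals used for the LOD scan."""
    adj = transform.adjust_medication(pheno)
    col = {"sbp": "adj_sbp", "dbp": "adj_dbp", "pp": "pp"}[trait]
    out = {}
    for study, sub in adj.groupby("study"):
        X = np.column_stack([
            np.ones(len(sub)), sub["age"], sub["age"] ** 2,
            (sub["sex"] == 2).astype(float), sub["bmi"]])
        y = sub[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        res = y - X @ beta
        out.update(dict(zip(sub["iid"], res - res.mean())))
    return pd.Series(out, name=trait)


def stage_linkage(outdir, config: PipelineConfig) -> linkage.LodProfile:
    genotypes, ped, pheno, gmap, anno = _load(outdir)
    rare_keys = set(anno["key"])
    marker_keys = [k for k in genotypes.keys if k not in rare_keys]
    markers = genotypes.subset(variant_keys=marker_keys)
    kept = linkage.prune_markers(markers, ped, config.prune_maf_min,
                                 config.prune_r2_max)
    pruned = markers.subset(variant_keys=kept)
    pruned_map = gmap[gmap["bp"].isin(pruned.variants["pos"])].reset_index(drop=True)
    ibd = linkage.multipoint_ibd(pruned, ped, pruned_map,
                                 grid_step_cm=config.grid_step_cm)
    resid = linkage_residuals(pheno, config.linkage_trait)
    K = pedigree_kinship(ped)
    profile = linkage.vc_lod(resid, K, ibd)

    ldir = os.path.join(outdir, "linkage")
    os.makedirs(ldir, exist_ok=True)
    chrom = str(gmap["chrom"].iloc[0])
    bp = np.interp(profile.grid_cm, gmap["cm"], gmap["bp"])
    pd.DataFrame({"cm": profile.grid_cm, "bp": bp.astype(int),
                  "lod": profile.lod}).to_csv(
        os.path.join(ldir, "lod_profile.tsv"), sep="\t", index=False)
    profile.family_lods.rename_axis("family").reset_index().to_csv(
        os.path.join(ldir, "family_lods.tsv"), sep="\t", index=False)
    c, s, e, *_ = linkage.lod_drop_region(profile, gmap, chrom, config.lod_drop)
    with open(os.path.join(ldir, "region.bed"), "w") as fh:
        fh.write(f"{c}\t{s - 1}\t{e}\tlod_drop_region\t{profile.mlod:.4f}\n")
    return profile


def stage_select(outdir, config: PipelineConfig) -> selection.SelectionResult:
    genotypes, ped, pheno, gmap, anno = _load(outdir)
    fam_lods = pd.read_csv(os.path.join(outdir, "linkage", "family_lods.tsv"),
                           sep="\t").set_index("family")["lod_j"]
    rare = genotypes.subset(variant_keys=[k for k in genotypes.keys
                                          if k in set(anno["key"])])
    gene_of = anno.drop_duplicates("key").set_index("key")["gene"]
    result = selection.select_variants(
        rare, ped, fam_lods, gene_of, lod_min=config.lod_min,
        count_mode=config.count_mode, mode=config.selection_mode,
        seed=config.seed)
    sdir = os.path.join(outdir, "selection")
    os.makedirs(sdir, exist_ok=True)
    result.table.rename_axis("variant").reset_index().to_csv(
        os.path.join(sdir, "selection.tsv"), sep="\t", index=False)
    with open(os.path.join(sdir, "mixtures.json"), "w") as fh:
        json.dump({g: {"pi": m.pi, "mu1": m.mu1, "mu2": m.mu2,
                       "sigma1": m.sigma1, "sigma2": m.sigma2,
                       "converged": m.converged, "degenerate": m.degenerate}
                   for g, m in result.mixtures.items()}, fh, indent=2)
    return result


def stage_group(outdir, config: PipelineConfig):
    genotypes, ped, pheno, gmap, anno = _load(outdir)
    sel = pd.read_csv(os.path.join(outdir, "selection", "selection.tsv"), sep="\t")
    final_keys = sel.loc[sel["final"], "variant"].tolist()
    sets = grouping.build_variant_sets(
        final_keys, anno, genotypes, sample_ids=pheno["iid"].tolist(),
        flank_bp=config.flank_bp, maf_coding=config.maf_coding,
        maf_noncoding=config.maf_noncoding, cadd_min=config.cadd_min,
        fathmm_min=config.fathmm_min)
    gdir = os.path.join(outdir, "sets")
    os.makedirs(gdir, exist_ok=True)
    grouping.sets_manifest(sets, anno).to_csv(
        os.path.join(gdir, "variant_sets.tsv"), sep="\t", index=False)
    return sets


def stage_transform(outdir, config: PipelineConfig) -> pd.DataFrame:
    _, _, pheno, _, _ = _load(outdir)
    adj = transform.adjust_medication(pheno)
    frames = [transform.residualize_and_rint(adj, t) for t in config.traits]
    out = pd.concat(frames, ignore_index=True)
    tdir = os.path.join(outdir, "transform")
    os.makedirs(tdir, exist_ok=True)
    out.to_csv(os.path.join(tdir, "rint.csv"), index=False)
    return out


def _null_inputs(pheno: pd.DataFrame, rint: pd.DataFrame, trait: str):
    sub = rint[rint["trait"] == trait].set_index("iid")
    ids = [i for i in pheno["iid"] if i in sub.index]
    y = sub.loc[ids, "rint"]
    ph = pheno.set_index("iid").loc[ids]
    X = pd.DataFrame({
        "age": ph["age"], "age2": ph["age"] ** 2,
        "sex": (ph["sex"] == 2).astype(float), "bmi": ph["bmi"],
    }, index=ids)
    for c in ph.columns:
        if c.startswith("PC"):
            X[c] = ph[c]
    for center in sorted(ph["center"].unique())[1:]:
        X[f"center_{center}"] = (ph["center"] == center).astype(float)
    return y, X, ids


def stage_assoc(outdir, config: PipelineConfig) -> pd.DataFrame:
    genotypes, ped, pheno, gmap, anno = _load(outdir)
    rint = pd.read_csv(os.path.join(outdir, "transform", "rint.csv"),
                       dtype={"iid": str})
    sets = pd.read_csv(os.path.join(outdir, "sets", "variant_sets.tsv"), sep="\t")
    K4 = sparsify_kinship(pedigree_kinship(ped), config.kinship_degree)
    strata = [("ALL", None)] + [(s, s) for s in sorted(pheno["study"].unique())]
    rows = []
    for trait in config.traits:
        for label, study in strata:
            ph = pheno if study is None else pheno[pheno["study"] == study]
            y, X, ids = _null_inputs(ph, rint, trait)
            if len(ids) < 30:
                continue
            null = association.fit_null(y, X, K4.subset(ids))
            idx = genotypes.sample_indices(ids)
            for (gene, sid), sub in sets.groupby(["gene", "set"]):
                keys = sub["variant"].tolist()
                G = genotypes.subset(variant_keys=keys).dosage[idx]
                poly = np.nanstd(G, axis=0) > 0
                if not poly.any():
                    continue
                G = G[:, poly]
                try:
                    res = association.test_variant_set(
                        null, G, gene, trait, int(sid), stratum=label)
                except Exception as exc:
                    warnings.warn(f"{gene} set {sid} {trait} [{label}]: {exc}")
                    continue
                for r in res:
                    rows.append((label, trait, gene, int(sid), r.nvar, r.test,
                                 r.beta, r.se, r.q_stat, r.p))
    out = pd.DataFrame(rows, columns=["stratum", "trait", "gene", "set", "nvar",
                                      "test", "beta", "se", "q_stat", "p"])
    adir = os.path.join(outdir, "assoc")
    os.makedirs(adir, exist_ok=True)
    if len(out):
        io_formats.write_results(out, os.path.join(adir, "results.tsv"))
    else:
        warnings.warn("no testable variant sets; association stage is empty")
        out.to_csv(os.path.join(adir, "results.tsv"), sep="\t", index=False)
    return out


def stage_meta(outdir, config: PipelineConfig) -> pd.DataFrame:
    res = io_formats.read_results(os.path.join(outdir, "assoc", "results.tsv"))
    per_stratum = res[res["stratum"] != "ALL"]
    rows = []
    for (trait, gene, sid, test), sub in per_stratum.groupby(
            ["trait", "gene", "set", "test"]):
        ps = sub["p"].dropna()
        if len(ps) < 2:
            continue
        m = meta.fisher_combine(ps.tolist(), labels=sub["stratum"].tolist())
        rows.append((trait, gene, int(sid), test, m.df, m.statistic, m.combined_p))
    out = pd.DataFrame(rows, columns=["trait", "gene", "set", "test", "df",
                                      "x2", "p"])
    mdir = os.path.join(outdir, "meta")
    os.makedirs(mdir, exist_ok=True)
    if len(out):
        io_formats.write_results(out, os.path.join(mdir, "meta.tsv"))
    else:
        out.to_csv(os.path.join(mdir, "meta.tsv"), sep="\t", index=False)
    return out


STAGES = ("simulate", "linkage", "select", "group", "transform", "assoc", "meta")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages in order; returns the manifest dict."""
    os.makedirs(outdir, exist_ok=True)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    for stage in STAGES:
        fn = {"simulate": stage_simulate, "linkage": stage_linkage,
              "select": stage_select, "group": stage_group,
              "transform": stage_transform, "assoc": stage_assoc,
              "meta": stage_meta}[stage]
        try:
            fn(config, outdir) if stage == "simulate" else fn(outdir, config)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed: {exc}; earlier outputs kept in "
                f"{outdir}; fix the config or inputs and rerun") from exc
    manifest = {
        "stages": list(STAGES),
        "seed": config.seed,
        "thresholds": {
            "lod_min": config.lod_min, "lod_drop": config.lod_drop,
            "maf_coding": config.maf_coding, "maf_noncoding": config.maf_noncoding,
            "cadd_min": config.cadd_min, "fathmm_min": config.fathmm_min,
            "prune_maf_min": config.prune_maf_min, "prune_r2_max": config.prune_r2_max,
            "kinship_degree": config.kinship_degree, "alpha": config.alpha,
        },
        "selection_mode": config.selection_mode,
        "outputs": {},
    }
    for root, _, files in os.walk(outdir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            p = os.path.join(root, f)
            manifest["outputs"][os.path.relpath(p, outdir)] = _sha256(p)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
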