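"""Calibration, recovery and enrichment experiments on synthetic cohorts.

These are the package's own validation studies: type-I error of the
gene-based tests under the full null pipeline (family structure, medication
adjustment, R-INT, sparse kinship), null LOD calibration against the
half-chi-square reference, variance-component recovery, EM mixture
recovery, and enrichment of the two-step selection for planted causal
variants.  Problem sizes default to desk scale (hundreds of families,
thousands of replicates) so a full run takes minutes, not hours.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom, chi2

from . import association, selection, transform
from .datatypes import PedigreeSet
from .kinship import pedigree_kinship, sparsify_kinship
from .linkage import multipoint_ibd, vc_lod
from .simulate import (
    SimulationConfig,
    gene_drop,
    linkage_marker_map,
    plant_rare_variants,
    default_carrier_plan,
    simulate_pedigrees,
    simulate_phenotypes,
)


def _null_config(n_families: int, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_families=n_families,
        family_structure=((2, False, 0.4), (3, False, 0.4), (2, True, 0.2)),
        n_linkage_markers=20,
        qtl_variance_fraction=0.0,
        polygenic_h2=0.35,
        seed=seed,
    )


def gene_test_type_i_error(n_reps: int = 2000, n_families: int = 100,
                           seed: int = 1, alphas=(0.05, 0.01)) -> dict:
    """Burden/SKAT rejection rates on a fixed rare-variant set under the
    trait null, with phenotypes redrawn each replicate and the whole
    medication-adjust -> R-INT -> LMM pipeline rerun."""
    cfg = _null_config(n_families, seed)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    rng = np.random.default_rng(seed + 1)
    _, origins = gene_drop(ped, gmap, rng.uniform(0.25, 0.5, len(gmap)),
                           seed + 2, return_origins=True)
    plan = default_carrier_plan(ped, cfg, seed + 3)
    rare, anno = plant_rare_variants(ped, cfg, plan, seed + 4, origins=origins)
    K = pedigree_kinship(ped)
    K4 = sparsify_kinship(K, 4)
    # one gene's polymorphic variants form the tested set
    keys = anno.loc[anno["gene"] == "GENE1", "key"].tolist()
    sub = rare.subset(variant_keys=keys)
    poly = np.nanstd(sub.dosage, axis=0) > 0
    G_all = sub.dosage[:, poly]
    maf = sub.maf()[poly]

    ids = ped.individuals
    idx = sub.sample_indices(ids)
    burden_p = np.empty(n_reps)
    skat_p = np.empty(n_reps)
    for rep in range(n_reps):
        pheno = simulate_phenotypes(rare, ped, cfg, seed=seed + 10 + rep,
                                    kinship=K)
        adj = transform.adjust_medication(pheno)
        rint = transform.residualize_and_rint(adj, "sbp")
        y = pd.Series(rint["rint"].to_numpy(), index=pheno["iid"])[ids]
        ph = pheno.set_index("iid").loc[ids]
        X = pd.DataFrame({
            "age": ph["age"], "age2": ph["age"] ** 2,
            "sex": (ph["sex"] == 2).astype(float), "bmi": ph["bmi"],
            "PC1": ph["PC1"], "PC2": ph["PC2"],
        }, index=ids)
        null = association.fit_null(y, X, K4)
        G = G_all[idx]
        burden_p[rep] = association.burden_test(null, G, maf=maf).p
        skat_p[rep] = association.skat_test(null, G, maf=maf).p
    out = {"n_reps": n_reps, "n_samples": len(ids), "nvar": int(poly.sum())}
    for a in alphas:
        lo = binom.ppf(0.025, n_reps, a) / n_reps
        hi = binom.ppf(0.975, n_reps, a) / n_reps
        out[f"burden_rate_{a}"] = float((burden_p < a).mean())
        out[f"skat_rate_{a}"] = float((skat_p < a).mean())
        out[f"ci_{a}"] = (float(lo), float(hi))
    return out


def null_mlod_calibration(n_reps: int = 150, n_families: int = 100,
                          seed: int = 2, grid_step_cm: float = 10.0) -> dict:
    """Distribution of the maximum LOD over the grid when the trait is pure
    noise; the half-chi-square(1) reference gives P(LOD > 3) = 1e-4 at a
    single position."""
    cfg = _null_config(n_families, seed)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    rng = np.random.default_rng(seed + 1)
    gm = gene_drop(ped, gmap, rng.uniform(0.25, 0.5, len(gmap)), seed + 2)
    ibd = multipoint_ibd(gm, ped, gmap, grid_step_cm=grid_step_cm)
    K = pedigree_kinship(ped)
    grid = np.arange(0.0, cfg.map_length_cm + 1e-9, grid_step_cm)
    ids = ped.individuals
    mlods = np.empty(n_reps)
    for rep in range(n_reps):
        resid = pd.Series(rng.standard_normal(len(ids)), index=ids)
        prof = vc_lod(resid, K, ibd, grid_cm=grid)
        mlods[rep] = prof.mlod
    point_ref = 0.5 * chi2.sf(2 * math.log(10) * 3.0, 1)
    return {
        "n_reps": n_reps,
        "n_grid": len(grid),
        "median_mlod": float(np.median(mlods)),
        "rate_mlod_gt_3": float((mlods > 3.0).mean()),
        "pointwise_reference_rate": float(point_ref),
    }


def heritability_recovery(n_reps: int = 50, n_families: int = 300,
                          h2: float = 0.4, seed: int = 3) -> dict:
    """REML recovery of h2 from block-diagonal family kinship."""
    rows = []
    for f in range(n_families):
        fid = f"F{f:04d}"
        rows += [(fid, f"{fid}_a", "", "", 1), (fid, f"{fid}_b", "", "", 2),
                 (fid, f"{fid}_c", f"{fid}_a", f"{fid}_b", 1),
                 (fid, f"{fid}_d", f"{fid}_a", f"{fid}_b", 2)]
    ped = PedigreeSet(pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex"]))
    K = pedigree_kinship(ped)
    ids = ped.individuals
    A = 2.0 * K.dense(ids)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(ids)))
    rng = np.random.default_rng(seed)
    ests = np.empty(n_reps)
    X = pd.DataFrame(index=pd.Index(ids))
    for rep in range(n_reps):
        g = math.sqrt(h2) * (L @ rng.standard_normal(len(ids)))
        e = math.sqrt(1 - h2) * rng.standard_normal(len(ids))
        y = pd.Series(g + e, index=ids)
        ests[rep] = association.fit_null(y, X, K).heritability
    se_mean = float(ests.std(ddof=1) / math.sqrt(n_reps))
    return {"n_reps": n_reps, "n_samples": len(ids), "truth": h2,
            "mean_h2": float(ests.mean()), "se_mean": se_mean,
            "z": float((ests.mean() - h2) / se_mean)}


def mixture_recovery(n_reps: int = 100, n: int = 500, pi: float = 0.3,
                     mu=(0.0, 0.6), sd=(0.1, 0.1), seed: int = 4) -> dict:
    """EM recovery of a two-Normal mixture at the stated simulation design."""
    rng = np.random.default_rng(seed)
    est = np.empty((n_reps, 3))
    for rep in range(n_reps):
        comp = rng.random(n) < pi
        x = np.where(comp, rng.normal(mu[0], sd[0], n),
                     rng.normal(mu[1], sd[1], n))
        fit = selection.fit_two_normal_mixture(x, seed=seed + rep)
        est[rep] = (fit.pi, fit.mu1, fit.mu2)
    mean = est.mean(axis=0)
    se = est.std(axis=0, ddof=1) / math.sqrt(n_reps)
    truth = np.array([pi, mu[0], mu[1]])
    return {"n_reps": n_reps, "n": n,
            "mean_pi": float(mean[0]), "mean_mu1": float(mean[1]),
            "mean_mu2": float(mean[2]),
            "z_scores": [float(z) for z in (mean - truth) / se]}


def selection_enrichment(n_reps: int = 100, n_families: int = 100,
                         seed: int = 5) -> dict:
    """Are planted causal co-segregating variants enriched in the step-2 set?

    Each replicate simulates a cohort whose QTL is the causal rare variants,
    computes family LODs at the QTL position, runs the two-step selection,
    and compares the causal fraction of the step-2 set against the causal
    fraction among all candidate variants (the random-draw expectation).
    """
    base = SimulationConfig(
        n_families=n_families,
        # large sibships: each family carries real segregation information,
        # so carrier families earn higher LOD_j and higher causal MAC
        family_structure=((4, False, 0.5), (5, False, 0.5)),
        n_linkage_markers=20,
        qtl_variance_fraction=0.5,
        polygenic_h2=0.15,
        n_genes=2,
        rare_variant_count_per_gene=30,
        rare_maf_range=(0.005, 0.03),   # non-causal pool segregates too
        causal_variants_per_gene=3,
        carrier_family_fraction=0.3,
        seed=seed,
    )
    ped = simulate_pedigrees(base)
    gmap = linkage_marker_map(base)
    K = pedigree_kinship(ped)
    rng = np.random.default_rng(seed)
    ratios, r_causal, r_noncausal = [], [], []
    for rep in range(n_reps):
        s = seed + 1000 * rep
        gm, origins = gene_drop(ped, gmap, rng.uniform(0.25, 0.5, len(gmap)),
                                s + 1, return_origins=True)
        plan = default_carrier_plan(ped, base, s + 2)
        rare, anno = plant_rare_variants(ped, base, plan, s + 3, origins=origins)
        causal = set(anno.loc[anno["causal"], "key"])
        seg = [k for k in causal
               if np.nansum(rare.subset(variant_keys=[k]).dosage) > 0]
        pheno = simulate_phenotypes(rare, ped, base, s + 4, qtl_variants=seg,
                                    kinship=K)
        resid = pd.Series(
            (pheno["latent_sbp"] - pheno["latent_sbp"].mean()).to_numpy(),
            index=pheno["iid"])
        ibd = multipoint_ibd(gm, ped, gmap, grid_step_cm=base.map_length_cm)
        prof = vc_lod(resid, K, ibd,
                      grid_cm=np.array([base.qtl_position_cm]))
        gene_of = anno.drop_duplicates("key").set_index("key")["gene"]
        res = selection.select_variants(rare, ped, prof.family_lods, gene_of,
                                        seed=s)
        tab = res.table
        defined = tab[tab["r"].notna()]
        if len(defined):
            is_causal = defined.index.isin(causal)
            if is_causal.any() and (~is_causal).any():
                r_causal.append(defined["r"][is_causal].mean())
                r_noncausal.append(defined["r"][~is_causal].mean())
        step2 = tab.index[tab["step2"]]
        candidates = defined.index
        if len(step2) and len(candidates):
            frac_step2 = np.mean([k in causal for k in step2])
            frac_background = np.mean([k in causal for k in candidates])
            if frac_background > 0:
                ratios.append(frac_step2 / frac_background)
    return {
        "n_reps": n_reps,
        "n_with_step2": len(ratios),
        "mean_enrichment": float(np.mean(ratios)) if ratios else float("nan"),
        "mean_r_causal": float(np.mean(r_causal)),
        "mean_r_noncausal": float(np.mean(r_noncausal)),
    }


def skat_tail_vs_montecarlo(n_draws: int = 100_000, seed: int = 6,
                            quantiles=(0.95, 0.99)) -> dict:
    """Compare analytic mixture-of-chi-square quantiles against Monte-Carlo
    quadratic-form samples for a kernel from simulated rare variants."""
    cfg = _null_config(60, seed)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    rng = np.random.default_rng(seed + 1)
    _, origins = gene_drop(ped, gmap, rng.uniform(0.25, 0.5, len(gmap)),
                           seed + 2, return_origins=True)
    plan = default_carrier_plan(ped, cfg, seed + 3)
    rare, anno = plant_rare_variants(ped, cfg, plan, seed + 4, origins=origins)
    keys = anno.loc[anno["gene"] == "GENE1", "key"].tolist()
    sub = rare.subset(variant_keys=keys)
    poly = np.nanstd(sub.dosage, axis=0) > 0
    G = sub.mean_imputed()[:, poly]
    maf = sub.maf()[poly]
    w = association.beta_weights(maf)
    Gw = (G - G.mean(axis=0)) * w
    lam = np.linalg.eigvalsh(Gw.T @ Gw)
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > 1e-10 * lam.max()]
    draws = (rng.standard_normal((n_draws, len(lam))) ** 2) @ lam
    out = {"n_draws": n_draws, "n_eigenvalues": len(lam)}
    for q in quantiles:
        q_mc = float(np.quantile(draws, q))
        target = 1.0 - q

        def f(x):
            return association.imhof_pvalue(x, lam) - target

        q_an = brentq(f, lam.sum() * 0.1, lam.sum() + 40 * math.sqrt(
            2 * (lam ** 2).sum()))
        out[f"mc_q{int(q * 100)}"] = q_mc
        out[f"analytic_q{int(q * 100)}"] = float(q_an)
        out[f"rel_err_q{int(q * 100)}"] = float(abs(q_mc - q_an) / q_an)
    return out
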