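"""Two-step linkage-evidence-weighted rare-variant selection.

Step 1: restrict to informative families (two-member parent-offspring
families carry no linkage information and are dropped), keep families whose
peak-position LOD contribution exceeds 0.1, and keep variants segregating at
least twice in those families.  Step 2: for each variant compute the Pearson
correlation r_i between its per-family minor-allele counts MAC_ij and the
family LODs, fit a two-component Gaussian mixture to the r values within
each gene, and keep variants whose r_i exceeds the midpoint of the two
component means (the equal-variance Fisher-discriminant boundary).  The
final set per gene is, by default, the union of the two steps.

"Segregating at least twice" is read as total minor-allele count >= 2 summed
over members of the selected families; ``count_mode="families"`` switches to
the alternative reading (observed in at least two distinct families).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConfigError, GenotypeMatrix, PedigreeSet

__all__ = [
    "informative_families",
    "family_mac_table",
    "step1_select",
    "mac_lod_correlation",
    "MixtureFit",
    "fit_two_normal_mixture",
    "fda_select",
    "final_selection",
    "select_variants",
]


def informative_families(pedigrees: PedigreeSet, family_lods: pd.Series) -> list[str]:
    """Families with LODs computed, minus two-member parent-offspring pairs."""
    keep = []
    for fid in family_lods.index:
        mem = pedigrees.members(fid)
        if len(mem) == 2:
            a, b = mem.iloc[0], mem.iloc[1]
            if a["iid"] in (b["father"], b["mother"]) or \
               b["iid"] in (a["father"], a["mother"]):
                continue  # parent-offspring duo: uninformative
        keep.append(fid)
    return keep


def family_mac_table(genotypes: GenotypeMatrix, pedigrees: PedigreeSet,
                     families: list[str]) -> pd.DataFrame:
    """MAC_ij: per-variant minor-allele counts over genotyped members of each
    family.  The minor allele is decided per variant on the pooled sample."""
    af = genotypes.alt_freq()
    flip = af > 0.5
    out = {}
    for fid in families:
        ids = [i for i in pedigrees.members(fid)["iid"] if i in genotypes.samples]
        idx = genotypes.sample_indices(ids)
        d = genotypes.dosage[idx]
        alt_count = np.nansum(d, axis=0)
        n_obs = np.sum(~np.isnan(d), axis=0)
        mac = np.where(flip, 2 * n_obs - alt_count, alt_count)
        out[fid] = mac
    return pd.DataFrame(out, index=genotypes.keys)


def step1_select(family_lods: pd.Series, genotypes: GenotypeMatrix,
                 pedigrees: PedigreeSet, eligible: list[str],
                 lod_min: float = 0.1, min_count: int = 2,
                 count_mode: str = "total"):
    """Families with LOD_j > lod_min and variants segregating >= min_count.

    Returns ``(selected_families, mac_table, step1_keys)`` where ``mac_table``
    is restricted to the selected families.
    """
    if count_mode not in ("total", "families"):
        raise ConfigError(f"unknown count_mode {count_mode!r}")
    selected = [f for f in eligible if family_lods.get(f, -np.inf) > lod_min]
    if not selected:
        warnings.warn("no families exceed the LOD threshold; empty selection")
        return [], pd.DataFrame(index=genotypes.keys), []
    mac = family_mac_table(genotypes, pedigrees, selected)
    if count_mode == "total":
        hits = mac.sum(axis=1) >= min_count
    else:
        hits = (mac > 0).sum(axis=1) >= min_count
    return selected, mac, mac.index[hits].tolist()


def mac_lod_correlation(mac: pd.DataFrame, family_lods: pd.Series) -> pd.Series:
    """Pearson correlation of MAC_ij with LOD_j across the selected families.

    NaN where the MAC vector is constant (zero variance) or fewer than two
    families are available.
    """
    fams = mac.columns.tolist()
    if len(fams) < 2:
        warnings.warn("fewer than two selected families; correlations undefined")
        return pd.Series(np.nan, index=mac.index, name="r")
    lod = family_lods[fams].to_numpy(dtype=float)
    lod_c = lod - lod.mean()
    denom_l = math.sqrt((lod_c ** 2).sum())
    M = mac.to_numpy(dtype=float)
    Mc = M - M.mean(axis=1, keepdims=True)
    num = Mc @ lod_c
    denom_m = np.sqrt((Mc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (denom_m * denom_l)
    r[denom_m == 0] = np.nan
    if denom_l == 0:
        r[:] = np.nan
    return pd.Series(r, index=mac.index, name="r")


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture (EM)."""

    pi: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    degenerate: bool = False

    @property
    def boundary(self) -> float:
        """Equal-variance Fisher-discriminant threshold: the mean midpoint."""
        return 0.5 * (self.mu1 + self.mu2)


def _em_once(x, pi, mu, sd, max_iter, tol, var_floor):
    n = len(x)
    trace = []
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        log_d = np.empty((n, 2))
        for k in range(2):
            log_d[:, k] = (math.log(pi if k == 0 else 1 - pi)
                           - 0.5 * math.log(2 * math.pi) - math.log(sd[k])
                           - 0.5 * ((x - mu[k]) / sd[k]) ** 2)
        m = log_d.max(axis=1)
        lse = m + np.log(np.exp(log_d - m[:, None]).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(log_d - lse[:, None])
        nk = resp.sum(axis=0)
        pi = max(min(nk[0] / n, 1 - 1e-6), 1e-6)
        mu = resp.T @ x / nk
        var = np.maximum((resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk, var_floor)
        sd = np.sqrt(var)
        if ll - ll_old < tol and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
    return pi, mu, sd, trace, converged


def fit_two_normal_mixture(r_values, seed: int = 0, max_iter: int = 1000,
                           tol: float = 1e-8, n_restarts: int = 3,
                           var_floor: float = 1e-6) -> MixtureFit:
    """EM fit of a two-Normal mixture to the per-gene r_i values.

    Initialized from the 25th/75th percentiles; best of ``n_restarts`` seeded
    restarts (the extras jitter the initial means).  The log-likelihood trace
    is non-decreasing by construction of EM.  All-identical input yields a
    degenerate flag and no fit.
    """
    x = np.asarray([v for v in r_values if not np.isnan(v)], dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        return MixtureFit(0.5, float(x[0]) if x.size else np.nan,
                          float(x[0]) if x.size else np.nan,
                          0.0, 0.0, [], False, True)
    rng = np.random.default_rng(seed)
    q25, q75 = np.percentile(x, [25, 75])
    sd0 = max(x.std() / 2.0, math.sqrt(var_floor))
    best = None
    for rep in range(n_restarts):
        mu0 = np.array([q25, q75], dtype=float)
        if rep > 0:
            mu0 = mu0 + rng.normal(0, sd0, 2)
        pi, mu, sd, trace, conv = _em_once(
            x, 0.5, mu0.copy(), np.array([sd0, sd0]), max_iter, tol, var_floor)
        if best is None or trace[-1] > best[3][-1]:
            best = (pi, mu, sd, trace, conv)
    pi, mu, sd, trace, conv = best
    if mu[0] > mu[1]:
        mu, sd, pi = mu[::-1], sd[::-1], 1 - pi
    return MixtureFit(float(pi), float(mu[0]), float(mu[1]),
                      float(sd[0]), float(sd[1]), trace, conv, False)


def fda_select(r: pd.Series, fit: MixtureFit) -> list[str]:
    """Variants whose r_i strictly exceeds the component-mean midpoint."""
    if fit.degenerate:
        return []
    thr = fit.boundary
    return r.index[(r > thr).fillna(False)].tolist()


def final_selection(step1: list[str], step2: list[str],
                    mode: str = "union") -> list[str]:
    """Combine the two steps; modes: union (default), step2_filter,
    intersection."""
    s1, s2 = list(dict.fromkeys(step1)), list(dict.fromkeys(step2))
    if mode == "union":
        return s1 + [v for v in s2 if v not in set(s1)]
    if mode == "intersection":
        out = [v for v in s1 if v in set(s2)]
        if not out:
            warnings.warn("intersection of step-1 and step-2 sets is empty")
        return out
    if mode == "step2_filter":
        return s2 if s2 else s1
    raise ConfigError(f"unknown selection mode {mode!r}")


@dataclass
class SelectionResult:
    selected_families: list[str]
    mac: pd.DataFrame
    table: pd.DataFrame          # per variant: gene, r, step1, step2, final
    mixtures: dict[str, MixtureFit]
    mode: str


def select_variants(genotypes: GenotypeMatrix, pedigrees: PedigreeSet,
                    family_lods: pd.Series, gene_of: pd.Series,
                    lod_min: float = 0.1, min_count: int = 2,
                    count_mode: str = "total", mode: str = "union",
                    min_mixture_n: int = 10, seed: int = 0) -> SelectionResult:
    """Run the full two-step selection over all genes.

    ``gene_of`` maps variant key -> gene symbol.  Genes with fewer than
    ``min_mixture_n`` defined r values skip step 2 (step 1 carries them).
    """
    eligible = informative_families(pedigrees, family_lods)
    selected, mac, step1 = step1_select(
        family_lods, genotypes, pedigrees, eligible, lod_min, min_count, count_mode)
    r_all = (mac_lod_correlation(mac.loc[step1], family_lods)
             if step1 else pd.Series(dtype=float, name="r"))
    step2: list[str] = []
    mixtures: dict[str, MixtureFit] = {}
    for gene, keys in gene_of.groupby(gene_of).groups.items():
        keys = [k for k in keys if k in r_all.index]
        r_gene = r_all[keys].dropna()
        if len(r_gene) < min_mixture_n:
            continue
        fit = fit_two_normal_mixture(r_gene.to_numpy(), seed=seed)
        mixtures[gene] = fit
        if not fit.degenerate:
            step2.extend(fda_select(r_gene, fit))
    final = final_selection(step1, step2, mode)
    table = pd.DataFrame(index=genotypes.keys)
    table["gene"] = gene_of.reindex(table.index)
    table["r"] = r_all.reindex(table.index)
    table["step1"] = table.index.isin(step1)
    table["step2"] = table.index.isin(step2)
    table["final"] = table.index.isin(final)
    return SelectionResult(selected, mac, table, mixtures, mode)
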