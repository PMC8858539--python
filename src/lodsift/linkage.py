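"""Multipoint variance-component linkage analysis.

Pipeline: prune a common-marker panel (MAF > 0.2, pairwise r^2 < 0.1), run an
inheritance-vector HMM per family to obtain the posterior expected pairwise
IBD sharing ``Pi_j(t)`` on a cM grid (Lander-Green), then maximize the
variance-component likelihood

    V_j(t) = 2 * Phi_j * sigma2_a + Pi_j(t) * sigma2_q + I * sigma2_e

jointly over families (block-diagonal, ML on pre-adjusted, centered
residuals).  The null model fixes sigma2_q = 0.  The LOD profile is

    LOD(t) = [l_alt(t) - l_null] / ln 10,

floored at 0 for the total profile; the maximum over positions is the MLOD.
Family-specific LOD_j are each family's log10 likelihood-ratio contribution
evaluated at the *global* maximum-likelihood estimates, so they sum to the
(unfloored) total LOD at the peak.  The linkage region is the widest
contiguous interval around the peak within a two-LOD drop.

The HMM hidden state is the inheritance vector (two meiosis bits per
non-founder); between adjacent loci each bit flips independently with the
Haldane recombination fraction, and emissions sum founder-allele assignments
at population frequencies.  Exact Lander-Green is exponential in the number
of meioses, so families beyond the configured bit cap are skipped and
reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datatypes import GenotypeMatrix, InputError, PedigreeSet, interpolate_bp
from .kinship import KinshipMatrix
from .simulate import haldane_theta

LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# marker pruning


def prune_markers(genotypes: GenotypeMatrix, pedigrees: PedigreeSet,
                  maf_min: float = 0.2, r2_max: float = 0.1,
                  window_bp: int = 1_000_000) -> list[str]:
    """Greedy left-to-right LD pruning of the linkage panel.

    A marker is kept iff its founder-sample MAF exceeds ``maf_min`` and its
    squared Pearson dosage correlation with every previously kept marker
    within ``window_bp`` is below ``r2_max``.
    """
    var = genotypes.variants
    if not var["pos"].is_monotonic_increasing:
        raise InputError("markers must be sorted by position before pruning")
    founder_idx = genotypes.sample_indices(pedigrees.founders())
    maf = genotypes.maf(sample_idx=founder_idx)   # unbiased founder MAF
    D = genotypes.dosage                          # LD on the full sample
    kept: list[int] = []
    for j in range(genotypes.n_variants):
        if not maf[j] > maf_min:
            continue
        ok = True
        for k in reversed(kept):
            if var["pos"].iloc[j] - var["pos"].iloc[k] > window_bp:
                break
            x, y = D[:, k], D[:, j]
            m = ~np.isnan(x) & ~np.isnan(y)
            if m.sum() < 3 or x[m].std() == 0 or y[m].std() == 0:
                continue
            r = np.corrcoef(x[m], y[m])[0, 1]
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    if not kept:
        raise InputError(
            "no markers survive pruning; relax maf_min/r2_max or check input")
    return [var.index[j] for j in kept]


# ---------------------------------------------------------------------------
# inheritance-vector HMM


@dataclass
class IbdProfile:
    """Posterior expected pairwise IBD sharing per family on a cM grid.

    ``pi[fid]`` has shape (n_grid, n_members, n_members); values in [0, 1],
    diagonal 1, parent-offspring entries exactly 0.5.  ``members[fid]`` gives
    the row order.  Families skipped for exceeding the bit cap are listed in
    ``skipped``.
    """

    grid_cm: np.ndarray
    members: dict[str, list[str]]
    pi: dict[str, np.ndarray]
    skipped: list[str] = field(default_factory=list)
    mendelian_warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def family_ids(self) -> list[str]:
        return list(self.pi)


class _FamilyHmm:
    """Exact Lander-Green machinery for one family."""

    def __init__(self, ped: PedigreeSet, fid: str):
        ped = ped.complete_parents()
        self.fid = fid
        self.order = ped.topological_order(fid)
        tab = ped.members(fid).set_index("iid")
        self.founders = [i for i in self.order if tab.loc[i, "father"] == ""]
        self.nonfounders = [i for i in self.order if tab.loc[i, "father"] != ""]
        self.n_bits = 2 * len(self.nonfounders)
        self.merlin_bits = self.n_bits - len(self.founders)
        S = 1 << self.n_bits
        nf = len(self.founders)
        n = len(self.order)
        slot = {f: (2 * k, 2 * k + 1) for k, f in enumerate(self.founders)}
        # per-state founder-slot origin of each individual's two haplotypes
        orig = np.zeros((S, n, 2), dtype=np.int16)
        states = np.arange(S)
        loc = {iid: i for i, iid in enumerate(self.order)}
        for i, iid in enumerate(self.order):
            if iid in slot:
                orig[:, i, 0] = slot[iid][0]
                orig[:, i, 1] = slot[iid][1]
        for m, iid in enumerate(self.nonfounders):
            i = loc[iid]
            fa, mo = tab.loc[iid, "father"], tab.loc[iid, "mother"]
            b_pat = (states >> (2 * m)) & 1
            b_mat = (states >> (2 * m + 1)) & 1
            orig[:, i, 0] = orig[states, loc[fa], b_pat]
            orig[:, i, 1] = orig[states, loc[mo], b_mat]
        self.orig = orig
        # pairwise allele sharing per state: (matches among the 4 slot pairs)/2
        eq = (orig[:, :, None, :, None] == orig[:, None, :, None, :])
        self.share = eq.sum(axis=(-1, -2)) / 2.0  # (S, n, n)
        # founder allele assignments (alt-allele indicators per slot)
        C = 1 << (2 * nf)
        assign = ((np.arange(C)[:, None] >> np.arange(2 * nf)) & 1).astype(np.int8)
        self.assign = assign
        self.n_alt = assign.sum(axis=1)
        # genotype implied per (assignment, state, individual)
        self.geno = (assign[:, orig[:, :, 0]] + assign[:, orig[:, :, 1]])  # (C, S, n)

    def emissions(self, obs: np.ndarray, freqs: np.ndarray):
        """P(observed genotypes | state) per marker; returns (M, S) array and
        a list of marker indices with zero likelihood (Mendelian conflict)."""
        M = obs.shape[1]
        S = self.orig.shape[0]
        nf2 = self.assign.shape[1]
        out = np.empty((M, S))
        bad = []
        for t in range(M):
            o = obs[:, t]
            seen = ~np.isnan(o)
            if not seen.any():
                out[t] = 1.0
                continue
            consistent = (self.geno[:, :, seen] == o[seen]).all(axis=2)  # (C, S)
            p = freqs[t]
            w = p ** self.n_alt * (1.0 - p) ** (nf2 - self.n_alt)
            e = w @ consistent
            if e.max() <= 0.0:
                bad.append(t)
                e = np.ones(S)
            out[t] = e
        return out, bad


def _propagate(v: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """Apply the bit-flip transition kernel (each bit flips w.p. theta)."""
    if n_bits == 0 or theta <= 0.0:
        return v
    w = v.reshape([2] * n_bits)
    for axis in range(n_bits):
        w = (1.0 - theta) * w + theta * np.flip(w, axis=axis)
    return w.reshape(-1)


def multipoint_ibd(genotypes: GenotypeMatrix, pedigrees: PedigreeSet,
                   gmap: pd.DataFrame, allele_freqs=None,
                   grid_step_cm: float = 1.0, bit_cap: int = 16) -> IbdProfile:
    """Forward-backward posterior IBD sharing on marker + uniform grid.

    ``genotypes`` should be restricted to the pruned linkage markers, with
    columns matching ``gmap`` rows (by variant order).  ``allele_freqs``
    defaults to founder-sample ALT frequencies.  Families whose MERLIN-style
    bit size ``2n - f`` exceeds ``bit_cap`` are skipped with a warning.
    Markers incompatible with Mendelian transmission in a family are treated
    as missing for that family and reported.
    """
    if len(gmap) != genotypes.n_variants:
        raise InputError("gmap rows must match genotype variants")
    cm = gmap["cm"].to_numpy(dtype=float)
    if np.any(np.diff(cm) < 0):
        raise InputError("genetic map must be sorted by cM position")
    if allele_freqs is None:
        fidx = genotypes.sample_indices(pedigrees.founders())
        allele_freqs = genotypes.alt_freq(sample_idx=fidx)
    freqs = np.clip(np.asarray(allele_freqs, dtype=float), 1e-4, 1 - 1e-4)

    grid = np.unique(np.concatenate([
        cm, np.arange(cm[0], cm[-1] + 1e-9, grid_step_cm)]))
    members: dict[str, list[str]] = {}
    pis: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    mendel: list[tuple[str, str]] = []
    sample_pos = {s: i for i, s in enumerate(genotypes.samples)}

    for fid in pedigrees.family_ids:
        hmm = _FamilyHmm(pedigrees, fid)
        if hmm.merlin_bits > bit_cap or hmm.n_bits > 22:
            warnings.warn(f"family {fid} exceeds bit cap; skipped")
            skipped.append(fid)
            continue
        idx = [sample_pos.get(i) for i in hmm.order]
        obs = np.full((len(hmm.order), genotypes.n_variants), np.nan)
        for r, i in enumerate(idx):
            if i is not None:
                obs[r] = genotypes.dosage[i]
        emis, bad = hmm.emissions(obs, freqs)
        for t in bad:
            mendel.append((fid, genotypes.variants.index[t]))
            warnings.warn(f"family {fid}: Mendelian conflict at marker "
                          f"{genotypes.variants.index[t]}; treated as missing")
        S = emis.shape[1]
        M = emis.shape[0]
        nb = hmm.n_bits
        theta = haldane_theta(np.diff(cm))
        # scaled forward/backward
        alpha = np.empty((M, S))
        v = np.full(S, 1.0 / S) * emis[0]
        alpha[0] = v / v.sum()
        for t in range(1, M):
            v = _propagate(alpha[t - 1], float(theta[t - 1]), nb) * emis[t]
            alpha[t] = v / v.sum()
        beta = np.empty((M, S))
        beta[M - 1] = emis[M - 1]
        beta[M - 1] /= beta[M - 1].sum()
        for t in range(M - 2, -1, -1):
            v = _propagate(beta[t + 1], float(theta[t]), nb) * emis[t]
            beta[t] = v / v.sum()
        n = len(hmm.order)
        pi = np.empty((len(grid), n, n))
        flat_share = hmm.share.reshape(S, n * n)
        for gi, t_cm in enumerate(grid):
            k = int(np.searchsorted(cm, t_cm, side="right")) - 1
            k = min(max(k, 0), M - 1)
            if abs(t_cm - cm[k]) < 1e-12:
                post = alpha[k] * _propagate_div_emis(beta, emis, k)
            else:
                dl = t_cm - cm[k]
                dr = cm[k + 1] - t_cm
                left = _propagate(alpha[k], float(haldane_theta(dl)), nb)
                right = _propagate(beta[k + 1], float(haldane_theta(dr)), nb)
                post = left * right
            post = post / post.sum()
            pi[gi] = (post @ flat_share).reshape(n, n)
        members[fid] = hmm.order
        pis[fid] = pi
    return IbdProfile(grid, members, pis, skipped, mendel)


def _propagate_div_emis(beta, emis, k):
    """Backward message at marker k excluding marker k's own emission."""
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(emis[k] > 0, beta[k] / emis[k], 0.0)
    s = b.sum()
    return b / s if s > 0 else np.full_like(b, 1.0 / b.size)


# ---------------------------------------------------------------------------
# variance-component LOD


@dataclass
class VcFit:
    sigma2_a: float
    sigma2_q: float
    sigma2_e: float
    loglik: float
    converged: bool = True


@dataclass
class LodProfile:
    grid_cm: np.ndarray
    lod: np.ndarray            # floored at 0
    raw_lod: np.ndarray        # unfloored log10 likelihood ratio
    peak_cm: float
    mlod: float
    family_lods: pd.Series
    null_fit: VcFit
    peak_fit: VcFit

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.raw_lod))


class _VcData:
    """Per-family residual vectors, 2*Phi blocks, and Pi stacks, grouped by
    family size so likelihoods evaluate with batched factorizations."""

    def __init__(self, residuals: pd.Series, kinship: KinshipMatrix,
                 ibd: IbdProfile):
        per_size: dict[int, list] = {}
        self.grid = ibd.grid_cm
        for fid in ibd.family_ids:
            ids = [i for i in ibd.members[fid] if i in residuals.index
                   and not np.isnan(residuals[i])]
            if len(ids) < 2:
                continue
            sel = [ibd.members[fid].index(i) for i in ids]
            per_size.setdefault(len(ids), []).append((
                fid,
                residuals[ids].to_numpy(dtype=float),
                2.0 * kinship.dense(ids),
                ibd.pi[fid][:, sel][:, :, sel],
            ))
        if not per_size:
            raise InputError("no families with >= 2 phenotyped members")
        self.groups = []
        self.fids: list[str] = []
        for k in sorted(per_size):
            items = per_size[k]
            self.fids.extend(f for f, *_ in items)
            self.groups.append((
                k,
                np.stack([y for _, y, _, _ in items]),          # (m, k)
                np.stack([p for _, _, p, _ in items]),          # (m, k, k)
                np.stack([q for _, _, _, q in items], axis=1),  # (n_grid, m, k, k)
            ))
        self.n = sum(g[0] * g[1].shape[0] for g in self.groups)
        self.scale = float(np.var(np.concatenate(
            [g[1].reshape(-1) for g in self.groups]))) or 1.0

    def standardize(self) -> None:
        std = math.sqrt(self.scale)
        self.groups = [(k, Y / std, P, Q) for k, Y, P, Q in self.groups]

    def family_loglik(self, sa, sq, se, grid_index) -> np.ndarray:
        """Gaussian log-likelihood contribution per family (order self.fids)."""
        parts = []
        for k, Y, PHI2, PI in self.groups:
            V = sa * PHI2 + se * np.eye(k)[None]
            if sq > 0 and grid_index is not None:
                V = V + sq * PI[grid_index]
            sign, logdet = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return np.full(len(self.fids), -np.inf)
            try:
                sol = np.linalg.solve(V, Y[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                return np.full(len(self.fids), -np.inf)
            quad = np.einsum("mk,mk->m", Y, sol)
            parts.append(-0.5 * (k * math.log(2 * math.pi) + logdet + quad))
        return np.concatenate(parts)

    def loglik(self, sa, sq, se, grid_index) -> float:
        return float(self.family_loglik(sa, sq, se, grid_index).sum())


def _maximize(data: _VcData, with_qtl: bool, grid_index,
              starts: list[np.ndarray], tol: float = 1e-8):
    """Bounded quasi-Newton on log-variances, best of the given starts."""
    def neg(x):
        if with_qtl:
            sa, sq, se = np.exp(x)
        else:
            sa, se = np.exp(x)
            sq = 0.0
        ll = data.loglik(sa, sq, se, grid_index)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    bounds = [(-20.0, 6.0)] * (3 if with_qtl else 2)
    for x0 in starts:
        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "gtol": 1e-10, "maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    if with_qtl:
        sa, sq, se = np.exp(x)
    else:
        (sa, se), sq = np.exp(x), 0.0
    return VcFit(sa * data.scale, sq * data.scale, se * data.scale,
                 -best.fun, bool(best.success))


def vc_lod(residuals: pd.Series, kinship: KinshipMatrix, ibd: IbdProfile,
           grid_cm=None) -> LodProfile:
    """Total and family-specific variance-component LOD profile.

    ``residuals`` are centered, pre-adjusted trait residuals indexed by
    individual id; individuals absent from the IBD profile (ungenotyped or in
    skipped families) are ignored.  Variances are estimated by ML on the
    standardized scale and reported in trait units squared.
    """
    data = _VcData(residuals, kinship, ibd)
    data.standardize()

    null_starts = [np.log([0.4, 0.6]), np.log([0.15, 0.85]), np.log([0.7, 0.3])]
    null = _maximize(data, False, None, null_starts)
    na, ne = null.sigma2_a / data.scale, null.sigma2_e / data.scale

    grid = data.grid if grid_cm is None else np.asarray(grid_cm, dtype=float)
    grid_idx = [int(np.argmin(np.abs(data.grid - g))) for g in grid]
    raw = np.empty(len(grid))
    fits = []
    eps = 1e-9
    alt_starts = [
        np.log([max(na, eps), eps, max(ne, eps)]),       # null solution, sq ~ 0
        np.log([max(na / 2, eps), max(na / 2, eps), max(ne, eps)]),
        np.log([max(na, eps), 0.3, max(ne * 0.7, eps)]),
    ]
    for j, gi in enumerate(grid_idx):
        alt = _maximize(data, True, gi, alt_starts)
        raw[j] = (alt.loglik - null.loglik) / LN10
        fits.append(alt)
    lod = np.maximum(raw, 0.0)
    peak = int(np.argmax(raw))
    alt_peak = fits[peak]
    fam_alt = data.family_loglik(alt_peak.sigma2_a / data.scale,
                                 alt_peak.sigma2_q / data.scale,
                                 alt_peak.sigma2_e / data.scale, grid_idx[peak])
    fam_null = data.family_loglik(null.sigma2_a / data.scale, 0.0,
                                  null.sigma2_e / data.scale, None)
    fam = pd.Series((fam_alt - fam_null) / LN10, index=data.fids, name="lod_j")
    return LodProfile(grid, lod, raw, float(grid[peak]), float(lod[peak]),
                      fam, null, alt_peak)


def family_lods(profile: LodProfile) -> pd.Series:
    """Per-family log10 likelihood-ratio contributions at the peak (sum to
    the unfloored total LOD there)."""
    return profile.family_lods


def lod_drop_region(profile: LodProfile, gmap: pd.DataFrame, chrom,
                    drop: float = 2.0):
    """Widest contiguous interval around the peak with LOD >= MLOD - drop.

    Returns ``(chrom, start_bp, end_bp, start_cm, end_cm)`` with bp endpoints
    interpolated from the genetic map.
    """
    lod = profile.lod
    if np.all(np.isnan(lod)):
        raise InputError("LOD profile is all-NaN")
    thr = profile.mlod - drop
    peak = profile.peak_index
    lo = peak
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    start_cm, end_cm = float(profile.grid_cm[lo]), float(profile.grid_cm[hi])
    start_bp, end_bp = interpolate_bp(gmap, chrom, [start_cm, end_cm])
    return str(chrom), int(round(start_bp)), int(round(end_bp)), start_cm, end_cm
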