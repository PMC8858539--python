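"""Linkage: pruning, multipoint IBD (with an exhaustive enumeration oracle),
variance-component LOD profiles and the two-LOD-drop region."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lodsift.datatypes import GenotypeMatrix, InputError, PedigreeSet
from lodsift.kinship import pedigree_kinship
from lodsift.linkage import (
    LodProfile,
    VcFit,
    lod_drop_region,
    multipoint_ibd,
    prune_markers,
    vc_lod,
)
from lodsift.simulate import (
    SimulationConfig,
    gene_drop,
    haldane_theta,
    linkage_marker_map,
    simulate_pedigrees,
    simulate_phenotypes,
)


def _geno(samples, dosage, positions, cm):
    var = pd.DataFrame({"chrom": "1", "pos": positions, "ref": "A",
                        "alt": "G", "filter": "PASS"})
    var.index = [f"1:{p}:A:G" for p in positions]
    gmap = pd.DataFrame({"marker": var.index, "chrom": "1",
                         "bp": positions, "cm": cm})
    return GenotypeMatrix(samples, var, np.asarray(dosage, float)), gmap


# ---------------------------------------------------------------------------
# pruning


def test_prune_drops_duplicate_marker(nuclear_family):
    g = np.array([[0.0], [2.0], [1.0], [1.0]])
    gm, _ = _geno(nuclear_family.individuals, np.hstack([g, g, g]),
                  [100, 200, 300], [0.0, 0.1, 0.2])
    kept = prune_markers(gm, nuclear_family, maf_min=0.0)
    assert kept == ["1:100:A:G"]


def test_prune_drops_low_maf_marker():
    cfg = SimulationConfig(n_families=200, family_structure=((1, False, 1.0),),
                           n_linkage_markers=2, seed=1)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    gm = gene_drop(ped, gmap, np.array([0.15, 0.4]), seed=2)
    kept = prune_markers(gm, ped)
    assert kept == [gm.keys[1]]    # founder MAF ~0.15 < 0.2 dropped


def test_independent_markers_all_survive():
    cfg = SimulationConfig(n_families=300, family_structure=((1, False, 1.0),),
                           n_linkage_markers=10, seed=3)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    gm = gene_drop(ped, gmap, np.full(10, 0.3), seed=4)
    kept = prune_markers(gm, ped)
    assert len(kept) == 10


def test_prune_error_when_nothing_survives(nuclear_family):
    gm, _ = _geno(nuclear_family.individuals, np.zeros((4, 2)),
                  [100, 200], [0.0, 1.0])
    with pytest.raises(InputError):
        prune_markers(gm, nuclear_family)


# ---------------------------------------------------------------------------
# multipoint IBD: invariants and brute-force oracle


def test_parent_offspring_sharing_is_half_everywhere():
    ped = PedigreeSet(pd.DataFrame({
        "fid": ["A"] * 3, "iid": ["fa", "mo", "c1"],
        "father": ["", "", "fa"], "mother": ["", "", "mo"], "sex": [1, 2, 1]}))
    rng = np.random.default_rng(5)
    fa = rng.binomial(2, 0.4, 5).astype(float)
    mo = rng.binomial(2, 0.4, 5).astype(float)
    child = fa // 2 + mo // 2   # always Mendelian-achievable
    gm, gmap = _geno(["fa", "mo", "c1"], np.vstack([fa, mo, child]),
                     [100, 200, 300, 400, 500], np.arange(5) * 10.0)
    ibd = multipoint_ibd(gm, ped, gmap)
    i, j = ibd.members["A"].index("fa"), ibd.members["A"].index("c1")
    assert np.allclose(ibd.pi["A"][:, i, j], 0.5, atol=1e-12)
    assert np.allclose(np.diagonal(ibd.pi["A"], axis1=1, axis2=2), 1.0)
    # symmetry
    assert np.allclose(ibd.pi["A"], np.transpose(ibd.pi["A"], (0, 2, 1)))


def test_duplicate_sibs_share_both_haplotypes_at_informative_markers(nuclear_family):
    # identical sib genotypes at fully informative markers (all four founder
    # alleles distinguishable through het/hom patterns) force Pi -> 1
    fa = [1.0, 1.0, 1.0]
    mo = [1.0, 1.0, 1.0]
    c = [2.0, 0.0, 2.0]
    gm, gmap = _geno(nuclear_family.individuals, np.vstack([fa, mo, c, c]),
                     [100, 200, 300], [0.0, 0.5, 1.0])
    ibd = multipoint_ibd(gm, nuclear_family, gmap, allele_freqs=np.full(3, 0.5),
                         grid_step_cm=0.5)
    mem = ibd.members["A"]
    i, j = mem.index("c1"), mem.index("c2")
    at_markers = ibd.pi["A"][[0, 1, 2], i, j]
    assert np.all(at_markers > 0.99)


def _enumerate_sib_pair_pi(obs, freqs, cm):
    """Independent oracle: exhaustive sum over founder-allele assignments and
    per-locus inheritance vectors chained by the bit-flip transition matrix.

    obs: (4, M) dosages ordered (fa, mo, c1, c2); returns Pi(c1,c2) at markers.
    """
    M = obs.shape[1]
    states = list(itertools.product([0, 1], repeat=4))  # c1 pat/mat, c2 pat/mat
    assigns = list(itertools.product([0, 1], repeat=4))  # fa0 fa1 mo0 mo1

    def emit(state, t):
        b1p, b1m, b2p, b2m = state
        p = freqs[t]
        tot = 0.0
        for a in assigns:
            w = 1.0
            for al in a:
                w *= p if al else (1 - p)
            g = [a[0] + a[1], a[2] + a[3],
                 a[b1p] + a[2 + b1m], a[b2p] + a[2 + b2m]]
            if all(np.isnan(obs[k, t]) or g[k] == obs[k, t] for k in range(4)):
                tot += w
        return tot

    def share(state):
        b1p, b1m, b2p, b2m = state
        return ((b1p == b2p) + (b1m == b2m)) / 2.0

    thetas = [haldane_theta(cm[t + 1] - cm[t]) for t in range(M - 1)]

    def trans(s, t, th):
        p = 1.0
        for x, y in zip(s, t):
            p *= th if x != y else (1 - th)
        return p

    pis = []
    for target in range(M):
        num = 0.0
        den = 0.0
        for path in itertools.product(range(len(states)), repeat=M):
            w = (1 / 16)
            for t in range(M - 1):
                w *= trans(states[path[t]], states[path[t + 1]], thetas[t])
            for t in range(M):
                w *= emit(states[path[t]], t)
            den += w
            num += w * share(states[path[target]])
        pis.append(num / den)
    return np.array(pis)


def test_hmm_posterior_matches_exhaustive_enumeration(nuclear_family):
    rng = np.random.default_rng(7)
    freqs = np.array([0.3, 0.5, 0.4])
    cm = np.array([0.0, 8.0, 20.0])
    # arbitrary (Mendelian-consistent) genotypes incl. a missing entry
    obs = np.array([[1, 1, 2],
                    [1, 0, 1],
                    [2, 1, 2],
                    [1, np.nan, 1]], dtype=float)
    gm, gmap = _geno(nuclear_family.individuals, obs, [1, 2, 3], cm)
    ibd = multipoint_ibd(gm, nuclear_family, gmap, allele_freqs=freqs,
                         grid_step_cm=100.0)
    mem = ibd.members["A"]
    i, j = mem.index("c1"), mem.index("c2")
    marker_rows = [int(np.argmin(np.abs(ibd.grid_cm - c))) for c in cm]
    got = ibd.pi["A"][marker_rows, i, j]
    want = _enumerate_sib_pair_pi(obs, freqs, cm)
    assert np.max(np.abs(got - want)) < 1e-10


def test_mean_sharing_over_gene_drops_matches_pair_expectations():
    cfg = SimulationConfig(n_families=60, family_structure=((2, False, 1.0),),
                           n_linkage_markers=20, seed=8)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    sib_means = []
    for seed in range(4):
        gm = gene_drop(ped, gmap, np.full(20, 0.4), seed=seed)
        ibd = multipoint_ibd(gm, ped, gmap, grid_step_cm=25.0)
        for fid in ibd.family_ids:
            mem = ibd.members[fid]
            kids = [m for m in mem if not ped.is_founder(m)]
            i, j = mem.index(kids[0]), mem.index(kids[1])
            sib_means.append(ibd.pi[fid][:, i, j].mean())
    assert np.mean(sib_means) == pytest.approx(0.5, abs=0.02)


def test_mendelian_conflict_marker_zeroed_with_warning(nuclear_family):
    obs = np.array([[0, 0], [0, 0], [2, 0], [0, 0]], dtype=float)  # c1 impossible
    gm, gmap = _geno(nuclear_family.individuals, obs, [1, 2], [0.0, 10.0])
    with pytest.warns(UserWarning, match="Mendelian"):
        ibd = multipoint_ibd(gm, nuclear_family, gmap)
    assert ibd.mendelian_warnings


def test_oversized_family_skipped():
    rows = [("A", "fa", "", "", 1), ("A", "mo", "", "", 2)]
    rows += [("A", f"c{k}", "fa", "mo", 1) for k in range(10)]  # 2n-f = 18
    ped = PedigreeSet(pd.DataFrame(rows, columns=["fid", "iid", "father",
                                                  "mother", "sex"]))
    gm, gmap = _geno(ped.individuals, np.ones((12, 2)), [1, 2], [0.0, 1.0])
    with pytest.warns(UserWarning, match="bit cap"):
        ibd = multipoint_ibd(gm, ped, gmap)
    assert ibd.skipped == ["A"]


# ---------------------------------------------------------------------------
# variance-component LOD


@pytest.fixture(scope="module")
def sibship_scan():
    """Shared planted-QTL scan used by the power checks."""
    cfg = SimulationConfig(n_families=150, family_structure=((4, False, 1.0),),
                           n_linkage_markers=30, qtl_variance_fraction=0.35,
                           polygenic_h2=0.25, seed=2)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    gm = gene_drop(ped, gmap, np.full(30, 0.35), seed=52)
    qtl_key = gm.keys[15]     # ~50 cM
    ibd = multipoint_ibd(gm, ped, gmap, grid_step_cm=10.0)
    K = pedigree_kinship(ped)
    return cfg, ped, gm, gmap, qtl_key, ibd, K


def test_lod_profile_nonnegative_and_family_lods_sum(sibship_scan):
    cfg, ped, gm, gmap, qtl_key, ibd, K = sibship_scan
    pheno = simulate_phenotypes(gm, ped, cfg, seed=102, qtl_variants=[qtl_key])
    resid = pd.Series((pheno["latent_sbp"] - pheno["latent_sbp"].mean()).to_numpy(),
                      index=pheno["iid"])
    prof = vc_lod(resid, K, ibd, grid_cm=np.arange(0.0, 101.0, 10.0))
    assert np.all(prof.lod >= 0.0)
    assert prof.mlod == prof.lod[prof.peak_index]
    # additivity of per-family log-likelihood contributions at the peak
    assert prof.family_lods.sum() == pytest.approx(
        prof.raw_lod[prof.peak_index], abs=1e-8)


def test_lod_power_at_qtl_exceeds_distant_position(sibship_scan):
    cfg, ped, gm, gmap, qtl_key, ibd, K = sibship_scan
    at_qtl, away = [], []
    for seed in range(6):
        pheno = simulate_phenotypes(gm, ped, cfg, seed=200 + seed,
                                    qtl_variants=[qtl_key])
        resid = pd.Series(
            (pheno["latent_sbp"] - pheno["latent_sbp"].mean()).to_numpy(),
            index=pheno["iid"])
        prof = vc_lod(resid, K, ibd, grid_cm=np.array([0.0, 50.0]))
        away.append(prof.raw_lod[0])
        at_qtl.append(prof.raw_lod[1])
    assert np.mean(at_qtl) > np.mean(away)


def test_pure_noise_gives_small_nonnegative_lod(sibship_scan):
    cfg, ped, gm, gmap, qtl_key, ibd, K = sibship_scan
    rng = np.random.default_rng(11)
    ids = ped.individuals
    resid = pd.Series(rng.standard_normal(len(ids)), index=ids)
    prof = vc_lod(resid, K, ibd, grid_cm=np.array([0.0, 50.0, 100.0]))
    assert np.all(prof.lod >= 0.0)
    assert prof.mlod < 2.0


def test_single_family_lod_equals_total():
    cfg = SimulationConfig(n_families=1, family_structure=((4, False, 1.0),),
                           n_linkage_markers=10, seed=3)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    gm = gene_drop(ped, gmap, np.full(10, 0.4), seed=4)
    ibd = multipoint_ibd(gm, ped, gmap, grid_step_cm=50.0)
    K = pedigree_kinship(ped)
    rng = np.random.default_rng(5)
    resid = pd.Series(rng.standard_normal(6), index=ped.individuals)
    prof = vc_lod(resid, K, ibd, grid_cm=np.array([50.0]))
    assert len(prof.family_lods) == 1
    assert prof.family_lods.iloc[0] == pytest.approx(
        prof.raw_lod[prof.peak_index], abs=1e-8)


# ---------------------------------------------------------------------------
# two-LOD-drop region


def _profile(grid, lod):
    lod = np.asarray(lod, float)
    peak = int(np.argmax(lod))
    return LodProfile(np.asarray(grid, float), np.maximum(lod, 0), lod,
                      float(grid[peak]), float(lod[peak]),
                      pd.Series(dtype=float), VcFit(1, 0, 1, 0.0),
                      VcFit(1, 1, 1, 0.0))


def _gmap(cm, bp):
    return pd.DataFrame({"marker": [f"m{i}" for i in range(len(cm))],
                         "chrom": "1", "bp": bp, "cm": cm})


def test_two_lod_drop_on_triangular_profile():
    grid = np.arange(0.0, 101.0, 10.0)
    lod = 3.28 - np.abs(grid - 50.0) * 0.08   # peak 3.28 at 50 cM
    gmap = _gmap([0.0, 100.0], [1, 100_000_001])
    c, s, e, scm, ecm = lod_drop_region(_profile(grid, lod), gmap, "1", drop=2.0)
    # crossing 1.28 happens 25 cM either side; grid resolution 10 cM
    assert scm == 30.0 and ecm == 70.0
    assert s == pytest.approx(30.0e6 + 1, rel=1e-6)
    assert e == pytest.approx(70.0e6 + 1, rel=1e-6)


def test_flat_profile_returns_whole_grid():
    grid = np.arange(0.0, 51.0, 10.0)
    gmap = _gmap([0.0, 50.0], [1, 50_000_001])
    _, _, _, scm, ecm = lod_drop_region(_profile(grid, np.ones(6)), gmap, "1")
    assert (scm, ecm) == (0.0, 50.0)


def test_monotone_profile_clips_at_grid_edge():
    grid = np.arange(0.0, 51.0, 10.0)
    gmap = _gmap([0.0, 50.0], [1, 50_000_001])
    _, _, _, scm, ecm = lod_drop_region(
        _profile(grid, np.linspace(0, 5, 6)), gmap, "1", drop=2.0)
    assert ecm == 50.0 and scm > 0.0


def test_all_nan_profile_rejected():
    gmap = _gmap([0.0, 50.0], [1, 50_000_001])
    prof = _profile([0.0, 50.0], [np.nan, np.nan])
    with pytest.raises(InputError):
        lod_drop_region(prof, gmap, "1")
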