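"""Mixed-model null fit, burden/SKAT/single-variant tests, thresholds."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import chi2

from lodsift.association import (
    beta_weights,
    burden_test,
    fit_null,
    liu_pvalue,
    region_threshold,
    single_variant_test,
    skat_test,
)
from lodsift.datatypes import ConfigError, InputError
from lodsift.kinship import KinshipMatrix, pedigree_kinship
from lodsift.simulate import SimulationConfig, simulate_pedigrees


def _null(n=400, seed=0, K=None):
    rng = np.random.default_rng(seed)
    ids = [f"S{i}" for i in range(n)]
    y = pd.Series(rng.normal(0, 1, n), index=ids)
    X = pd.DataFrame({"x": rng.normal(0, 1, n)}, index=ids)
    if K is None:
        K = KinshipMatrix(ids, sp.csr_matrix((n, n)))
    return fit_null(y, X, K), y, X, rng


def test_beta_weight_reference_values():
    assert beta_weights(0.01) == pytest.approx(25 * 0.99 ** 24, rel=1e-12)
    assert beta_weights(0.01) == pytest.approx(19.64, abs=0.01)
    assert beta_weights(0.04) == pytest.approx(25 * 0.96 ** 24, rel=1e-12)
    # heavier weight on the rarer variant
    assert beta_weights(0.001) > beta_weights(0.01) > beta_weights(0.05)


def test_zero_kinship_null_model_matches_ols():
    null, y, X, _ = _null()
    Xv = np.column_stack([np.ones(len(y)), X["x"]])
    beta_ols, *_ = np.linalg.lstsq(Xv, y.to_numpy(), rcond=None)
    assert np.allclose(null.beta, beta_ols)
    assert null.sigma2_g == 0.0
    resid = y.to_numpy() - Xv @ beta_ols
    assert null.sigma2_e == pytest.approx(resid @ resid / (len(y) - 2))


def test_heritability_recovered_in_family_data():
    cfg = SimulationConfig(n_families=150, family_structure=((3, False, 1.0),),
                           seed=1)
    ped = simulate_pedigrees(cfg)
    K = pedigree_kinship(ped)
    ids = ped.individuals
    A = 2.0 * K.dense(ids)
    L = np.linalg.cholesky(A + 1e-8 * np.eye(len(ids)))
    rng = np.random.default_rng(2)
    h2 = 0.4
    ests = []
    for rep in range(8):
        g = np.sqrt(h2) * (L @ rng.standard_normal(len(ids)))
        y = pd.Series(g + np.sqrt(1 - h2) * rng.standard_normal(len(ids)),
                      index=ids)
        X = pd.DataFrame(index=y.index)
        null = fit_null(y, X, K)
        ests.append(null.heritability)
    assert np.mean(ests) == pytest.approx(h2, abs=0.1)


def test_duplicating_families_preserves_variance_components():
    cfg = SimulationConfig(n_families=40, family_structure=((2, False, 1.0),),
                           seed=3)
    ped = simulate_pedigrees(cfg)
    K = pedigree_kinship(ped)
    ids = ped.individuals
    rng = np.random.default_rng(4)
    A = 2.0 * K.dense(ids)
    L = np.linalg.cholesky(A + 1e-8 * np.eye(len(ids)))
    y = pd.Series(0.6 * (L @ rng.standard_normal(len(ids)))
                  + 0.8 * rng.standard_normal(len(ids)), index=ids)
    null1 = fit_null(y, pd.DataFrame(index=y.index), K, method="ml")
    ids2 = ids + [f"{i}__dup" for i in ids]
    K2 = KinshipMatrix(ids2, sp.block_diag([K.matrix, K.matrix]).tocsr())
    y2 = pd.Series(np.concatenate([y.to_numpy(), y.to_numpy()]), index=ids2)
    null2 = fit_null(y2, pd.DataFrame(index=y2.index), K2, method="ml")
    assert null2.sigma2_g == pytest.approx(null1.sigma2_g, rel=1e-4, abs=1e-8)
    assert null2.sigma2_e == pytest.approx(null1.sigma2_e, rel=1e-4, abs=1e-8)


def test_single_variant_equals_burden_and_skat_on_one_variant():
    null, y, X, rng = _null(seed=5)
    g = rng.binomial(2, 0.05, len(y)).astype(float)
    sv = single_variant_test(null, g)
    b = burden_test(null, g[:, None], weights=np.ones(1))
    s = skat_test(null, g[:, None], weights=np.ones(1))
    assert sv.p == pytest.approx(b.p, rel=1e-12)
    z = b.beta / b.se
    assert s.p == pytest.approx(chi2.sf(z * z, 1), rel=1e-10)


def test_burden_beta_sign_flips_under_allele_recoding():
    null, y, X, rng = _null(seed=6)
    g = rng.binomial(2, 0.1, len(y)).astype(float)
    a = single_variant_test(null, g)
    b = single_variant_test(null, 2.0 - g)
    assert a.beta == pytest.approx(-b.beta)
    assert a.p == pytest.approx(b.p, rel=1e-10)


def test_gene_tests_invariant_to_variant_order_and_zero_weight_padding():
    null, y, X, rng = _null(seed=7)
    G = rng.binomial(2, 0.03, (len(y), 6)).astype(float)
    maf = G.mean(axis=0) / 2
    perm = rng.permutation(6)
    b0 = burden_test(null, G, maf=maf)
    b1 = burden_test(null, G[:, perm], maf=maf[perm])
    s0 = skat_test(null, G, maf=maf)
    s1 = skat_test(null, G[:, perm], maf=maf[perm])
    assert b0.p == pytest.approx(b1.p, rel=1e-10)
    assert s0.p == pytest.approx(s1.p, rel=1e-8)
    # appending a zero-weight variant changes nothing
    Gz = np.hstack([G, rng.binomial(2, 0.2, (len(y), 1)).astype(float)])
    w = np.append(beta_weights(maf), 0.0)
    b2 = burden_test(null, Gz, weights=w)
    s2 = skat_test(null, Gz, weights=w)
    assert b2.p == pytest.approx(b0.p, rel=1e-10)
    assert s2.p == pytest.approx(s0.p, rel=1e-8)


def test_monomorphic_set_rejected():
    null, y, X, _ = _null(seed=8)
    with pytest.raises(InputError):
        burden_test(null, np.zeros((len(y), 3)))


def test_imhof_and_liu_agree_for_moderate_p():
    from lodsift.association import mixture_chi2_pvalue

    rng = np.random.default_rng(9)
    n_imhof = 0
    for _ in range(20):
        lam = rng.uniform(0.2, 3.0, rng.integers(2, 10))
        q = float(lam.sum() + rng.uniform(0, 3) * np.sqrt(2 * (lam ** 2).sum()))
        p, method = mixture_chi2_pvalue(q, lam)
        if method != "imhof":
            continue   # slow oscillatory tails legitimately fall back to Liu
        n_imhof += 1
        p_l = liu_pvalue(q, lam)
        if p > 1e-4:
            assert p_l == pytest.approx(p, rel=0.15)
    assert n_imhof >= 10   # inversion is the primary route, not the exception


def test_mean_imputation_of_missing_dosages():
    null, y, X, rng = _null(seed=10)
    g = rng.binomial(2, 0.1, len(y)).astype(float)
    g_missing = g.copy()
    g_missing[:10] = np.nan
    res = single_variant_test(null, g_missing)
    assert np.isfinite(res.p)


def test_region_thresholds_from_gene_counts():
    assert region_threshold(52) == pytest.approx(9.62e-4, abs=5e-7)
    assert region_threshold(354) == pytest.approx(1.41e-4, abs=5e-7)
    assert region_threshold(29) == pytest.approx(1.72e-3, abs=5e-6)
    assert region_threshold(112) == pytest.approx(4.46e-4, abs=5e-7)
    assert region_threshold(1) == 0.05
    with pytest.raises(ConfigError):
        region_threshold(0)
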