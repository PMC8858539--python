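"""Two-step LOD-weighted variant selection: thresholds, correlations, EM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lodsift.datatypes import ConfigError, GenotypeMatrix, PedigreeSet
from lodsift.selection import (
    fda_select,
    final_selection,
    fit_two_normal_mixture,
    informative_families,
    mac_lod_correlation,
    select_variants,
    step1_select,
)


def _ped(rows):
    return PedigreeSet(pd.DataFrame(rows, columns=["fid", "iid", "father",
                                                   "mother", "sex"]))


def _gm(samples, dosage):
    n_var = np.asarray(dosage).shape[1]
    var = pd.DataFrame({"chrom": "1", "pos": np.arange(1, n_var + 1),
                        "ref": "A", "alt": "T", "filter": "PASS"})
    var.index = [f"1:{p}:A:T" for p in var["pos"]]
    return GenotypeMatrix(samples, var, np.asarray(dosage, float))


def test_informative_families_excludes_parent_offspring_duos():
    rows = [
        ("A", "mo", "", "", 2), ("A", "kid", "", "mo", 1),   # mother-child duo
        ("B", "s1", "", "", 1), ("B", "s2", "", "", 2),       # two-member, no link
        ("C", "fa", "", "", 1), ("C", "mo2", "", "", 2),
        ("C", "c", "fa", "mo2", 1),                           # trio
    ]
    ped = _ped(rows)
    lods = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0})
    assert informative_families(ped, lods) == ["B", "C"]


def test_step1_lod_threshold_and_mac_rule():
    rows = []
    for f in (1, 2, 3):
        rows += [(f"F{f}", f"F{f}_fa", "", "", 1), (f"F{f}", f"F{f}_mo", "", "", 2),
                 (f"F{f}", f"F{f}_c1", f"F{f}_fa", f"F{f}_mo", 1),
                 (f"F{f}", f"F{f}_c2", f"F{f}_fa", f"F{f}_mo", 2)]
    ped = _ped(rows)
    lods = pd.Series({"F1": 0.5, "F2": 0.05, "F3": 0.2})
    samples = ped.individuals
    d = np.zeros((12, 3))
    d[0, 0] = 1.0                      # v1: MAC 1 in selected F1 -> excluded
    d[0, 1], d[2, 1] = 1.0, 1.0        # v2: MAC 2 in F1 -> included
    d[0, 2], d[8, 2] = 1.0, 1.0        # v3: MAC 1 in F1 + 1 in F3 -> included
    gm = _gm(samples, d)
    fams, mac, keys = step1_select(lods, gm, ped, ["F1", "F2", "F3"])
    assert fams == ["F1", "F3"]
    assert keys == ["1:2:A:T", "1:3:A:T"]
    # alternative reading: >= 2 distinct families
    _, _, keys_fam = step1_select(lods, gm, ped, ["F1", "F2", "F3"],
                                  count_mode="families")
    assert keys_fam == ["1:3:A:T"]


def test_mac_lod_correlation_examples():
    lods = pd.Series({"F1": 0.2, "F2": 0.4, "F3": 0.6, "F4": 0.8})
    mac = pd.DataFrame({
        "F1": [1, 2, 4, 0], "F2": [2, 2, 3, 0],
        "F3": [3, 2, 2, 0], "F4": [4, 2, 1, 0]},
        index=["prop", "const", "rev", "zero"])
    r = mac_lod_correlation(mac, lods)
    assert r["prop"] == pytest.approx(1.0)
    assert np.isnan(r["const"]) and np.isnan(r["zero"])
    assert r["rev"] == pytest.approx(-1.0)


def test_mixture_on_separated_clusters():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(-0.5, 0.01, 50), rng.normal(0.5, 0.01, 50)])
    fit = fit_two_normal_mixture(x, seed=1)
    assert fit.converged and not fit.degenerate
    assert fit.mu1 == pytest.approx(-0.5, abs=0.01)
    assert fit.mu2 == pytest.approx(0.5, abs=0.01)
    assert fit.pi == pytest.approx(0.5, abs=0.05)
    # fda picks exactly the upper cluster
    r = pd.Series(x, index=[f"v{i}" for i in range(100)])
    sel = fda_select(r, fit)
    assert set(sel) == {f"v{i}" for i in range(50, 100)}


def test_em_loglik_trace_nondecreasing():
    rng = np.random.default_rng(3)
    for _ in range(5):
        x = np.concatenate([rng.normal(0, 0.1, 60), rng.normal(0.4, 0.2, 40)])
        fit = fit_two_normal_mixture(x, seed=4)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs > -1e-9)


def test_degenerate_mixture_flagged():
    fit = fit_two_normal_mixture(np.full(20, 0.3))
    assert fit.degenerate
    r = pd.Series(np.full(20, 0.3), index=[f"v{i}" for i in range(20)])
    assert fda_select(r, fit) == []


def test_fda_threshold_boundary_is_strict():
    fit = fit_two_normal_mixture(
        np.concatenate([np.random.default_rng(0).normal(0, 0.01, 20),
                        np.random.default_rng(1).normal(0.4, 0.01, 20)]), seed=0)
    thr = fit.boundary
    r = pd.Series([thr, thr + 1e-9, 0.3], index=["at", "above", "in"])
    sel = fda_select(r, fit)
    assert "at" not in sel and "above" in sel and "in" in sel


def test_final_selection_modes():
    s1, s2 = ["a", "b", "c"], ["b", "c"]
    assert final_selection(s1, s2, "union") == ["a", "b", "c"]
    assert final_selection(s1, s2, "intersection") == ["b", "c"]
    assert final_selection(s1, [], "step2_filter") == s1   # fallback
    assert final_selection(s1, s2, "step2_filter") == s2
    with pytest.raises(ConfigError):
        final_selection(s1, s2, "bogus")
    with pytest.warns(UserWarning):
        assert final_selection(["a"], ["b"], "intersection") == []


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.permutations(list(range(6))))
def test_selection_invariant_to_family_label_permutation(perm):
    """Consistently relabelling families leaves the selected set unchanged."""
    rows = []
    for f in range(6):
        rows += [(f"F{f}", f"F{f}_fa", "", "", 1), (f"F{f}", f"F{f}_mo", "", "", 2),
                 (f"F{f}", f"F{f}_c1", f"F{f}_fa", f"F{f}_mo", 1),
                 (f"F{f}", f"F{f}_c2", f"F{f}_fa", f"F{f}_mo", 2)]
    ped = _ped(rows)
    rng = np.random.default_rng(9)
    d = rng.binomial(1, 0.1, (24, 12)).astype(float)
    gm = _gm(ped.individuals, d)
    lods = pd.Series({f"F{f}": v for f, v in
                      zip(range(6), [0.5, 0.3, 0.2, 0.05, -0.1, 0.15])})
    gene_of = pd.Series("G1", index=gm.keys)
    base = select_variants(gm, ped, lods, gene_of, min_mixture_n=5, seed=0)
    # permuted family ordering in the LOD series
    lods_perm = lods.iloc[list(perm)]
    alt = select_variants(gm, ped, lods_perm, gene_of, min_mixture_n=5, seed=0)
    assert sorted(base.table.index[base.table["final"]]) == \
        sorted(alt.table.index[alt.table["final"]])
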