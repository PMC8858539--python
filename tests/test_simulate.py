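"""Synthetic-cohort generator: structure, Mendelian consistency, determinism."""

import numpy as np
import pandas as pd
import pytest

from lodsift.datatypes import ConfigError
from lodsift.simulate import (
    MedicationModel,
    SimulationConfig,
    gene_drop,
    haldane_theta,
    linkage_marker_map,
    simulate_dataset,
    simulate_pedigrees,
    simulate_phenotypes,
)


def test_haldane_map_function_reference_values():
    assert haldane_theta(10.0) == pytest.approx(0.09063, abs=5e-6)
    assert haldane_theta(0.0) == 0.0
    # unlinked limit
    assert haldane_theta(1e6) == pytest.approx(0.5)


def test_nuclear_family_structure():
    cfg = SimulationConfig(n_families=1, family_structure=((2, False, 1.0),))
    ped = simulate_pedigrees(cfg)
    assert len(ped.individuals) == 4
    assert len(ped.founders()) == 2


@pytest.mark.parametrize("bad", [
    dict(n_families=0),
    dict(family_structure=()),
    dict(qtl_variance_fraction=0.6, polygenic_h2=0.5),
    dict(rare_maf_range=(0.01, 0.2)),
])
def test_invalid_configuration_rejected(bad):
    with pytest.raises(ConfigError):
        SimulationConfig(**bad)


def test_pedigree_simulation_is_deterministic():
    cfg = SimulationConfig(n_families=100, seed=7)
    a = simulate_pedigrees(cfg)
    b = simulate_pedigrees(cfg)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_pedigrees_are_structurally_valid():
    ped = simulate_pedigrees(SimulationConfig(n_families=50, seed=3))
    # every non-founder has both parents in the same family; ctor validates
    for child, fa, mo in ped.trios():
        fam = ped.table.set_index("iid")["fid"]
        assert fam[child] == fam[fa] == fam[mo]


def test_gene_drop_is_mendelian_consistent_in_all_trios(small_dataset):
    gm = small_dataset.markers
    ped = small_dataset.pedigrees
    idx = {s: i for i, s in enumerate(gm.samples)}
    for child, fa, mo in ped.trios():
        c, f, m = (gm.dosage[idx[i]] for i in (child, fa, mo))
        # child dosage must be achievable from one allele per parent
        cmin = np.clip(f - 1, 0, 1) + np.clip(m - 1, 0, 1)
        cmax = np.clip(f, 0, 1) + np.clip(m, 0, 1)
        assert np.all((c >= cmin) & (c <= cmax))


def test_gene_drop_founder_frequency_matches_target():
    # 500 founder couples -> 2000 founder haplotypes
    cfg = SimulationConfig(n_families=500, family_structure=((1, False, 1.0),),
                           n_linkage_markers=2, seed=5)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    gm = gene_drop(ped, gmap, np.array([0.3, 0.3]), seed=6)
    fidx = gm.sample_indices(ped.founders())
    freq = gm.alt_freq(sample_idx=fidx)
    n_hap = 2 * len(ped.founders())
    se = np.sqrt(0.3 * 0.7 / n_hap)
    assert np.all(np.abs(freq - 0.3) < 3 * se)


def test_zero_distance_markers_share_haplotype_blocks():
    cfg = SimulationConfig(n_families=50, family_structure=((3, False, 1.0),),
                           seed=9)
    ped = simulate_pedigrees(cfg)
    gmap = pd.DataFrame({"marker": ["a", "b"], "chrom": "1",
                         "bp": [100, 200], "cm": [5.0, 5.0]})
    gm, origins = gene_drop(ped, gmap, np.array([0.4, 0.4]), seed=10,
                            return_origins=True)
    for iid, arr in origins.slots.items():
        assert np.array_equal(arr[:, 0], arr[:, 1])


def test_gene_drop_unsorted_map_rejected(nuclear_family):
    gmap = pd.DataFrame({"marker": ["a", "b"], "chrom": "1",
                         "bp": [100, 200], "cm": [5.0, 1.0]})
    with pytest.raises(ConfigError):
        gene_drop(nuclear_family, gmap, np.array([0.4, 0.4]), seed=1)


def test_rare_variant_annotation_deterministic(small_config):
    a = simulate_dataset(small_config).annotation
    b = simulate_dataset(small_config).annotation
    pd.testing.assert_frame_equal(a, b)


def test_causal_variant_mac_within_mendelian_bounds(small_dataset):
    anno = small_dataset.annotation
    rare = small_dataset.rare
    ped = small_dataset.pedigrees
    for key in anno.loc[anno["causal"], "key"]:
        sub = rare.subset(variant_keys=[key])
        for fid in ped.family_ids:
            ids = ped.members(fid)["iid"].tolist()
            mac = np.nansum(sub.dosage[sub.sample_indices(ids)])
            assert 0 <= mac <= 2 * len(ids)


def test_phenotype_variance_matches_configured_sd():
    cfg = SimulationConfig(
        n_families=500, family_structure=((2, False, 1.0),),
        n_linkage_markers=2, qtl_variance_fraction=0.0, polygenic_h2=0.0,
        covariate_effects=(0.0, 0.0, 0.0, 0.0),
        studies=(type(SimulationConfig().studies[0])("S1", "AA", 20.0, ("C1",)),),
        medication_model=MedicationModel(intercept=-30.0),  # nobody treated
        seed=4)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    gm = gene_drop(ped, gmap, np.array([0.3, 0.3]), seed=5)
    ph = simulate_phenotypes(gm, ped, cfg, seed=6)
    assert ph["sbp"].var() == pytest.approx(400.0, rel=0.10)


def test_treated_individuals_observe_latent_minus_effect(small_dataset):
    ph = small_dataset.phenotypes
    treated = ph[ph["med"] == 1]
    assert len(treated) > 0
    assert np.allclose(treated["sbp"], treated["latent_sbp"] - 15.0)
    assert np.allclose(treated["dbp"], treated["latent_dbp"] - 10.0)


def test_full_sib_phenotype_correlation_matches_kin_expectation():
    # corr(sibs) ~ h2/2 + qtl/2 for latent traits
    h2, q2 = 0.5, 0.2
    cfg = SimulationConfig(
        n_families=1500, family_structure=((2, False, 1.0),),
        n_linkage_markers=3, qtl_variance_fraction=q2, polygenic_h2=h2,
        covariate_effects=(0.0, 0.0, 0.0, 0.0),
        studies=(type(SimulationConfig().studies[0])("S1", "AA", 20.0, ("C1",)),),
        seed=11)
    ped = simulate_pedigrees(cfg)
    gmap = linkage_marker_map(cfg)
    gm = gene_drop(ped, gmap, np.full(3, 0.3), seed=12)
    qtl = gm.keys[1]
    ph = simulate_phenotypes(gm, ped, cfg, seed=13, qtl_variants=[qtl]).set_index("iid")
    sib1, sib2 = [], []
    for fid in ped.family_ids:
        kids = [i for i in ped.members(fid)["iid"] if not ped.is_founder(i)]
        sib1.append(ph.loc[kids[0], "latent_sbp"])
        sib2.append(ph.loc[kids[1], "latent_sbp"])
    r = np.corrcoef(sib1, sib2)[0, 1]
    # QTL sib correlation is ~q2/2 for an additive locus
    assert r == pytest.approx(h2 / 2 + q2 / 2, abs=0.06)


def test_dataset_outputs_identical_across_runs(small_config, small_dataset):
    other = simulate_dataset(small_config)
    assert np.array_equal(other.markers.dosage, small_dataset.markers.dosage)
    assert np.array_equal(other.rare.dosage, small_dataset.rare.dosage)
    pd.testing.assert_frame_equal(other.phenotypes, small_dataset.phenotypes)
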