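"""Synthetic pedigree / genotype / blood-pressure cohort generator.

Emulates the structure the analysis assumes: multiple studies with differing
trait scales, nuclear and three-generation families, a panel of common
linkage markers on a centimorgan map, rare coding and non-coding variants
clustered in genes under a linkage peak and co-segregating within carrier
families, and BP phenotypes with polygenic + QTL + covariate + noise
components plus BP-dependent antihypertensive-medication use.

Recombination uses the Haldane (no-interference) map function: two loci
``d`` cM apart recombine with probability ``theta = (1 - exp(-2d/100)) / 2``.
One crossover process is simulated per meiosis, matching the transition
model of the multipoint IBD HMM in :mod:`lodsift.linkage`.

The phenotype model for a latent (untreated) trait is::

    latent = baseline + covariates + beta_q * QTL dosage + polygenic + noise

where the polygenic value is multivariate normal with covariance
``2 * Phi * sigma2_a`` from pedigree kinship, and the QTL effect is scaled so
the QTL and polygenic components explain the configured fractions of the
trait variance (``trait_SD_mmHg ** 2``).  Medication use is drawn from a
logistic model on the latent systolic BP, and treated individuals' observed
pressures are ``latent - treatment_effect`` — the bias the downstream
+15/+10 mmHg adjustment is designed to correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigError,
    GenotypeMatrix,
    PedigreeSet,
    SEX_FEMALE,
    SEX_MALE,
    variant_key,
)

__all__ = [
    "StudySpec",
    "MedicationModel",
    "SimulationConfig",
    "haldane_theta",
    "simulate_pedigrees",
    "linkage_marker_map",
    "gene_drop",
    "plant_rare_variants",
    "default_carrier_plan",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
]

_CHROM = "1"
_BP_PER_CM = 1_000_000  # pseudo-chromosome: 1 cM per Mb


@dataclass(frozen=True)
class StudySpec:
    study_id: str
    ancestry: str
    trait_sd_mmhg: float
    center_ids: tuple[str, ...] = ("C1",)

    def __post_init__(self):
        if self.trait_sd_mmhg <= 0:
            raise ConfigError(f"study {self.study_id}: trait SD must be > 0")


@dataclass(frozen=True)
class MedicationModel:
    """P(treated) = expit(intercept + slope * (latent SBP - 140 mmHg))."""

    intercept: float = -2.2
    slope: float = 0.06
    treatment_effect_sbp: float = 15.0
    treatment_effect_dbp: float = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``family_structure`` is a distribution over ``(n_offspring,
    include_grandparents)`` given as ``((n_offspring, grandparents, weight),
    ...)``.  Grandparent families add the father's parents as founders.
    """

    n_families: int = 100
    family_structure: tuple[tuple[int, bool, float], ...] = (
        (2, False, 0.5),
        (3, False, 0.3),
        (2, True, 0.2),
    )
    n_linkage_markers: int = 60
    map_length_cm: float = 100.0
    qtl_position_cm: float = 50.0
    qtl_maf: float = 0.3
    qtl_variance_fraction: float = 0.15
    polygenic_h2: float = 0.35
    n_genes: int = 5
    rare_variant_count_per_gene: int = 20
    rare_maf_range: tuple[float, float] = (0.001, 0.01)
    causal_variants_per_gene: int = 3
    carrier_family_fraction: float = 0.3
    studies: tuple[StudySpec, ...] = (
        StudySpec("HYPERGEN", "AA", 21.0, ("C1", "C2")),
        StudySpec("GENOA", "AA", 19.0, ("C3",)),
    )
    baseline_sbp: float = 127.0
    baseline_dbp: float = 79.0
    dbp_sd_fraction: float = 0.6
    covariate_effects: tuple[float, float, float, float] = (0.35, 0.002, -4.0, 0.5)
    medication_model: MedicationModel = MedicationModel()
    seed: int = 17

    def __post_init__(self):
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if not self.family_structure:
            raise ConfigError("family_structure distribution is empty")
        if any(w < 0 for _, _, w in self.family_structure):
            raise ConfigError("family_structure weights must be non-negative")
        if sum(w for _, _, w in self.family_structure) <= 0:
            raise ConfigError("family_structure weights sum to zero")
        if any(k < 1 for k, _, _ in self.family_structure):
            raise ConfigError("each family needs at least one offspring")
        if not 0 <= self.qtl_variance_fraction < 1 or not 0 <= self.polygenic_h2 < 1:
            raise ConfigError("variance fractions must be in [0, 1)")
        if self.qtl_variance_fraction + self.polygenic_h2 >= 1:
            raise ConfigError("qtl_variance_fraction + polygenic_h2 must be < 1")
        lo, hi = self.rare_maf_range
        if not (0 < lo <= hi <= 0.05):
            raise ConfigError("rare_maf_range must satisfy 0 < lo <= hi <= 0.05")
        if not 0 <= self.qtl_position_cm <= self.map_length_cm:
            raise ConfigError("qtl_position_cm outside the map")


def haldane_theta(d_cm) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# pedigrees


def simulate_pedigrees(config: SimulationConfig) -> PedigreeSet:
    """Draw family structures from the configured distribution.

    Deterministic given ``config.seed``.  Ids are ``F####_I##``; founders have
    no parents.  Grandparent families attach the father's parents.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([w for _, _, w in config.family_structure], dtype=float)
    weights = weights / weights.sum()
    rows = []
    for f in range(config.n_families):
        fid = f"F{f + 1:04d}"
        k = rng.choice(len(config.family_structure), p=weights)
        n_off, grand, _ = config.family_structure[k]
        nxt = iter(range(1, 64))

        def iid():
            return f"{fid}_I{next(nxt):02d}"

        father, mother = iid(), iid()
        if grand:
            gf, gm = iid(), iid()
            rows.append((fid, gf, "", "", SEX_MALE))
            rows.append((fid, gm, "", "", SEX_FEMALE))
            rows.append((fid, father, gf, gm, SEX_MALE))
        else:
            rows.append((fid, father, "", "", SEX_MALE))
        rows.append((fid, mother, "", "", SEX_FEMALE))
        for _ in range(int(n_off)):
            sex = SEX_MALE if rng.random() < 0.5 else SEX_FEMALE
            rows.append((fid, iid(), father, mother, sex))
    table = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    return PedigreeSet(table)


# ---------------------------------------------------------------------------
# gene drop


def linkage_marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced common-marker map over the pseudo-chromosome."""
    cm = np.linspace(0.0, config.map_length_cm, config.n_linkage_markers)
    return pd.DataFrame({
        "marker": [f"M{i + 1:04d}" for i in range(config.n_linkage_markers)],
        "chrom": _CHROM,
        "bp": (cm * _BP_PER_CM).astype(int) + 1,
        "cm": cm,
    })


class _Origins:
    """Founder-haplotype origin of every individual's two haplotypes.

    ``slots[iid]`` -> (2, n_positions) int array of global founder haplotype
    slot ids; founders occupy two constant slots.  Shared by the marker gene
    drop and the rare-variant planting so causal alleles ride real meioses.
    """

    def __init__(self, pedigrees: PedigreeSet, cm_positions: np.ndarray, rng):
        pedigrees = pedigrees.complete_parents()
        cm = np.asarray(cm_positions, dtype=float)
        if np.any(np.diff(cm) < 0):
            raise ConfigError("cM positions must be sorted")
        self.cm = cm
        theta = haldane_theta(np.diff(cm))
        self.slots: dict[str, np.ndarray] = {}
        self.founder_slot: dict[str, tuple[int, int]] = {}
        nslot = 0
        P = len(cm)
        for fid in pedigrees.family_ids:
            order = pedigrees.topological_order(fid)
            tab = pedigrees.members(fid).set_index("iid")
            for iid in order:
                fa, mo = tab.loc[iid, "father"], tab.loc[iid, "mother"]
                if fa == "":
                    self.founder_slot[iid] = (nslot, nslot + 1)
                    arr = np.empty((2, P), dtype=np.int32)
                    arr[0, :] = nslot
                    arr[1, :] = nslot + 1
                    nslot += 2
                else:
                    arr = np.empty((2, P), dtype=np.int32)
                    for h, parent in enumerate((fa, mo)):
                        # meiosis: which parental haplotype at each position
                        b = np.empty(P, dtype=np.int64)
                        b[0] = rng.integers(2)
                        if P > 1:
                            flips = rng.random(P - 1) < theta
                            b[1:] = flips
                            b = np.cumsum(b) % 2
                        arr[h] = self.slots[parent][b, np.arange(P)]
                self.slots[iid] = arr
        self.n_slots = nslot

    def at(self, cm_value: float) -> dict[str, tuple[int, int]]:
        """Origins at the position closest to ``cm_value``."""
        j = int(np.argmin(np.abs(self.cm - cm_value)))
        return {iid: (int(a[0, j]), int(a[1, j])) for iid, a in self.slots.items()}


def gene_drop(pedigrees: PedigreeSet, gmap: pd.DataFrame, founder_freqs,
              seed: int, return_origins: bool = False):
    """Drop founder haplotypes through the pedigree at the mapped markers.

    Founder haplotypes are independent Bernoulli draws at the given ALT
    frequencies; offspring haplotypes follow Mendelian transmission with
    Haldane recombination between adjacent markers.  Output is Mendelian
    consistent within every family by construction.
    """
    freqs = np.asarray(founder_freqs, dtype=float)
    if freqs.ndim == 0:
        freqs = np.full(len(gmap), float(freqs))
    if len(freqs) != len(gmap):
        raise ConfigError("founder_freqs length must match the map")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ConfigError("founder allele frequencies must be in (0, 1)")
    cm = gmap["cm"].to_numpy(dtype=float)
    if np.any(np.diff(cm) < 0):
        raise ConfigError("genetic map cM positions must be sorted")
    rng = np.random.default_rng(seed)
    origins = _Origins(pedigrees, cm, rng)
    alleles = (rng.random((origins.n_slots, len(cm))) < freqs).astype(np.int8)
    samples = pedigrees.individuals
    dosage = np.empty((len(samples), len(cm)))
    cols = np.arange(len(cm))
    for i, iid in enumerate(samples):
        o = origins.slots[iid]
        dosage[i] = alleles[o[0], cols] + alleles[o[1], cols]
    variants = pd.DataFrame({
        "chrom": gmap["chrom"].astype(str).to_numpy(),
        "pos": gmap["bp"].to_numpy(dtype=int),
        "ref": "A",
        "alt": "G",
        "filter": "PASS",
    })
    variants.index = [variant_key(c, p, "A", "G")
                      for c, p in zip(variants["chrom"], variants["pos"])]
    gm = GenotypeMatrix(samples, variants, dosage)
    if return_origins:
        return gm, origins
    return gm


# ---------------------------------------------------------------------------
# rare variants under the peak

_NONCODING_CONSEQUENCES = ("intron_variant", "synonymous_variant",
                           "upstream_gene_variant", "3_prime_UTR_variant")
_CODING_CONSEQUENCES = ("missense_variant", "splice_region_variant",
                        "frameshift_variant", "stop_gained")


def default_carrier_plan(pedigrees: PedigreeSet, config: SimulationConfig,
                         seed: int) -> dict[str, tuple[list[int], list[str]]]:
    """Per gene: indices of causal variants and the carrier founder families."""
    rng = np.random.default_rng(seed)
    fams = pedigrees.family_ids
    n_carrier = max(1, int(round(config.carrier_family_fraction * len(fams))))
    plan = {}
    for g in range(config.n_genes):
        gene = f"GENE{g + 1}"
        causal = list(range(min(config.causal_variants_per_gene,
                                config.rare_variant_count_per_gene)))
        carriers = sorted(rng.choice(fams, size=n_carrier, replace=False))
        plan[gene] = (causal, list(carriers))
    return plan


def _gene_intervals(config: SimulationConfig) -> pd.DataFrame:
    """Gene intervals of 40 kb tiled around the QTL position."""
    width = 40_000
    gap = 20_000
    qtl_bp = int(config.qtl_position_cm * _BP_PER_CM)
    start0 = qtl_bp - (config.n_genes * (width + gap)) // 2
    rows = []
    for g in range(config.n_genes):
        s = start0 + g * (width + gap)
        rows.append((f"GENE{g + 1}", _CHROM, s, s + width))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def plant_rare_variants(pedigrees: PedigreeSet, config: SimulationConfig,
                        carrier_plan: dict, seed: int,
                        origins: _Origins | None = None):
    """Introduce rare variants in genes under the peak; returns (GenotypeMatrix, annotation).

    Causal variants are placed on one founder haplotype per carrier family
    (the family's risk haplotype) and transmitted through the same simulated
    meioses as the linkage markers, creating co-segregation between family
    minor-allele counts, IBD sharing at the QTL, and — once phenotypes are
    attached — family-specific LOD scores.  Non-causal rare variants are
    scattered across founder haplotypes at frequencies from
    ``rare_maf_range``.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_intervals(config)
    gene_lookup = genes.set_index("gene")
    for gene, (causal_idx, fams) in carrier_plan.items():
        if gene not in gene_lookup.index:
            raise ConfigError(f"carrier plan names unknown gene {gene}")
        unknown = set(fams) - set(pedigrees.family_ids)
        if unknown:
            raise ConfigError(f"carrier families not in pedigree: {sorted(unknown)}")
        if max(causal_idx, default=-1) >= config.rare_variant_count_per_gene:
            raise ConfigError(f"causal variant index out of range for {gene}")

    samples = pedigrees.individuals
    sample_pos = {s: i for i, s in enumerate(samples)}
    n_founder_hap = 2 * len(pedigrees.founders())

    rows, dosage_cols, anno_rows = [], [], []
    risk_slot: dict[tuple[str, str], int] = {}
    for _, g in genes.iterrows():
        gene = g["gene"]
        causal_idx, carrier_fams = carrier_plan.get(gene, ([], []))
        positions = np.sort(rng.choice(
            np.arange(g["start"] + 1, g["end"]), size=config.rare_variant_count_per_gene,
            replace=False))
        for v in range(config.rare_variant_count_per_gene):
            pos = int(positions[v])
            cm_pos = pos / _BP_PER_CM
            if origins is None:
                raise ConfigError("plant_rare_variants requires gene-drop origins")
            orig_at = origins.at(cm_pos)
            carrier_slots: set[int] = set()
            causal = v in causal_idx
            if causal:
                for fid in carrier_fams:
                    key = (gene, fid)
                    if key not in risk_slot:
                        fam_founders = pedigrees.founders(fid)
                        fo = fam_founders[int(rng.integers(len(fam_founders)))]
                        hap = int(rng.integers(2))
                        risk_slot[key] = origins.founder_slot[fo][hap]
                    carrier_slots.add(risk_slot[key])
            else:
                maf = rng.uniform(*config.rare_maf_range)
                n_copies = rng.binomial(n_founder_hap, maf)
                if n_copies > 0:
                    all_slots = [s for pair in origins.founder_slot.values() for s in pair]
                    carrier_slots = set(rng.choice(all_slots, size=n_copies, replace=False))
            dos = np.zeros(len(samples))
            if carrier_slots:
                for iid, (a, b) in orig_at.items():
                    if iid in sample_pos:  # phantom parents carry no samples
                        dos[sample_pos[iid]] = (a in carrier_slots) + (b in carrier_slots)
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
            key = variant_key(_CHROM, pos, ref, alt)
            rows.append((key, _CHROM, pos, ref, alt))
            dosage_cols.append(dos)
            if causal:
                consequence = _CODING_CONSEQUENCES[int(rng.integers(2))]  # missense/splice
                cadd = rng.uniform(15, 35)
                fathmm = rng.uniform(0.6, 0.99)
            else:
                coding = rng.random() < 0.3
                consequence = (_CODING_CONSEQUENCES[int(rng.integers(len(_CODING_CONSEQUENCES)))]
                               if coding else
                               _NONCODING_CONSEQUENCES[int(rng.integers(len(_NONCODING_CONSEQUENCES)))])
                cadd = rng.uniform(0, 20)
                fathmm = rng.uniform(0, 0.8)
            anno_rows.append((key, gene, consequence, round(cadd, 3), round(fathmm, 3),
                              _CHROM, int(g["start"]), int(g["end"]), causal))

    variants = pd.DataFrame([r[1:] for r in rows],
                            columns=["chrom", "pos", "ref", "alt"],
                            index=[r[0] for r in rows])
    variants["filter"] = "PASS"
    dosage = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    gm = GenotypeMatrix(samples, variants, dosage)
    anno = pd.DataFrame(anno_rows, columns=["key", "gene", "consequence", "cadd_phred",
                                            "fathmm_xf", "gene_chrom", "gene_start",
                                            "gene_end", "causal"])
    return gm, anno


# ---------------------------------------------------------------------------
# phenotypes


def _polygenic_values(pedigrees: PedigreeSet, sigma2_a: float, rng,
                      kinship=None) -> pd.Series:
    """MVN(0, 2*Phi*sigma2_a) drawn family by family (exact, cheap)."""
    from .kinship import pedigree_kinship

    if sigma2_a <= 0:
        return pd.Series(0.0, index=pedigrees.individuals)
    K = pedigree_kinship(pedigrees) if kinship is None else kinship
    ids = pedigrees.individuals
    A = 2.0 * sigma2_a * K.dense(ids) + 1e-10 * np.eye(len(ids))
    L = np.linalg.cholesky(A)   # block diagonal over families: cheap
    return pd.Series(L @ rng.standard_normal(len(ids)), index=ids)


def simulate_phenotypes(genotypes: GenotypeMatrix, pedigrees: PedigreeSet,
                        config: SimulationConfig, seed: int,
                        qtl_variants: list[str] | None = None,
                        kinship=None) -> pd.DataFrame:
    """BP phenotypes with polygenic + QTL + covariate + noise components.

    ``qtl_variants`` names the dosage columns whose (unit-weighted) sum is the
    QTL burden; its effect size is scaled so the QTL explains
    ``qtl_variance_fraction`` of the configured trait variance.  DBP shares
    the QTL (scaled) but has its own polygenic and residual draws; its
    residual noise is correlated with SBP's (rho 0.6) so SBP > DBP almost
    surely.  The raw pulse pressure column is *not* emitted — it is derived
    downstream after medication adjustment.
    """
    if config.qtl_variance_fraction + config.polygenic_h2 >= 1:
        raise ConfigError("variance fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    samples = pedigrees.individuals
    n = len(samples)

    # QTL burden, standardized on the simulated sample
    if config.qtl_variance_fraction > 0:
        if not qtl_variants:
            raise ConfigError("qtl_variance_fraction > 0 requires qtl_variants")
        sub = genotypes.subset(samples=samples, variant_keys=qtl_variants)
        burden = np.nansum(sub.dosage, axis=1)
        sd = burden.std()
        if sd == 0:
            raise ConfigError("QTL variants are monomorphic in the sample")
        qtl_std = (burden - burden.mean()) / sd
    else:
        qtl_std = np.zeros(n)

    # family/study assignment: whole families belong to one study
    weights = np.ones(len(config.studies)) / len(config.studies)
    fam_study = {fid: config.studies[rng.choice(len(config.studies), p=weights)]
                 for fid in pedigrees.family_ids}

    tab = pedigrees.table.set_index("iid").loc[samples]
    founder = (tab["father"] == "").to_numpy()
    parent_ids = (set(tab["father"]) | set(tab["mother"])) - {""}
    is_parent = tab.index.isin(sorted(parent_ids))
    u = rng.random(n)
    age = np.select(
        [founder & is_parent, founder, is_parent],
        [45 + 30 * u, 60 + 25 * u, 45 + 25 * u],
        default=25 + 25 * u)
    sex = tab["sex"].to_numpy(dtype=int)
    female = (sex == SEX_FEMALE).astype(float)
    bmi = rng.normal(28.0, 4.0, n)
    b_age, b_age2, b_sex, b_bmi = config.covariate_effects
    cov_eff = b_age * age + b_age2 * age ** 2 + b_sex * female + b_bmi * bmi
    cov_eff = cov_eff - cov_eff.mean()

    fids = tab["fid"].to_numpy()
    studies = [fam_study[f] for f in fids]
    sd_sbp = np.array([s.trait_sd_mmhg for s in studies])
    sd_dbp = config.dbp_sd_fraction * sd_sbp
    h2, q2 = config.polygenic_h2, config.qtl_variance_fraction
    e2 = 1.0 - h2 - q2

    poly_s = _polygenic_values(pedigrees, h2, rng, kinship).loc[samples].to_numpy()
    poly_d = _polygenic_values(pedigrees, h2, rng, kinship).loc[samples].to_numpy()
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    noise_s = math.sqrt(e2) * z1
    noise_d = math.sqrt(e2) * (0.6 * z1 + math.sqrt(1 - 0.36) * z2)

    latent_sbp = config.baseline_sbp + cov_eff + sd_sbp * (
        math.sqrt(q2) * qtl_std + poly_s + noise_s)
    latent_dbp = config.baseline_dbp + 0.5 * cov_eff + sd_dbp * (
        math.sqrt(q2) * qtl_std + poly_d + noise_d)

    med = config.medication_model
    p_treat = 1.0 / (1.0 + np.exp(-(med.intercept + med.slope * (latent_sbp - 140.0))))
    treated = rng.random(n) < p_treat
    sbp = np.where(treated, latent_sbp - med.treatment_effect_sbp, latent_sbp)
    dbp = np.where(treated, latent_dbp - med.treatment_effect_dbp, latent_dbp)

    center = [s.center_ids[rng.integers(len(s.center_ids))] for s in studies]
    pheno = pd.DataFrame({
        "iid": samples,
        "fid": fids,
        "study": [s.study_id for s in studies],
        "center": center,
        "ancestry": [s.ancestry for s in studies],
        "sex": sex,
        "age": np.round(age, 1),
        "bmi": np.round(bmi, 2),
        "sbp": sbp,
        "dbp": dbp,
        "med": treated.astype(int),
        "PC1": rng.standard_normal(n),
        "PC2": rng.standard_normal(n),
        "latent_sbp": latent_sbp,
        "latent_dbp": latent_dbp,
    })
    return pheno


# ---------------------------------------------------------------------------
# end-to-end bundle


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    pedigrees: PedigreeSet
    gmap: pd.DataFrame
    markers: GenotypeMatrix
    rare: GenotypeMatrix
    annotation: pd.DataFrame
    phenotypes: pd.DataFrame

    @property
    def genotypes(self) -> GenotypeMatrix:
        """Markers and rare variants merged, sorted by position."""
        var = pd.concat([self.markers.variants, self.rare.variants])
        dosage = np.hstack([self.markers.dosage, self.rare.dosage])
        order = np.argsort(var["pos"].to_numpy(), kind="stable")
        return GenotypeMatrix(self.markers.samples, var.iloc[order], dosage[:, order])


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the whole generator: pedigrees, markers, rare variants, phenotypes.

    The phenotype QTL is the set of causal rare variants planted in carrier
    families, so linkage evidence, family LODs and MAC–LOD correlations all
    trace back to the same alleles.
    """
    seed = config.seed
    ped = simulate_pedigrees(config)
    gmap = linkage_marker_map(config)
    freqs = np.random.default_rng(seed + 1).uniform(0.25, 0.5, len(gmap))
    markers, origins = gene_drop(ped, gmap, freqs, seed + 2, return_origins=True)
    plan = default_carrier_plan(ped, config, seed + 3)
    rare, anno = plant_rare_variants(ped, config, plan, seed + 4, origins=origins)
    causal_keys = anno.loc[anno["causal"], "key"].tolist()
    segregating = [k for k in causal_keys
                   if np.nansum(rare.subset(variant_keys=[k]).dosage) > 0]
    qtl = segregating if config.qtl_variance_fraction > 0 else None
    pheno = simulate_phenotypes(rare, ped, config, seed + 5, qtl_variants=qtl)
    return SyntheticDataset(config, ped, gmap, markers, rare, anno, pheno)


# ---------------------------------------------------------------------------
# writers

_PHENO_COLUMNS = ["iid", "fid", "study", "center", "ancestry", "sex", "age",
                  "bmi", "sbp", "dbp", "med", "PC1", "PC2"]


def write_dataset(ds: SyntheticDataset, outdir, depth_mean: float = 30.0) -> dict:
    """Emit VCF v4.2 (GT:DP), PED, phenotype CSV, map TSV and annotation TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "ped": os.path.join(outdir, "families.ped"),
        "pheno": os.path.join(outdir, "phenotypes.csv"),
        "map": os.path.join(outdir, "genetic_map.tsv"),
        "anno": os.path.join(outdir, "annotation.tsv"),
    }
    gm = ds.genotypes
    rng = np.random.default_rng(ds.config.seed + 9)
    depth = rng.poisson(depth_mean, size=gm.dosage.shape)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={_CHROM}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, (key, row) in enumerate(gm.variants.iterrows()):
            cells = []
            for i in range(gm.n_samples):
                d = gm.dosage[i, j]
                gt = "./." if np.isnan(d) else gt_map[d]
                cells.append(f"{gt}:{depth[i, j]}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{key}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t{row.get('filter', 'PASS')}\t.\tGT:DP\t"
                     + "\t".join(cells) + "\n")
    ds.pedigrees.to_ped(paths["ped"])
    ds.phenotypes[_PHENO_COLUMNS].to_csv(paths["pheno"], index=False)
    ds.gmap.to_csv(paths["map"], sep="\t", index=False)
    anno = ds.annotation.drop(columns=["causal"])
    anno.to_csv(paths["anno"], sep="\t", index=False)
    return paths
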