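"""Pedigree and genotype-based kinship, sparsification, unrelated selection.

The discovery mixed models use pedigree kinship (exact under the recorded
family structures); the KING-robust estimator is the genotype-based
cross-check and the replication-path relatedness filter.  "Fourth-degree"
sparsification zeroes coefficients below the KING degree boundary
``2 ** -(degree + 3/2)`` (0.0221 for degree 4); the unrelated-subset filter
uses the third-degree boundary 0.0884.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import ConfigError, GenotypeMatrix, PedigreeSet

UNRELATED_KINSHIP_THRESHOLD = 0.0884  # KING third-degree boundary


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients phi, stored sparse.

    ``provenance`` is "pedigree" or "genotype".  Pedigree kinship has
    diagonal >= 0.5 and off-diagonal in [0, 0.5].
    """

    sample_ids: list[str]
    matrix: sp.csr_matrix
    provenance: str = "pedigree"

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.matrix = sp.csr_matrix(self.matrix)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ConfigError("kinship matrix shape inconsistent with sample ids")
        asym = abs(self.matrix - self.matrix.T)
        if asym.nnz and asym.max() > 1e-10:
            raise ConfigError("kinship matrix must be symmetric")

    def phi(self, i: str, j: str) -> float:
        a = self.sample_ids.index(i)
        b = self.sample_ids.index(j)
        return float(self.matrix[a, b])

    def dense(self, ids=None) -> np.ndarray:
        if ids is None:
            return self.matrix.toarray()
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return self.matrix[np.ix_(idx, idx)].toarray()

    def subset(self, ids) -> "KinshipMatrix":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return KinshipMatrix(list(ids), self.matrix[np.ix_(idx, idx)],
                             self.provenance)

    def to_triplets(self) -> pd.DataFrame:
        coo = sp.triu(self.matrix).tocoo()
        return pd.DataFrame({
            "id1": [self.sample_ids[i] for i in coo.row],
            "id2": [self.sample_ids[j] for j in coo.col],
            "phi": coo.data,
        })


def pedigree_kinship(pedigrees: PedigreeSet) -> KinshipMatrix:
    """Recursive pedigree kinship.

    phi(i,i) = (1 + phi(f_i, m_i)) / 2; for i a non-founder and j not a
    descendant of i, phi(i,j) = (phi(f_i,j) + phi(m_i,j)) / 2; founders are
    mutually unrelated.  Computed family by family in topological order, so
    every pair is resolved once the later-born member is expanded.
    """
    orig_ids = pedigrees.individuals
    pedigrees = pedigrees.complete_parents()
    ids = pedigrees.individuals
    pos = {s: k for k, s in enumerate(ids)}
    blocks = []
    for fid in pedigrees.family_ids:
        order = pedigrees.topological_order(fid)
        tab = pedigrees.members(fid).set_index("iid")
        k = len(order)
        local = {iid: i for i, iid in enumerate(order)}
        phi = np.zeros((k, k))
        for rank, iid in enumerate(order):
            i = local[iid]
            fa, mo = tab.loc[iid, "father"], tab.loc[iid, "mother"]
            if fa == "":
                phi[i, i] = 0.5
            else:
                a, b = local[fa], local[mo]
                phi[i, i] = 0.5 * (1.0 + phi[a, b])
                # earlier members cannot be descendants of i, so the
                # parent-averaging recursion applies to each of them
                for jid in order[:rank]:
                    j = local[jid]
                    val = 0.5 * (phi[a, j] + phi[b, j])
                    phi[i, j] = phi[j, i] = val
        blocks.append((order, phi))
    mat = sp.lil_matrix((len(ids), len(ids)))
    for order, phi in blocks:
        idx = [pos[i] for i in order]
        mat[np.ix_(idx, idx)] = phi
    K = KinshipMatrix(ids, mat.tocsr(), "pedigree")
    return K.subset(orig_ids) if len(orig_ids) != len(ids) else K


def king_robust(genotypes: GenotypeMatrix, pairs=None,
                min_shared: int = 100) -> pd.DataFrame:
    """Within-pair KING-robust kinship estimates.

    For samples i, j over shared non-missing variants::

        phi_hat = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j))

    where N_Aa,Aa counts doubly-heterozygous variants, N_AA,aa opposite
    homozygotes, and N_Aa(.) heterozygote counts on the shared set.  Pairs
    with fewer than ``min_shared`` shared variants get phi = NaN.

    Returns a DataFrame (id1, id2, phi, n_shared); ``pairs`` defaults to all
    unordered pairs.
    """
    ids = genotypes.samples
    D = genotypes.dosage
    if pairs is None:
        pairs = [(ids[a], ids[b]) for a in range(len(ids))
                 for b in range(a + 1, len(ids))]
    pos = {s: k for k, s in enumerate(ids)}
    rows = []
    for i, j in pairs:
        gi, gj = D[pos[i]], D[pos[j]]
        ok = ~np.isnan(gi) & ~np.isnan(gj)
        n_shared = int(ok.sum())
        if n_shared < min_shared:
            rows.append((i, j, np.nan, n_shared))
            continue
        a, b = gi[ok], gj[ok]
        n_hh = int(np.sum((a == 1) & (b == 1)))
        n_opp = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
        n_het_i = int(np.sum(a == 1))
        n_het_j = int(np.sum(b == 1))
        denom = n_het_i + n_het_j
        phi = (n_hh - 2.0 * n_opp) / denom if denom else np.nan
        rows.append((i, j, phi, n_shared))
    return pd.DataFrame(rows, columns=["id1", "id2", "phi", "n_shared"])


def king_degree_threshold(degree: int) -> float:
    """KING kinship boundary below which a pair is beyond ``degree`` relatives."""
    return 2.0 ** -(degree + 1.5)


def sparsify_kinship(K: KinshipMatrix, degree: int | None = 4) -> KinshipMatrix:
    """Zero off-diagonal entries below the degree boundary (0.0221 at degree 4).

    ``degree=None`` is the identity (keep everything); the diagonal is never
    touched.
    """
    if degree is None:
        return KinshipMatrix(K.sample_ids, K.matrix.copy(), K.provenance)
    if degree < 1:
        raise ConfigError("sparsification degree must be >= 1")
    thr = king_degree_threshold(degree)
    mat = K.matrix.tocoo()
    diag = mat.row == mat.col
    keep = diag | (mat.data >= thr)
    out = sp.csr_matrix((mat.data[keep], (mat.row[keep], mat.col[keep])),
                        shape=mat.shape)
    return KinshipMatrix(K.sample_ids, out, K.provenance)


def select_unrelated(K: KinshipMatrix,
                     threshold: float = UNRELATED_KINSHIP_THRESHOLD) -> list[str]:
    """Greedy unrelated subset: repeatedly drop the sample with the most
    over-threshold partners (ties broken by sample-id order) until no pair
    exceeds the threshold."""
    ids = K.sample_ids
    mat = K.matrix.tocoo()
    adj: dict[str, set[str]] = {s: set() for s in ids}
    for i, j, v in zip(mat.row, mat.col, mat.data):
        if i != j and v > threshold:
            adj[ids[i]].add(ids[j])
            adj[ids[j]].add(ids[i])
    alive = set(ids)
    while True:
        worst, worst_deg = None, 0
        for s in sorted(alive):
            deg = len(adj[s] & alive)
            if deg > worst_deg:
                worst, worst_deg = s, deg
        if worst is None:
            break
        alive.discard(worst)
    return [s for s in ids if s in alive]
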