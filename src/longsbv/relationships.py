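"""Pedigree and genomic relationship matrices and the single-step inverse.

Implements the numerator relationship matrix A (tabular method, inbreeding
on the diagonal), its sparse inverse by Henderson's rules with inbreeding,
the VanRaden-style genomic relationship, its scaling to match the pedigree
submatrix of the genotyped animals, blending, and the single-step inverse

    H^-1 = A^-1 + [[0, 0], [0, Omega_w^-1 - A22^-1]]

with Omega_w = (1 - w) Omega* + w A22 (default blend weight w = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .synthetic import PedigreeTable, GenotypeTable

__all__ = [
    "numerator_relationship",
    "a_inverse",
    "submatrix_a22",
    "vanraden_omega",
    "scale_omega",
    "blend_omega",
    "h_inverse",
    "RelationshipSet",
    "build_relationships",
]


def numerator_relationship(ped: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Diagonal entries are 1 + F_i.  Requires the pedigree ordered
    parents-first (validated; a violated ordering implies a cycle or a
    forward reference and is reported).
    """
    ped.validate()
    sire, dam = ped.parent_indices()
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def _mendelian_variances(ped: PedigreeTable, F: np.ndarray) -> np.ndarray:
    sire, dam = ped.parent_indices()
    n = len(ped)
    dvec = np.empty(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            dvec[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            dvec[i] = 0.75 - 0.25 * F[p]
        else:
            dvec[i] = 1.0
    return dvec


def a_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> sp.csc_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Inbreeding coefficients are taken from the pedigree table when present,
    otherwise computed by the tabular method.  Nonzeros involve only
    animal-parent-mate triplets.
    """
    ped.validate()
    if F is None:
        F = ped.table["F"].to_numpy(dtype=float)
        if np.any(np.isnan(F)):
            F = np.diag(numerator_relationship(ped)) - 1.0
    dvec = _mendelian_variances(ped, F)
    alpha = 1.0 / dvec
    sire, dam = ped.parent_indices()
    n = len(ped)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        a = alpha[i]
        add(i, i, a)
        for p in (sire[i], dam[i]):
            if p >= 0:
                add(i, p, -0.5 * a)
                add(p, i, -0.5 * a)
                add(p, p, 0.25 * a)
        if sire[i] >= 0 and dam[i] >= 0:
            add(sire[i], dam[i], 0.25 * a)
            add(dam[i], sire[i], 0.25 * a)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def submatrix_a22(
    A: np.ndarray, pedigree_ids: np.ndarray, genotyped_ids: np.ndarray
) -> np.ndarray:
    """Rows/columns of A restricted to the genotyped animals, order kept."""
    pos = {aid: i for i, aid in enumerate(pedigree_ids)}
    try:
        idx = np.array([pos[g] for g in genotyped_ids], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"genotyped id {exc} not in pedigree") from exc
    return A[np.ix_(idx, idx)]


def vanraden_omega(
    geno: GenotypeTable, freqs: np.ndarray | None = None
) -> np.ndarray:
    """Genomic relationship Omega = Z Z' / (2 sum p(1-p)).

    Dosages are centered by twice the allele frequency (computed from the
    genotyped set itself unless supplied).  Monomorphic SNPs contribute
    nothing; an all-monomorphic panel is an error.
    """
    M = geno.dosages.astype(float)
    if M.shape[0] < 2:
        raise ValueError("need at least two genotyped animals")
    p = geno.allele_frequencies if freqs is None else np.asarray(freqs, float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic: zero VanRaden denominator")
    Z = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (Z @ Z.T) / denom


def _diag_offdiag_means(M: np.ndarray) -> tuple[float, float]:
    n = M.shape[0]
    dmean = float(np.mean(np.diag(M)))
    omean = float((M.sum() - np.trace(M)) / (n * (n - 1))) if n > 1 else 0.0
    return dmean, omean


def scale_omega(Omega: np.ndarray, A22: np.ndarray) -> np.ndarray:
    """Affine rescale Omega* = a + b*Omega matching A22's diag/off-diag means."""
    if Omega.shape != A22.shape:
        raise ValueError("Omega and A22 dimensions differ")
    do, oo = _diag_offdiag_means(Omega)
    da, oa = _diag_offdiag_means(A22)
    if abs(do - oo) < 1e-14:
        raise ValueError("Omega diagonal and off-diagonal means coincide; "
                         "scaling system is singular")
    b = (da - oa) / (do - oo)
    a = da - b * do
    return a + b * Omega


def blend_omega(
    Omega_star: np.ndarray, A22: np.ndarray, w: float = 0.05
) -> np.ndarray:
    """Entrywise convex combination (1-w) Omega* + w A22."""
    if not 0 <= w <= 1:
        raise ValueError("blend weight must lie in [0, 1]")
    if Omega_star.shape != A22.shape:
        raise ValueError("dimension mismatch")
    return (1.0 - w) * Omega_star + w * A22


def h_inverse(
    A_inv: sp.spmatrix,
    A22: np.ndarray,
    Omega_omega: np.ndarray,
    genotyped_positions: np.ndarray,
) -> sp.csc_matrix:
    """Single-step H^-1 over the full pedigree order.

    ``genotyped_positions`` gives the 0-based rows of the genotyped animals
    within the full pedigree.  The correction block
    Omega_w^-1 - A22^-1 is dense and added in place.
    """
    n = A_inv.shape[0]
    g = np.asarray(genotyped_positions, dtype=np.int64)
    if len(g) == 0:
        return sp.csc_matrix(A_inv)
    try:
        Om_inv = np.linalg.inv(Omega_omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "blended genomic relationship is singular; increase the blend weight"
        ) from exc
    A22_inv = np.linalg.inv(A22)
    corr = Om_inv - A22_inv
    corr = 0.5 * (corr + corr.T)
    rows = np.repeat(g, len(g))
    cols = np.tile(g, len(g))
    C = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    H = (sp.csc_matrix(A_inv) + C.tocsc()).tocsc()
    return H


@dataclass
class RelationshipSet:
    """All relationship matrices for one population, with id bookkeeping."""

    pedigree_ids: np.ndarray
    genotyped_ids: np.ndarray
    A: np.ndarray
    A_inv: sp.csc_matrix
    A22: np.ndarray
    Omega: np.ndarray | None
    Omega_star: np.ndarray | None
    Omega_omega: np.ndarray | None
    H_inv: sp.csc_matrix | None
    blend_weight: float

    @property
    def genotyped_positions(self) -> np.ndarray:
        pos = {aid: i for i, aid in enumerate(self.pedigree_ids)}
        return np.array([pos[g] for g in self.genotyped_ids], dtype=np.int64)


def build_relationships(
    ped: PedigreeTable,
    geno: GenotypeTable | None = None,
    blend_weight: float = 0.05,
) -> RelationshipSet:
    """Assemble A, A^-1, A22 and (when genotypes are given) the H^-1 chain."""
    A = numerator_relationship(ped)
    Ainv = a_inverse(ped, F=np.diag(A) - 1.0)
    ids = ped.ids
    if geno is None:
        gids = np.array([], dtype=ids.dtype)
        return RelationshipSet(
            pedigree_ids=ids, genotyped_ids=gids, A=A, A_inv=Ainv,
            A22=np.zeros((0, 0)), Omega=None, Omega_star=None,
            Omega_omega=None, H_inv=None, blend_weight=blend_weight,
        )
    gids = np.asarray(geno.ids)
    A22 = submatrix_a22(A, ids, gids)
    Omega = vanraden_omega(geno)
    Omega_star = scale_omega(Omega, A22)
    Omega_w = blend_omega(Omega_star, A22, blend_weight)
    pos = {aid: i for i, aid in enumerate(ids)}
    gpos = np.array([pos[g] for g in gids], dtype=np.int64)
    Hinv = h_inverse(Ainv, A22, Omega_w, gpos)
    return RelationshipSet(
        pedigree_ids=ids, genotyped_ids=gids, A=A, A_inv=Ainv, A22=A22,
        Omega=Omega, Omega_star=Omega_star, Omega_omega=Omega_w,
        H_inv=Hinv, blend_weight=blend_weight,
    )
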