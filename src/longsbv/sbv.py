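"""Eigen-summarization of the genetic covariance function into SBV.

The genetic covariance matrix over weeks, G = Psi K_a Psi', has rank at
most 3 under a degree-2 random regression.  Its leading eigenvectors L_Gl
define summarized breeding values SBV_l,i = L_Gl' u_i that are genetically
independent across l, and index heritabilities
h2_l = L'GL / L'(G + P + D)L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EigenSummary", "eigen_g", "compute_sbv", "sbv_table",
           "sbv_heritability"]


@dataclass
class EigenSummary:
    """Descending eigenvalues and sign-fixed orthonormal eigenvectors of G."""

    values: np.ndarray    # all eigenvalues, descending
    vectors: np.ndarray   # columns are eigenvectors, same order
    shares: np.ndarray    # values / sum(values)

    def vector(self, l: int) -> np.ndarray:
        """1-based l-th eigenvector."""
        return self.vectors[:, l - 1]

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.values)
        df = pd.DataFrame(
            self.vectors, columns=[f"L{l}" for l in range(1, n + 1)]
        )
        df.loc["eigenvalue"] = self.values
        df.loc["share"] = self.shares
        return df


def eigen_g(G: np.ndarray, atol: float = 1e-10) -> EigenSummary:
    """Eigen-decompose a symmetric PSD covariance matrix.

    Eigenvalues are returned in descending order; each eigenvector's sign
    is fixed so its entry-sum is positive (first nonzero entry positive on
    a tie), making the decomposition deterministic.
    """
    G = np.asarray(G, float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    if np.max(np.abs(G - G.T)) > atol:
        raise ValueError("G is not symmetric within tolerance")
    w, V = np.linalg.eigh(0.5 * (G + G.T))
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    for k in range(V.shape[1]):
        s = V[:, k].sum()
        if abs(s) < atol:
            nz = np.nonzero(np.abs(V[:, k]) > atol)[0]
            s = V[nz[0], k] if len(nz) else 1.0
        if s < 0:
            V[:, k] = -V[:, k]
    w = np.where(np.abs(w) < atol, 0.0, w)
    total = w.sum()
    shares = w / total if total > 0 else np.zeros_like(w)
    return EigenSummary(values=w, vectors=V, shares=shares)


def compute_sbv(u_table: pd.DataFrame, eig: EigenSummary, l: int) -> pd.Series:
    """SBV_l,i = L_Gl' u_i for every animal (rows of ``u_table``)."""
    rank = int(np.sum(eig.values > 0))
    if not 1 <= l <= max(rank, 1):
        raise ValueError(f"SBV index {l} exceeds the rank ({rank}) of G")
    L = eig.vector(l)
    if u_table.shape[1] != len(L):
        raise ValueError("u_table width does not match the eigenvector length")
    vals = u_table.to_numpy(dtype=float) @ L
    return pd.Series(vals, index=u_table.index, name=f"SBV{l}")


def sbv_table(u_table: pd.DataFrame, eig: EigenSummary, n_sbv: int = 3
              ) -> pd.DataFrame:
    """First ``n_sbv`` summarized breeding values per animal."""
    return pd.concat(
        [compute_sbv(u_table, eig, l) for l in range(1, n_sbv + 1)], axis=1
    )


def sbv_heritability(
    G: np.ndarray, P: np.ndarray, D: np.ndarray, L: np.ndarray
) -> float:
    """Index heritability L'GL / L'(G + P + D)L with D the residual diagonal."""
    L = np.asarray(L, float)
    D = np.asarray(D, float)
    Dm = np.diag(D) if D.ndim == 1 else D
    num = float(L @ G @ L)
    den = float(L @ (G + P + Dm) @ L)
    if den <= 0:
        raise ValueError("zero or negative total variance for this index")
    return num / den
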