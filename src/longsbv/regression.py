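"""Degree-2 Legendre random-regression model for longitudinal RFI.

The model for the feed intake of animal ``i`` in week ``j`` is

    FI_ij = x_ij' beta + b1 MBW_ij + b2 ADG_ij + b3 BFT_ij
            + sum_q a_iq phi_q(j) + sum_q b_iq phi_q(j) + e_ij

with genetic coefficients a ~ N(0, A (x) K_a) (or H in the single-step
variant), permanent-environment coefficients b ~ N(0, I (x) K_b) and
heterogeneous weekly residual variances e_ij ~ N(0, D_j).  Estimation is by
Henderson's mixed-model equations with known variance components; weekly
breeding values are u_ij = Psi_j . a_i.

A small dense REML estimator is provided for desk-scale parameter-recovery
checks (balanced complete records, per-week mean fixed effects); variance
components are otherwise treated as known inputs throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

__all__ = [
    "LegendreBasis",
    "legendre_basis",
    "VarianceComponents",
    "covariance_functions",
    "ModelSpec",
    "DesignInfo",
    "build_fixed_design",
    "MMESystem",
    "build_mme",
    "solve_blup",
    "BLUPSolution",
    "predict_weekly_ebv",
    "theoretical_accuracy",
    "estimate_varcomp",
]


# ---------------------------------------------------------------------------
# Legendre basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LegendreBasis:
    """Normalized Legendre polynomial values at standardized test weeks."""

    times: np.ndarray  # original week indices 1..n
    t: np.ndarray      # standardized to [-1, 1]
    Psi: np.ndarray    # (n_times, degree+1)
    degree: int

    def row(self, week: int) -> np.ndarray:
        j = int(np.where(self.times == week)[0][0])
        return self.Psi[j]


def legendre_basis(n_times: int = 10, degree: int = 2) -> LegendreBasis:
    """Normalized Legendre basis phi_q on weeks 1..n_times.

    Weeks are standardized to t = -1 + 2 (j - 1) / (n_times - 1) and
    phi_q(t) = sqrt((2q + 1) / 2) P_q(t), so phi_0 = sqrt(1/2) everywhere.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if n_times < degree + 1:
        raise ValueError("need n_times >= degree + 1 for full column rank")
    times = np.arange(1, n_times + 1)
    t = -1.0 + 2.0 * (times - 1) / (n_times - 1) if n_times > 1 else np.zeros(1)
    V = np.polynomial.legendre.legvander(t, degree)
    norms = np.sqrt((2 * np.arange(degree + 1) + 1) / 2.0)
    return LegendreBasis(times=times, t=t, Psi=V * norms, degree=degree)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Coefficient covariances K_a, K_b and weekly residual variances D."""

    K_a: np.ndarray
    K_b: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        self.K_a = np.asarray(self.K_a, float)
        self.K_b = np.asarray(self.K_b, float)
        self.D = np.asarray(self.D, float)

    def covariance_functions(self, basis: LegendreBasis):
        return covariance_functions(self, basis)


def covariance_functions(
    vc: VarianceComponents, basis: LegendreBasis
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic and permanent-environment covariance functions over weeks.

    G = Psi K_a Psi' and P = Psi K_b Psi', both rank <= degree + 1.
    """
    G = basis.Psi @ vc.K_a @ basis.Psi.T
    P = basis.Psi @ vc.K_b @ basis.Psi.T
    return G, P


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Fixed-effect structure of the longitudinal model.

    The first listed factor keeps all its levels and absorbs the overall
    mean; later factors drop their first level for identifiability.  The
    special factor names ``week_gen`` (week-by-generation combination) and
    ``week`` are derived from the record table.  ``trait_covariates`` enter
    as fixed phenotypic regressions (coefficients estimated jointly) unless
    ``fix_betas`` supplies known values, in which case the response is
    offset instead.
    """

    factors: tuple = ("week_gen", "batch_sex", "herd", "pen")
    covariates: tuple = ("age",)
    trait_covariates: tuple = ("MBW", "ADG", "BFT")
    fix_betas: tuple | None = None


@dataclass
class DesignInfo:
    """Frozen encoding of a fitted fixed-effect design (for reuse)."""

    levels: dict
    covariate_means: dict
    columns: list


def _derived_columns(records: pd.DataFrame, spec: "ModelSpec") -> pd.DataFrame:
    out = records
    if "week_gen" in spec.factors and "week_gen" not in out.columns:
        out = out.copy()
        out["week_gen"] = (
            out["week"].astype(str) + "_" + out["generation"].astype(str)
        )
    return out


def build_fixed_design(
    records: pd.DataFrame, spec: ModelSpec, info: DesignInfo | None = None
) -> tuple[sp.csr_matrix, DesignInfo]:
    """Sparse fixed-effect design matrix for the record table.

    With ``info`` given, the stored level maps and centering constants are
    reused (unseen levels raise).
    """
    recs = _derived_columns(records, spec)
    if "week" in spec.factors and "week" not in recs.columns:
        raise ValueError("records lack a week column")
    n = len(recs)
    blocks = []
    columns: list[str] = []
    levels: dict = {}
    cov_means: dict = {}
    for k, f in enumerate(spec.factors):
        col = recs[f] if f != "week" else recs["week"].astype(str)
        if info is None:
            levs = sorted(pd.unique(col).tolist())
        else:
            levs = info.levels[f]
            unseen = set(col) - set(levs)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} for factor {f}")
        levels[f] = levs
        used = levs if k == 0 else levs[1:]
        lut = {lv: i for i, lv in enumerate(used)}
        codes = np.array([lut.get(v, -1) for v in col], dtype=np.int64)
        keep = codes >= 0
        B = sp.coo_matrix(
            (np.ones(keep.sum()), (np.where(keep)[0], codes[keep])),
            shape=(n, len(used)),
        )
        blocks.append(B)
        columns.extend(f"{f}={lv}" for lv in used)
    for c in list(spec.covariates) + (
        list(spec.trait_covariates) if spec.fix_betas is None else []
    ):
        vals = recs[c].to_numpy(dtype=float)
        mu = float(vals.mean()) if info is None else info.covariate_means[c]
        cov_means[c] = mu
        blocks.append(sp.coo_matrix((vals - mu).reshape(-1, 1)))
        columns.append(f"beta_{c}" if c in spec.trait_covariates else c)
    if blocks:
        X = sp.hstack(blocks).tocsr()
    else:
        X = sp.csr_matrix((n, 0))
    if info is None:
        info = DesignInfo(levels=levels, covariate_means=cov_means, columns=columns)
    return X, info


def fixed_part_prediction(
    records: pd.DataFrame, spec: ModelSpec, info: DesignInfo, beta: pd.Series
) -> np.ndarray:
    """x_ij' beta-hat (including trait regressions) for each record row."""
    X, _ = build_fixed_design(records, spec, info)
    b = beta.reindex(info.columns).to_numpy(dtype=float)
    pred = X @ b
    if spec.fix_betas is not None:
        recs = records
        for bv, c in zip(spec.fix_betas, spec.trait_covariates):
            pred = pred + bv * recs[c].to_numpy(dtype=float)
    return pred


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

@dataclass
class MMESystem:
    """Assembled Henderson system with its equation index map."""

    lhs: sp.csc_matrix
    rhs: np.ndarray
    n_fixed: int
    ped_ids: np.ndarray
    phen_ids: np.ndarray
    design_info: DesignInfo
    spec: ModelSpec
    basis: LegendreBasis
    vc: VarianceComponents
    _lu: object = field(default=None, repr=False)

    @property
    def dimension(self) -> int:
        return self.lhs.shape[0]

    def genetic_slice(self, animal_id) -> slice:
        q = self.basis.degree + 1
        pos = int(np.where(self.ped_ids == animal_id)[0][0])
        start = self.n_fixed + q * pos
        return slice(start, start + q)

    def factorize(self):
        if self._lu is None:
            self._lu = spla.splu(self.lhs)
        return self._lu


def _safe_inv(K: np.ndarray, name: str) -> np.ndarray:
    try:
        cond = np.linalg.cond(K)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"{name} is (near-)singular; add a small ridge eps*I before fitting"
        )
    return np.linalg.inv(K)


def build_mme(
    phen: pd.DataFrame,
    spec: ModelSpec,
    basis: LegendreBasis,
    vc: VarianceComponents,
    rel_inv: sp.spmatrix,
    ped_ids: np.ndarray,
) -> MMESystem:
    """Assemble the sparse mixed-model equations.

    ``rel_inv`` is A^-1 or H^-1 over ``ped_ids`` (pedigree order); genetic
    coefficient equations exist for every pedigree animal,
    permanent-environment equations for every animal in the record table.
    Missing records contribute nothing to the data part.
    """
    Ka_inv = _safe_inv(vc.K_a, "K_a")
    has_pe = not np.allclose(vc.K_b, 0.0)
    Kb_inv = _safe_inv(vc.K_b, "K_b") if has_pe else None
    recs = phen.loc[~phen["missing"]].reset_index(drop=True)
    X, info = build_fixed_design(recs, spec, None)
    nf = X.shape[1]
    ped_ids = np.asarray(ped_ids)
    phen_ids = (
        np.asarray(pd.unique(phen["animal"]))
        if has_pe else np.array([], dtype=object)
    )
    ped_pos = {a: i for i, a in enumerate(ped_ids)}
    phen_pos = {a: i for i, a in enumerate(phen_ids)}
    missing_ped = [a for a in pd.unique(phen["animal"]) if a not in ped_pos]
    if missing_ped:
        raise ValueError(f"phenotyped animals not in pedigree: {missing_ped[:5]}")
    n_ped, n_phen = len(ped_ids), len(phen_ids)
    R = len(recs)
    week = recs["week"].to_numpy(dtype=np.int64)
    jidx = week - 1
    Psi_rows = basis.Psi[jidx]  # (R, 3)
    arow = np.array([ped_pos[a] for a in recs["animal"]], dtype=np.int64)
    q = basis.degree + 1
    rr = np.repeat(np.arange(R), q)
    Za = sp.coo_matrix(
        (Psi_rows.ravel(), (rr, (q * arow[:, None] + np.arange(q)).ravel())),
        shape=(R, q * n_ped),
    )
    parts = [X, Za]
    if has_pe:
        brow = np.array([phen_pos[a] for a in recs["animal"]], dtype=np.int64)
        Zb = sp.coo_matrix(
            (Psi_rows.ravel(), (rr, (q * brow[:, None] + np.arange(q)).ravel())),
            shape=(R, q * n_phen),
        )
        parts.append(Zb)
    T = sp.hstack(parts).tocsr()
    y = recs["FI"].to_numpy(dtype=float)
    if spec.fix_betas is not None:
        for bv, c in zip(spec.fix_betas, spec.trait_covariates):
            y = y - bv * recs[c].to_numpy(dtype=float)
    w = 1.0 / vc.D[jidx]
    Tw = T.multiply(w.reshape(-1, 1)).tocsr()
    lhs = (T.T @ Tw).tocsc()
    rhs = np.asarray(Tw.T @ y).ravel()
    prior_blocks = [
        sp.csc_matrix((nf, nf)),
        sp.kron(sp.csc_matrix(rel_inv), Ka_inv, format="csc"),
    ]
    if has_pe:
        prior_blocks.append(
            sp.kron(sp.identity(n_phen, format="csc"), Kb_inv, format="csc")
        )
    prior = sp.block_diag(prior_blocks, format="csc")
    lhs = (lhs + prior).tocsc()
    return MMESystem(
        lhs=lhs, rhs=rhs, n_fixed=nf, ped_ids=ped_ids, phen_ids=phen_ids,
        design_info=info, spec=spec, basis=basis, vc=vc,
    )


@dataclass
class BLUPSolution:
    """Unpacked solution of the mixed-model equations."""

    fixed: pd.Series
    a: pd.DataFrame  # genetic coefficients, index = pedigree ids
    b: pd.DataFrame  # permanent-environment coefficients, index = record ids
    spec: ModelSpec
    design_info: DesignInfo
    basis: LegendreBasis
    vc: VarianceComponents
    relative_residual: float


def solve_blup(mme: MMESystem, rtol: float = 1e-8) -> BLUPSolution:
    """Direct sparse solve of the MME with a relative-residual check."""
    lu = mme.factorize()
    x = lu.solve(mme.rhs)
    denom = max(np.linalg.norm(mme.rhs), 1.0)
    rel = float(np.linalg.norm(mme.lhs @ x - mme.rhs) / denom)
    if not np.isfinite(rel) or rel > rtol:
        raise RuntimeError(
            f"MME solve failed (relative residual {rel:.2e}); the system is "
            "likely singular - check for confounded fixed-effect levels"
        )
    nf = mme.n_fixed
    q = mme.basis.degree + 1
    n_ped, n_phen = len(mme.ped_ids), len(mme.phen_ids)
    beta = pd.Series(x[:nf], index=mme.design_info.columns)
    a = pd.DataFrame(
        x[nf:nf + q * n_ped].reshape(n_ped, q),
        index=mme.ped_ids, columns=[f"a{i}" for i in range(q)],
    )
    b = pd.DataFrame(
        x[nf + q * n_ped:nf + q * n_ped + q * n_phen].reshape(n_phen, q),
        index=mme.phen_ids, columns=[f"b{i}" for i in range(q)],
    )
    return BLUPSolution(
        fixed=beta, a=a, b=b, spec=mme.spec, design_info=mme.design_info,
        basis=mme.basis, vc=mme.vc, relative_residual=rel,
    )


def predict_weekly_ebv(sol: BLUPSolution, basis: LegendreBasis | None = None
                       ) -> pd.DataFrame:
    """Weekly breeding values u_ij = Psi_j . a_i for every pedigree animal."""
    basis = basis or sol.basis
    U = sol.a.to_numpy() @ basis.Psi.T
    return pd.DataFrame(U, index=sol.a.index, columns=basis.times)


def theoretical_accuracy(
    mme: MMESystem, L: np.ndarray, animal_ids: Sequence
) -> pd.Series:
    """Model-based accuracy of L'u_i from the inverse coefficient matrix.

    acc_i = sqrt(1 - PEV(L'u_i) / (L'GL)); PEV values exceeding the prior
    variance (numerical noise for animals with no information) are clamped
    to accuracy 0 with a warning.
    """
    L = np.asarray(L, float)
    lu = mme.factorize()
    G, _ = covariance_functions(mme.vc, mme.basis)
    lgl = float(L @ G @ L)
    c = mme.basis.Psi.T @ L
    out = {}
    clamped = 0
    q = mme.basis.degree + 1
    for aid in animal_ids:
        sl = mme.genetic_slice(aid)
        E = np.zeros((mme.dimension, q))
        E[sl, :] = np.eye(q)
        C = lu.solve(E)[sl, :]
        pev = float(c @ C @ c)
        ratio = 1.0 - pev / lgl
        if ratio < 0:
            clamped += 1
            ratio = 0.0
        out[aid] = float(np.sqrt(ratio))
    if clamped:
        warnings.warn(
            f"{clamped} animal(s) had PEV above the prior variance; "
            "accuracy clamped to 0"
        )
    return pd.Series(out)


# ---------------------------------------------------------------------------
# desk-scale REML
# ---------------------------------------------------------------------------

def _tri_from_flat(v: np.ndarray) -> np.ndarray:
    Lm = np.zeros((3, 3))
    Lm[np.tril_indices(3)] = v
    return Lm


def estimate_varcomp(
    phen: pd.DataFrame,
    basis: LegendreBasis,
    rel_inv: sp.spmatrix,
    ped_ids: np.ndarray,
    init: VarianceComponents,
    response: str = "FI",
    max_animals: int = 500,
    maxiter: int = 300,
) -> tuple[VarianceComponents, dict]:
    """REML for (K_a, K_b, D) on balanced complete records.

    Maximizes the restricted log-likelihood over Cholesky-parameterized
    K_a, K_b and log-D, with per-week mean fixed effects.  Intended for
    parameter-recovery checks: only animals with a complete set of weekly
    records are used, and the animal count is capped (dense relationship
    algebra).  The trick is to rotate animals by the eigenvectors of the
    relationship matrix, which makes records independent across animals and
    the likelihood a sum of 10-dimensional Gaussian terms.
    """
    nw = len(basis.times)
    recs = phen.loc[~phen["missing"], ["animal", "week", response]]
    wide = recs.pivot_table(index="animal", columns="week", values=response)
    wide = wide.dropna()
    if wide.shape[1] != nw:
        raise ValueError("no animal has a complete set of weekly records")
    if len(wide) > max_animals:
        raise ValueError(
            f"{len(wide)} complete animals exceed the REML size guard "
            f"({max_animals}); subsample first"
        )
    ped_ids = np.asarray(ped_ids)
    pos = {a: i for i, a in enumerate(ped_ids)}
    idx = np.array([pos[a] for a in wide.index], dtype=np.int64)
    A_full = np.linalg.inv(np.asarray(rel_inv.todense()))
    A_sub = A_full[np.ix_(idx, idx)]
    lam, U = np.linalg.eigh(A_sub)
    Y = U.T @ wide.to_numpy(dtype=float)     # rotated records
    cvec = U.T @ np.ones(len(wide))          # rotated per-week-mean design
    Psi = basis.Psi

    def unpack(theta):
        La = _tri_from_flat(theta[:6])
        Lb = _tri_from_flat(theta[6:12])
        D = np.exp(theta[12:12 + nw])
        return La @ La.T, Lb @ Lb.T, D

    def neg_reml(theta):
        try:
            Ka, Kb, D = unpack(theta)
            Ga = Psi @ Ka @ Psi.T
            Sb = Psi @ Kb @ Psi.T + np.diag(D)
            V = lam[:, None, None] * Ga + Sb
            sign, logdet = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return 1e10
            Vinv = np.linalg.inv(V)
            Viy = np.einsum("nij,nj->ni", Vinv, Y)
            quad = float(np.einsum("ni,ni->", Y, Viy))
            XtViX = np.einsum("n,nij->ij", cvec**2, Vinv)
            XtViy = np.einsum("n,nij,nj->i", cvec, Vinv, Y)
            s2, ld2 = np.linalg.slogdet(XtViX)
            if s2 <= 0:
                return 1e10
            adj = float(XtViy @ np.linalg.solve(XtViX, XtViy))
            val = 0.5 * (float(logdet.sum()) + quad + ld2 - adj)
            return val if np.isfinite(val) else 1e10
        except np.linalg.LinAlgError:
            return 1e10

    theta0 = np.concatenate(
        [
            np.linalg.cholesky(init.K_a + 1e-8 * np.eye(3))[np.tril_indices(3)],
            np.linalg.cholesky(init.K_b + 1e-8 * np.eye(3))[np.tril_indices(3)],
            np.log(np.maximum(init.D, 1e-8)),
        ]
    )
    res = minimize(neg_reml, theta0, method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxfun": 5 * maxiter})
    Ka, Kb, D = unpack(res.x)
    report = {
        "converged": bool(res.success),
        "n_evaluations": int(res.nfev),
        "restricted_loglik": -float(res.fun),
        "message": str(res.message),
        "n_animals": int(len(wide)),
    }
    if not res.success:
        warnings.warn(f"REML did not report convergence: {res.message}")
    return VarianceComponents(K_a=Ka, K_b=Kb, D=D), report
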