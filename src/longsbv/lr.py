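"""LR-method validation of SBV predictions over generation cut-offs.

Predictions from a partial dataset (fewer phenotyped generations) are
compared with predictions from a larger one on a focal group of genotyped,
unphenotyped dams:

* standardized bias   delta_mu_wp = (mean(p) - mean(w)) / L'GL
* dispersion slope    b_wp        = cov(p, w) / var(p)
* accuracy ratio      rho_wp      = cor(p, w)

Cut-off ``i`` keeps the phenotypes of the first ``2 + i`` generations; the
focal group of cut ``i`` consists of the genotyped dams of the first
generation without phenotypes in that partial dataset.  Statistics are
computed separately per line and per SBV index, for pedigree-only (A) and
single-step (H) fits, under three comparison layouts: (1) next cut as the
reference, (2) the full dataset as the reference, (3) pedigree-only versus
single-step predictions from the same dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PedigreeTable

__all__ = [
    "CutoffSpec",
    "FocalGroup",
    "make_cutoffs",
    "focal_group",
    "lr_bias",
    "lr_dispersion",
    "lr_accuracy_ratio",
    "lr_reliability",
    "run_scenarios",
]

SMALL_GROUP = 10


@dataclass
class CutoffSpec:
    """A partial dataset: phenotypes restricted to early generations."""

    cut: int
    last_phenotyped_generation: int
    phenotypes: pd.DataFrame  # records of later generations removed


@dataclass
class FocalGroup:
    """Genotyped, unphenotyped dams of the first phenotype-less generation."""

    cut: int
    ids: np.ndarray
    lines: pd.Series  # line label per focal id


def make_cutoffs(
    phen: pd.DataFrame, ped: PedigreeTable, cuts: int = 5
) -> list[CutoffSpec]:
    """Partial phenotype tables for cut-offs 1..cuts.

    Cut ``i`` keeps records of generations 0..(i + 1), i.e. the first
    ``2 + i`` generations; the pedigree is never reduced.
    """
    gens = np.sort(phen["generation"].unique())
    max_gen = int(ped.table["generation"].max())
    out = []
    for i in range(1, cuts + 1):
        last = i + 1
        if last > max_gen:
            raise ValueError(
                f"cut-{i} needs generation {last} but the pedigree stops "
                f"at generation {max_gen}"
            )
        part = phen.loc[phen["generation"] <= last].reset_index(drop=True)
        part.attrs = dict(phen.attrs)
        out.append(
            CutoffSpec(cut=i, last_phenotyped_generation=last, phenotypes=part)
        )
    return out


def focal_group(
    ped: PedigreeTable,
    cutoff: CutoffSpec,
    genotyped_ids: np.ndarray,
    whole_phen: pd.DataFrame,
) -> FocalGroup:
    """Dams of the first unphenotyped generation, restricted to genotyped.

    Sires are excluded (their progeny counts differ systematically between
    partial and whole data); any dam with own phenotypes is excluded.
    """
    tab = ped.table
    first_missing = cutoff.last_phenotyped_generation + 1
    progeny = tab[(tab["generation"] == first_missing) & tab["phenotyped"]]
    dams = np.unique(progeny["dam"].to_numpy())
    dams = dams[dams > 0]
    phen_ids = set(whole_phen["animal"].unique())
    gset = set(np.asarray(genotyped_ids).tolist())
    sex = tab.set_index("id")["sex"]
    keep = [
        d for d in dams
        if d in gset and d not in phen_ids and sex.get(d) == "F"
    ]
    ids = np.array(keep)
    if len(ids) == 0:
        warnings.warn(f"empty focal group for cut-{cutoff.cut}")
    elif len(ids) < SMALL_GROUP:
        warnings.warn(
            f"focal group for cut-{cutoff.cut} has only {len(ids)} dams; "
            "LR statistics will be noisy"
        )
    lines = tab.set_index("id").loc[ids, "line"] if len(ids) else pd.Series(dtype=object)
    return FocalGroup(cut=cutoff.cut, ids=ids, lines=lines)


def _paired(p, w):
    p = np.asarray(p, float)
    w = np.asarray(w, float)
    if p.shape != w.shape:
        raise ValueError("partial and whole prediction vectors differ in length")
    return p, w


def lr_bias(esbv_p, esbv_w, sbv_variance: float) -> float:
    """(mean(p) - mean(w)) / L'GL; 0 when the partial evaluation is unbiased."""
    p, w = _paired(esbv_p, esbv_w)
    if len(p) < 2:
        raise ValueError("need at least two focal animals")
    if sbv_variance <= 0:
        raise ValueError("SBV variance must be positive")
    return float((p.mean() - w.mean()) / sbv_variance)


def lr_dispersion(esbv_p, esbv_w) -> float:
    """cov(p, w) / var(p); 1 when there is no over-/under-dispersion."""
    p, w = _paired(esbv_p, esbv_w)
    vp = np.var(p, ddof=1)
    if vp <= 0:
        raise ValueError("zero variance in partial predictions")
    return float(np.cov(p, w, ddof=1)[0, 1] / vp)


def lr_accuracy_ratio(esbv_p, esbv_w) -> float:
    """cor(p, w): the ratio of partial to whole prediction accuracy."""
    p, w = _paired(esbv_p, esbv_w)
    vp, vw = np.var(p, ddof=1), np.var(w, ddof=1)
    if vp <= 0 or vw <= 0:
        raise ValueError("zero variance in one of the prediction vectors")
    return float(np.cov(p, w, ddof=1)[0, 1] / np.sqrt(vp * vw))


def lr_reliability(esbv_p, esbv_w, sigma2_ustar: float) -> float:
    """cov(p, w) / sigma2_u*: selected reliability at the time of selection."""
    if sigma2_ustar is None or sigma2_ustar <= 0:
        raise ValueError("a positive group genetic variance sigma2_u* is required")
    p, w = _paired(esbv_p, esbv_w)
    r = float(np.cov(p, w, ddof=1)[0, 1] / sigma2_ustar)
    if r > 1:
        warnings.warn(f"reliability {r:.3f} exceeds 1; reporting as computed")
    return r


def run_scenarios(
    sbv_tables: dict,
    focal_groups: list[FocalGroup],
    eigenvalues: np.ndarray,
    n_cuts: int = 5,
    n_sbv: int = 3,
    relmats: tuple = ("A", "H"),
    sigma2_ustar: float | None = None,
) -> pd.DataFrame:
    """The full LR comparison grid.

    ``sbv_tables`` maps ``(relmat, dataset)`` to a per-animal SBV table
    (columns SBV1..SBVn), where ``dataset`` is a cut index 1..n_cuts or
    ``"full"``.  Comparison (1) uses the next cut as reference (the full
    data for the last cut), comparison (2) the full data (cuts 1..n_cuts-1,
    the last being identical to comparison (1)), and comparison (3) pits
    pedigree-only against single-step predictions from the same dataset
    (a: each cut, b: full data).  Statistics are computed per line and per
    SBV index; rows with an unavailable fit are skipped.
    """
    groups = {g.cut: g for g in focal_groups}
    use_h = "H" in relmats and any(k[0] == "H" for k in sbv_tables)
    rows = []

    def dataset(i):
        return "full" if i == n_cuts + 1 else i

    def emit(comparison, cut, relmat_label, key_p, key_w):
        if key_p not in sbv_tables or key_w not in sbv_tables:
            warnings.warn(f"missing fit for scenario {comparison}/cut-{cut}; skipped")
            return
        grp = groups.get(cut)
        if grp is None or len(grp.ids) == 0:
            return
        tp, tw = sbv_tables[key_p], sbv_tables[key_w]
        for line in sorted(grp.lines.unique()):
            ids = grp.ids[(grp.lines == line).to_numpy()]
            if len(ids) < 2:
                continue
            for l in range(1, n_sbv + 1):
                p = tp.loc[ids, f"SBV{l}"].to_numpy()
                w = tw.loc[ids, f"SBV{l}"].to_numpy()
                rec = {
                    "line": line, "sbv": l, "relmat": relmat_label,
                    "cut": cut, "comparison": comparison, "n_focal": len(ids),
                    "delta_mu": lr_bias(p, w, float(eigenvalues[l - 1])),
                    "b": lr_dispersion(p, w),
                    "rho": lr_accuracy_ratio(p, w),
                }
                rec["reliability"] = (
                    lr_reliability(p, w, sigma2_ustar)
                    if sigma2_ustar is not None else np.nan
                )
                rows.append(rec)

    for i in range(1, n_cuts + 1):
        emit("1a", i, "A", ("A", i), ("A", dataset(i + 1)))
        if use_h:
            emit("1b", i, "H", ("H", i), ("H", dataset(i + 1)))
    for i in range(1, n_cuts):
        emit("2a", i, "A", ("A", i), ("A", "full"))
        if use_h:
            emit("2b", i, "H", ("H", i), ("H", "full"))
    if use_h:
        for i in range(1, n_cuts + 1):
            emit("3a", i, "AvsH", ("A", i), ("H", i))
            emit("3b", i, "AvsH", ("A", "full"), ("H", "full"))
    return pd.DataFrame(rows)
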