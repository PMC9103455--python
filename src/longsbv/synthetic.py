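"""Synthetic divergent-selection experiment generator.

Generates, from a single :class:`~longsbv.config.SimulationConfig`:

* a multi-generation two-line pedigree with replacement parents selected
  either at random or by truncation on the first true summarized breeding
  value (a desk-scale stand-in for the selection on RFI EBV practised in
  divergent-selection experiments);
* true random-regression genetic coefficients with covariance ``A (x) K_a``
  by construction (parent average plus Mendelian sampling);
* SNP genotypes by gene dropping, returned for the parents of phenotyped
  animals only (no genotyped animal has own phenotypes);
* weekly feed-intake records built from the degree-2 Legendre
  random-regression model with animal-specific production-trait trajectories
  (metabolic body weight, average daily gain, backfat) entering as fixed
  phenotypic regressions;
* missing weekly records concentrated in a configurable subset of animals.

Every operation is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .regression import legendre_basis

__all__ = [
    "PedigreeTable",
    "GenotypeTable",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_genotypes",
    "simulate_phenotypes",
    "apply_missingness",
    "simulate_population",
    "SimulatedData",
]

TRAITS = ("FI", "MBW", "ADG", "BFT")


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), stream)))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class PedigreeTable:
    """Ordered pedigree (parents precede offspring).

    ``table`` columns: id, sire, dam (0 = unknown), sex ('M'/'F'),
    generation, line, litter (mating index, -1 for founders), phenotyped
    (bool) and inbreeding coefficient F (computed by the tabular method).
    ``coefficients`` holds the true genetic random-regression coefficients
    (one 3-vector per animal, pedigree order) when they were co-generated
    with the pedigree (required when selection acts on them).
    """

    table: pd.DataFrame
    coefficients: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def founder_mask(self) -> np.ndarray:
        return ((self.table["sire"] == 0) & (self.table["dam"] == 0)).to_numpy()

    def phenotyped_ids(self) -> np.ndarray:
        return self.table.loc[self.table["phenotyped"], "id"].to_numpy()

    def genotyped_ids(self) -> np.ndarray:
        """Parents of phenotyped animals (none of which have own phenotypes)."""
        phen = self.table[self.table["phenotyped"]]
        parents = np.union1d(phen["sire"].to_numpy(), phen["dam"].to_numpy())
        return parents[parents > 0]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based positions of sire and dam per animal; -1 when unknown."""
        pos = {aid: i for i, aid in enumerate(self.ids)}
        sire = np.array([pos.get(s, -1) for s in self.table["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) for d in self.table["dam"]], dtype=np.int64)
        return sire, dam

    def validate(self) -> None:
        pos = {aid: i for i, aid in enumerate(self.ids)}
        gen = self.table["generation"].to_numpy()
        for col in ("sire", "dam"):
            for i, p in enumerate(self.table[col]):
                if p == 0:
                    continue
                j = pos.get(p)
                if j is None:
                    raise ValueError(f"unknown {col} id {p}")
                if j >= i:
                    raise ValueError(f"{col} {p} does not precede offspring")
                if gen[j] >= gen[i]:
                    raise ValueError(
                        f"{col} {p} (gen {gen[j]}) not from a prior generation"
                    )

    # -- round-trip ----------------------------------------------------
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PedigreeTable":
        tab = pd.read_csv(path)
        for col, default in (("litter", -1), ("phenotyped", False)):
            if col not in tab.columns:
                tab[col] = default
        if "F" not in tab.columns:
            tab["F"] = np.nan
        return cls(table=tab)


def _extend_A(A: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Append a batch of animals (parents all in A, or both unknown) to A."""
    n_old = A.shape[0]
    m = len(sire)
    known = sire >= 0  # batches are homogeneous: both parents known or none
    P = np.zeros((m, n_old))
    C = np.eye(m)
    if known.any():
        s, d = sire[known], dam[known]
        P[known] = 0.5 * (A[s, :] + A[d, :])
        cross = 0.25 * (
            A[np.ix_(s, s)] + A[np.ix_(s, d)] + A[np.ix_(d, s)] + A[np.ix_(d, d)]
        )
        diag = 1.0 + 0.5 * A[s, d]
        idx = np.where(known)[0]
        C[np.ix_(idx, idx)] = cross
        C[idx, idx] = diag
    out = np.empty((n_old + m, n_old + m))
    out[:n_old, :n_old] = A
    out[:n_old, n_old:] = P.T
    out[n_old:, :n_old] = P
    out[n_old:, n_old:] = C
    return out


def simulate_pedigree(config: SimulationConfig) -> PedigreeTable:
    """Build the two-line pedigree, selecting replacement parents per line.

    When ``selection_mode == 'divergent_on_sbv1'`` true genetic coefficients
    are co-generated (gene dropping through the pedigree as it grows) and
    replacement sires are truncation-selected on the first true summarized
    breeding value, downward in the first (low) line and upward in the
    second; replacement dams are sampled at random within litter (one female
    per litter), as in within-family dam replacement.  The coefficients used
    for selection are returned on the table so downstream phenotypes are
    consistent with the realized selection.
    """
    cfg = config
    rng_ped = _rng(cfg.seed, 0)
    rng_bv = _rng(cfg.seed, 1)
    chol_Ka = np.linalg.cholesky(cfg.K_a + 1e-12 * np.eye(3))
    basis = legendre_basis(cfg.n_weeks, 2)
    G = basis.Psi @ cfg.K_a @ basis.Psi.T
    evals, evecs = np.linalg.eigh(G)
    L1 = evecs[:, -1]
    if L1.sum() < 0:
        L1 = -L1
    w_sel = basis.Psi.T @ L1  # SBV1 = w_sel . a_i

    select = cfg.selection_mode == "divergent_on_sbv1"
    rows: list[tuple] = []
    A = np.zeros((0, 0))
    coeffs = np.zeros((0, 3))
    next_id = 1
    litter_counter = 0
    # per line: current breeding animals (row indices into the tables)
    cur_sires: dict[str, list[int]] = {}
    cur_dams: dict[str, list[int]] = {}

    def add_batch(sire_idx, dam_idx, sexes, gen, line, litters, phen_flags):
        nonlocal A, coeffs, next_id
        sire_idx = np.asarray(sire_idx, dtype=np.int64)
        dam_idx = np.asarray(dam_idx, dtype=np.int64)
        m = len(sire_idx)
        F_parents = np.diag(A) - 1.0 if A.size else np.zeros(0)
        A = _extend_A(A, sire_idx, dam_idx)
        new = np.empty((m, 3))
        known = sire_idx >= 0
        z = rng_bv.standard_normal((m, 3))
        if (~known).any():
            new[~known] = z[~known] @ chol_Ka.T
        if known.any():
            s, d = sire_idx[known], dam_idx[known]
            msv = 0.5 - 0.25 * (F_parents[s] + F_parents[d])
            pa = 0.5 * (coeffs[s] + coeffs[d])
            new[known] = pa + np.sqrt(msv)[:, None] * (z[known] @ chol_Ka.T)
        coeffs = np.vstack([coeffs, new])
        start = len(rows)
        for k in range(m):
            sid = rows[sire_idx[k]][0] if sire_idx[k] >= 0 else 0
            did = rows[dam_idx[k]][0] if dam_idx[k] >= 0 else 0
            rows.append(
                (next_id, sid, did, sexes[k], gen, line, litters[k], phen_flags[k])
            )
            next_id += 1
        return list(range(start, start + m))

    # founders (generation 0): unphenotyped breeding animals of each line
    for line in cfg.lines:
        n_f = cfg.n_sires_per_gen + cfg.n_dams_per_gen
        sexes = ["M"] * cfg.n_sires_per_gen + ["F"] * cfg.n_dams_per_gen
        idx = add_batch(
            [-1] * n_f, [-1] * n_f, sexes, 0, line, [-1] * n_f, [False] * n_f
        )
        cur_sires[line] = idx[: cfg.n_sires_per_gen]
        cur_dams[line] = idx[cfg.n_sires_per_gen:]

    for gen in range(1, cfg.n_generations):
        phen_gen = gen in cfg.phenotyped_generations
        last = gen == cfg.n_generations - 1
        for line in cfg.lines:
            sires, dams = cur_sires[line], cur_dams[line]
            if not sires or not dams:
                raise ValueError(
                    f"no parents available for line {line} generation {gen}"
                )
            dam_order = rng_ped.permutation(len(dams))
            litters: list[list[int]] = []
            sexes_all: list[str] = []
            sire_col: list[int] = []
            dam_col: list[int] = []
            litter_col: list[int] = []
            litter_ids: list[int] = []
            for k, dpos in enumerate(dam_order):
                d_idx = dams[dpos]
                # round-robin sire allocation, avoiding full-sib matings
                for shift in range(len(sires)):
                    s_idx = sires[(k + shift) % len(sires)]
                    same_litter = (
                        rows[s_idx][6] >= 0 and rows[s_idx][6] == rows[d_idx][6]
                    )
                    if not same_litter:
                        break
                m = cfg.progeny_per_mating
                n_male = m // 2
                sx = np.array(["M"] * n_male + ["F"] * (m - n_male))
                rng_ped.shuffle(sx)
                sexes_all.extend(sx.tolist())
                sire_col.extend([s_idx] * m)
                dam_col.extend([d_idx] * m)
                litter_col.extend([litter_counter] * m)
                litter_ids.append(litter_counter)
                litter_counter += 1
            idx = add_batch(
                sire_col,
                dam_col,
                sexes_all,
                gen,
                line,
                litter_col,
                [phen_gen] * len(sire_col),
            )
            # group new rows per litter
            litters = [
                [idx[j] for j in range(len(idx)) if litter_col[j] == lid]
                for lid in litter_ids
            ]
            if last:
                continue
            # replacement dams: one female per litter
            new_dams: list[int] = []
            for lit in litters:
                females = [i for i in lit if rows[i][3] == "F"]
                if females:
                    new_dams.append(int(rng_ped.choice(females)))
            if len(new_dams) < cfg.n_dams_per_gen:
                pool = [
                    i for lit in litters for i in lit
                    if rows[i][3] == "F" and i not in new_dams
                ]
                extra = rng_ped.choice(
                    pool, size=cfg.n_dams_per_gen - len(new_dams), replace=False
                )
                new_dams.extend(int(e) for e in extra)
            new_dams = new_dams[: cfg.n_dams_per_gen]
            # replacement sires
            males = [i for lit in litters for i in lit if rows[i][3] == "M"]
            if select:
                sbv1 = coeffs[males] @ w_sel
                order = np.argsort(sbv1)
                if line == cfg.lines[1]:  # high line: largest SBV1
                    order = order[::-1]
                new_sires = [males[o] for o in order[: cfg.n_sires_per_gen]]
            else:
                new_sires = [
                    int(i)
                    for i in rng_ped.choice(
                        males, size=cfg.n_sires_per_gen, replace=False
                    )
                ]
            # selected replacements do not get phenotyped
            for i in new_sires + list(new_dams):
                rows[i] = rows[i][:7] + (False,)
            cur_sires[line] = new_sires
            cur_dams[line] = list(new_dams)

    tab = pd.DataFrame(
        rows,
        columns=[
            "id", "sire", "dam", "sex", "generation", "line", "litter", "phenotyped"
        ],
    )
    tab["F"] = np.diag(A) - 1.0
    ped = PedigreeTable(table=tab, coefficients=coeffs if select else None)
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def simulate_breeding_values(
    ped: PedigreeTable, K_a: np.ndarray, seed: int
) -> np.ndarray:
    """Gene-drop genetic random-regression coefficients down the pedigree.

    Founders draw from N(0, K_a); non-founders take the parent average plus
    a Mendelian-sampling deviation with covariance
    ``(1/2 - (F_s + F_d)/4) K_a`` (both parents known) or
    ``(3/4 - F_known/4) K_a`` (one parent known).  The stacked coefficients
    then have covariance ``A (x) K_a`` by construction.
    """
    K_a = np.asarray(K_a, dtype=float)
    rng = _rng(seed, 11)
    chol = np.linalg.cholesky(K_a + 1e-12 * np.eye(3))
    sire, dam = ped.parent_indices()
    F = ped.table["F"].to_numpy()
    n = len(ped)
    a = np.empty((n, 3))
    z = rng.standard_normal((n, 3)) @ chol.T
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            a[i] = z[i]
        elif s >= 0 and d >= 0:
            msv = 0.5 - 0.25 * (F[s] + F[d])
            a[i] = 0.5 * (a[s] + a[d]) + np.sqrt(msv) * z[i]
        else:
            p = s if s >= 0 else d
            msv = 0.75 - 0.25 * F[p]
            a[i] = 0.5 * a[p] + np.sqrt(msv) * z[i]
    if np.allclose(K_a, 0):
        a[:] = 0.0
    return a


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Allele dosages (0/1/2) for a subset of pedigree animals."""

    ids: np.ndarray
    snp_ids: list[str]
    dosages: np.ndarray  # (n_animals, n_snps) int8
    field_meta: dict = field(default_factory=dict)

    @property
    def allele_frequencies(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.ids, columns=self.snp_ids)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            ids=df.index.to_numpy(),
            snp_ids=list(df.columns),
            dosages=df.to_numpy(dtype=np.int8),
        )


def simulate_genotypes(
    ped: PedigreeTable,
    config: SimulationConfig,
    seed: int | None = None,
    subset: Sequence[int] | None = None,
) -> GenotypeTable:
    """Gene-drop SNP genotypes; return dosages for the genotyped subset.

    Founder haplotypes are Bernoulli draws at per-SNP allele frequencies
    sampled uniformly from ``founder_maf_range``; each non-founder inherits
    one allele per parent uniformly at random.  A missing parent's gamete is
    drawn from the founder frequencies.  By default the genotyped subset is
    the parents of phenotyped animals, so no genotyped animal has own
    phenotypes.
    """
    cfg = config
    rng = _rng(cfg.seed if seed is None else seed, 2)
    m = cfg.n_snps
    lo, hi = cfg.founder_maf_range
    p = rng.uniform(lo, hi, size=m)
    sire, dam = ped.parent_indices()
    n = len(ped)
    hap = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        for which, par in ((0, sire[i]), (1, dam[i])):
            if par < 0:
                hap[i, which] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, which] = hap[par, pick, np.arange(m)]
    if subset is None:
        subset = ped.genotyped_ids()
    subset = np.asarray(subset)
    pos = {aid: i for i, aid in enumerate(ped.ids)}
    try:
        rowsel = np.array([pos[a] for a in subset], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"genotype subset id {exc} not in pedigree") from exc
    dos = hap[rowsel].sum(axis=1).astype(np.int8)
    snp_ids = [f"snp{k + 1:05d}" for k in range(m)]
    return GenotypeTable(ids=subset, snp_ids=snp_ids, dosages=dos)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    ped: PedigreeTable,
    a_coeffs: np.ndarray,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate the long-format weekly record table for phenotyped animals.

    Feed intake follows the degree-2 random-regression model: fixed effects
    (week-by-generation, batch-by-sex, herd, pen, age-at-test slope), the
    phenotypic regressions on MBW/ADG/BFT, the genetic and
    permanent-environment Legendre curves, and a heterogeneous weekly
    residual.  Production traits are smooth animal-specific trajectories
    plus measurement noise.  The true fixed-effect values and
    permanent-environment coefficients are attached via ``attrs`` for use
    as test oracles.
    """
    cfg = config
    rng = _rng(cfg.seed if seed is None else seed, 3)
    basis = legendre_basis(cfg.n_weeks, 2)
    tab = ped.table
    phen_rows = tab.index[tab["phenotyped"]].to_numpy()
    n_phen = len(phen_rows)
    weeks = np.arange(1, cfg.n_weeks + 1)

    # permanent-environment coefficients
    cholb = np.linalg.cholesky(cfg.K_b + 1e-12 * np.eye(3))
    b = rng.standard_normal((n_phen, 3)) @ cholb.T
    if np.allclose(cfg.K_b, 0):
        b[:] = 0.0

    # fixed-effect level values
    gens = sorted(tab["generation"].unique())
    wg_eff = {
        (w, g): rng.normal(0.0, cfg.sd_week_gen) for g in gens for w in weeks
    }
    batch_of_litter = lambda lit: (lit % cfg.n_batches) if lit >= 0 else 0
    bs_eff = {
        (bt, sx): rng.normal(0.0, cfg.sd_batch_sex)
        for bt in range(cfg.n_batches)
        for sx in ("M", "F")
    }
    herd_eff = {h: rng.normal(0.0, cfg.sd_herd) for h in range(2)}
    pen_eff = {p: rng.normal(0.0, cfg.sd_pen) for p in range(cfg.n_pens)}
    if cfg.sd_week_gen == 0:
        wg_eff = {k: 0.0 for k in wg_eff}
    if cfg.sd_batch_sex == 0:
        bs_eff = {k: 0.0 for k in bs_eff}
    if cfg.sd_herd == 0:
        herd_eff = {k: 0.0 for k in herd_eff}
    if cfg.sd_pen == 0:
        pen_eff = {k: 0.0 for k in pen_eff}

    recs = []
    true_pe = {}
    for k, row in enumerate(phen_rows):
        aid = tab.at[row, "id"]
        lit = int(tab.at[row, "litter"])
        gen = int(tab.at[row, "generation"])
        line = tab.at[row, "line"]
        sex = tab.at[row, "sex"]
        batch = batch_of_litter(lit)
        herd = lit % 2 if lit >= 0 else 0
        pen = int(rng.integers(0, cfg.n_pens))
        age_dev = rng.uniform(-10.0, 10.0)
        # production-trait trajectories
        mbw = 13.0 + 1.5 * weeks + rng.normal(0, 1.0) + rng.normal(0, 0.3, cfg.n_weeks)
        adg = (
            0.9 + 0.02 * (weeks - 5.5) + rng.normal(0, 0.08)
            + rng.normal(0, 0.05, cfg.n_weeks)
        )
        bft = 8.0 + 0.7 * weeks + rng.normal(0, 1.5) + rng.normal(0, 0.5, cfg.n_weeks)
        curve = basis.Psi @ (a_coeffs[row] + b[k])
        resid = rng.standard_normal(cfg.n_weeks) * np.sqrt(cfg.D)
        fi = (
            np.array([wg_eff[(w, gen)] for w in weeks])
            + bs_eff[(batch, sex)]
            + herd_eff[herd]
            + pen_eff[pen]
            + cfg.age_slope * age_dev
            + cfg.beta1 * mbw
            + cfg.beta2 * adg
            + cfg.beta3 * bft
            + curve
            + resid
        )
        true_pe[aid] = b[k]
        for j, w in enumerate(weeks):
            recs.append(
                (
                    aid, int(w), fi[j], mbw[j], adg[j], bft[j],
                    f"b{batch:02d}x{sex}", f"h{herd}", f"p{pen:02d}",
                    age_dev, gen, line, False,
                )
            )
    phen = pd.DataFrame(
        recs,
        columns=[
            "animal", "week", "FI", "MBW", "ADG", "BFT",
            "batch_sex", "herd", "pen", "age", "generation", "line", "missing",
        ],
    )
    phen.attrs["true_fixed_effects"] = {
        "week_gen": {f"{w}_{g}": v for (w, g), v in wg_eff.items()},
        "batch_sex": {f"b{bt:02d}x{sx}": v for (bt, sx), v in bs_eff.items()},
        "herd": {f"h{h}": v for h, v in herd_eff.items()},
        "pen": {f"p{p:02d}": v for p, v in pen_eff.items()},
        "age_slope": cfg.age_slope,
        "betas": (cfg.beta1, cfg.beta2, cfg.beta3),
    }
    phen.attrs["true_pe_coefficients"] = true_pe
    return phen


def apply_missingness(
    phen: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Blank weekly records: pick a fraction of animals, then weeks within.

    A missing record keeps its row but has all four trait fields set to NaN
    and ``missing=True``; overall record missingness is approximately
    ``missing_animal_fraction * missing_week_rate``.
    """
    cfg = config
    for name in ("missing_animal_fraction", "missing_week_rate"):
        v = getattr(cfg, name)
        if not 0 <= v <= 1:
            raise ValueError(f"{name} out of [0, 1]")
    rng = _rng(cfg.seed if seed is None else seed, 4)
    out = phen.copy()
    animals = out["animal"].unique()
    hit = animals[rng.random(len(animals)) < cfg.missing_animal_fraction]
    mask = out["animal"].isin(hit).to_numpy() & (
        rng.random(len(out)) < cfg.missing_week_rate
    )
    out.loc[mask, list(TRAITS)] = np.nan
    out.loc[mask, "missing"] = True
    out.attrs = dict(phen.attrs)
    return out


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    config: SimulationConfig
    pedigree: PedigreeTable
    coefficients: np.ndarray  # true genetic coefficients, pedigree order
    genotypes: GenotypeTable
    phenotypes: pd.DataFrame

    def design_summary(self) -> pd.DataFrame:
        """Per line/generation counts of animals and phenotyped animals."""
        t = self.pedigree.table
        return (
            t.groupby(["line", "generation"])
            .agg(n_animals=("id", "size"), n_phenotyped=("phenotyped", "sum"))
            .reset_index()
        )


def simulate_population(
    config: SimulationConfig, with_missing: bool = True
) -> SimulatedData:
    """Run the whole generator: pedigree, coefficients, genotypes, records."""
    ped = simulate_pedigree(config)
    if ped.coefficients is not None:
        a = ped.coefficients
    else:
        a = simulate_breeding_values(ped, config.K_a, config.seed)
        ped.coefficients = a
    geno = simulate_genotypes(ped, config)
    phen = simulate_phenotypes(ped, a, config)
    if with_missing and config.missing_animal_fraction > 0:
        phen = apply_missingness(phen, config)
    return SimulatedData(
        config=config, pedigree=ped, coefficients=a, genotypes=geno, phenotypes=phen
    )
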