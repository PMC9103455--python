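"""Shared fixtures and independent dense oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from longsbv.config import SimulationConfig
from longsbv.synthetic import PedigreeTable, simulate_population


def make_pedigree(records, coefficients=None):
    """Build a PedigreeTable from (id, sire, dam, sex, gen, line) tuples."""
    tab = pd.DataFrame(
        records, columns=["id", "sire", "dam", "sex", "generation", "line"]
    )
    tab["litter"] = -1
    tab["phenotyped"] = True
    tab["F"] = np.nan
    ped = PedigreeTable(table=tab, coefficients=coefficients)
    from longsbv.relationships import numerator_relationship

    tab["F"] = np.nan
    A = numerator_relationship(ped)
    tab["F"] = np.diag(A) - 1.0
    return ped


def random_pedigree(rng, n, n_founders=5, line="L1"):
    """Random valid pedigree: animal i draws parents from earlier animals."""
    recs = []
    gen_of = {}
    for i in range(1, n + 1):
        if i <= n_founders:
            s = d = 0
            g = 0
        else:
            males = [j for j in range(1, i) if (j % 2 == 1)]
            females = [j for j in range(1, i) if (j % 2 == 0)]
            s = int(rng.choice(males)) if males else 0
            d = int(rng.choice(females)) if females else 0
            g = max(gen_of.get(s, 0), gen_of.get(d, 0)) + 1
        gen_of[i] = g
        recs.append((i, s, d, "M" if i % 2 == 1 else "F", g, line))
    # ensure generation ordering invariant: parents are earlier ids with
    # strictly smaller generation by construction above
    return make_pedigree(recs)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_generations=8,
        n_sires_per_gen=3,
        n_dams_per_gen=8,
        progeny_per_mating=5,
        n_snps=300,
        seed=20220513,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    """Full pipeline run on the small two-line fixture (shared, read-only)."""
    import warnings

    from longsbv.config import RunConfig
    from longsbv.pipeline import run_pipeline

    cfg = RunConfig(simulation=small_config, seed=small_config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


# ---------------------------------------------------------------------------
# dense oracles (kept deliberately independent of the package internals)
# ---------------------------------------------------------------------------

def dense_blup_oracle(y, X, Za, Zb, Ka_full, Kb_full, Rdiag):
    """GLS/BLUP by brute-force dense inversion.

    V = Za Ka_full Za' + Zb Kb_full Zb' + diag(Rdiag);
    beta = (X'V^-1X)^-1 X'V^-1 y;  u_a = Ka_full Za' V^-1 (y - X beta).
    """
    V = Za @ Ka_full @ Za.T + np.diag(Rdiag)
    if Zb is not None and Kb_full is not None:
        V = V + Zb @ Kb_full @ Zb.T
    Vinv = np.linalg.inv(V)
    if X.shape[1]:
        XtVinv = X.T @ Vinv
        beta = np.linalg.solve(XtVinv @ X, XtVinv @ y)
        resid = y - X @ beta
    else:
        beta = np.zeros(0)
        resid = y
    a_hat = Ka_full @ Za.T @ (Vinv @ resid)
    b_hat = (
        Kb_full @ Zb.T @ (Vinv @ resid)
        if Zb is not None and Kb_full is not None
        else None
    )
    return beta, a_hat, b_hat
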