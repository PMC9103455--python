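"""Summarized phenotypes: correction, imputation, univariate BLUP, and the
exact equivalence with longitudinal SBV under an isotropic residual."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from longsbv.config import RunConfig, SimulationConfig
from longsbv.regression import (
    ModelSpec,
    VarianceComponents,
    build_mme,
    covariance_functions,
    legendre_basis,
    predict_weekly_ebv,
    solve_blup,
)
from longsbv.relationships import a_inverse, numerator_relationship
from longsbv.sbv import eigen_g, sbv_table
from longsbv.summarized import (
    compare_predictions,
    correct_phenotypes,
    fit_summarized_blup,
    fit_summarized_with_fixed_effects,
    impute_missing_weeks,
    summarize,
)
from longsbv.synthetic import simulate_population

from conftest import make_pedigree


def _population(seed=11, missing=False, **kw):
    base = dict(
        n_generations=5, n_sires_per_gen=3, n_dams_per_gen=8,
        progeny_per_mating=5, n_snps=60, seed=seed,
    )
    base.update(kw)
    cfg = SimulationConfig(**base)
    return cfg, simulate_population(cfg, with_missing=missing)


class TestCorrection:
    def test_zero_effect_fit_returns_raw_fi(self):
        cfg, data = _population()
        spec = ModelSpec(factors=(), covariates=(), fix_betas=(0.0, 0.0, 0.0))
        vc = VarianceComponents(cfg.K_a, cfg.K_b, cfg.D)
        mme = build_mme(data.phenotypes, spec, legendre_basis(10, 2), vc,
                        a_inverse(data.pedigree), data.pedigree.ids)
        sol = solve_blup(mme)
        w = correct_phenotypes(data.phenotypes, sol)
        recs = data.phenotypes
        for _, r in recs.head(20).iterrows():
            assert w.loc[r["animal"], r["week"]] == pytest.approx(r["FI"])

    def test_known_regressions_subtracted_exactly(self):
        cfg, data = _population(seed=12)
        spec = ModelSpec(factors=(), covariates=(),
                         fix_betas=(cfg.beta1, cfg.beta2, cfg.beta3))
        vc = VarianceComponents(cfg.K_a, cfg.K_b, cfg.D)
        sol = solve_blup(
            build_mme(data.phenotypes, spec, legendre_basis(10, 2), vc,
                      a_inverse(data.pedigree), data.pedigree.ids)
        )
        w = correct_phenotypes(data.phenotypes, sol)
        r = data.phenotypes.iloc[7]
        expected = (
            r["FI"] - cfg.beta1 * r["MBW"] - cfg.beta2 * r["ADG"]
            - cfg.beta3 * r["BFT"]
        )
        assert w.loc[r["animal"], r["week"]] == pytest.approx(expected)


class TestImputation:
    def test_identity_without_missing(self):
        w = pd.DataFrame(np.arange(20.0).reshape(2, 10) + 1,
                         index=[1, 2], columns=range(1, 11))
        out, counts = impute_missing_weeks(w)
        pd.testing.assert_frame_equal(out, w)
        assert counts.sum() == 0

    def test_all_missing_animal_gets_weekly_means(self):
        w = pd.DataFrame(np.arange(20.0).reshape(2, 10) + 1,
                         index=[1, 2], columns=range(1, 11))
        w.loc[3] = np.nan
        out, counts = impute_missing_weeks(w)
        np.testing.assert_allclose(out.loc[3], w.loc[[1, 2]].mean())
        assert counts.loc[3] == 10
        assert counts.sum() == 10

    def test_week_missing_everywhere_raises(self):
        w = pd.DataFrame(np.ones((3, 10)), columns=range(1, 11))
        w[5] = np.nan
        with pytest.raises(ValueError):
            impute_missing_weeks(w)


class TestSummarize:
    def test_orthonormal_projections(self):
        cfg = SimulationConfig()
        basis = legendre_basis(10, 2)
        eig = eigen_g(basis.Psi @ cfg.K_a @ basis.Psi.T)
        w = pd.DataFrame([eig.vector(1), eig.vector(2)], index=["a", "b"])
        y1 = summarize(w, eig.vector(1))
        assert y1.loc["a"] == pytest.approx(1.0)
        assert y1.loc["b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        w = pd.DataFrame(rng.standard_normal((6, 10)))
        L = rng.standard_normal(10)
        y = summarize(w, L)
        for i in range(6):
            assert y.iloc[i] == pytest.approx(
                float(np.dot(w.iloc[i], L)), abs=1e-12
            )

    def test_missing_entries_rejected(self):
        w = pd.DataFrame(np.ones((2, 10)))
        w.iloc[0, 3] = np.nan
        with pytest.raises(ValueError):
            summarize(w, np.ones(10))


class TestSummarizedBlup:
    def test_scalar_shrinkage(self):
        # unrelated animals, equal variances: u = 0.5 (y - mean)
        rng = np.random.default_rng(4)
        ids = np.arange(1, 11)
        y = pd.Series(rng.standard_normal(10), index=ids)
        fit = fit_summarized_blup(
            y, sp.identity(10, format="csc"), ids, 1.0, 1.0
        )
        np.testing.assert_allclose(
            fit.ebv.to_numpy(), 0.5 * (y - y.mean()), atol=1e-10
        )
        assert fit.mu == pytest.approx(y.mean())

    def test_zero_genetic_variance_rejected_and_limit(self):
        ids = np.arange(1, 5)
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=ids)
        with pytest.raises(ValueError):
            fit_summarized_blup(y, sp.identity(4, format="csc"), ids, 0.0, 1.0)
        tiny = fit_summarized_blup(
            y, sp.identity(4, format="csc"), ids, 1e-10, 1.0
        )
        np.testing.assert_allclose(tiny.ebv.to_numpy(), 0.0, atol=1e-6)

    def test_dense_gls_oracle_on_pedigree(self):
        from conftest import random_pedigree

        rng = np.random.default_rng(5)
        ped = random_pedigree(rng, 20)
        A = numerator_relationship(ped)
        s2g, s2e = 0.4, 0.6
        y = pd.Series(rng.standard_normal(20) + 2.0, index=ped.ids)
        fit = fit_summarized_blup(y, a_inverse(ped), ped.ids, s2g, s2e)
        V = s2g * A + s2e * np.eye(20)
        Vinv = np.linalg.inv(V)
        one = np.ones(20)
        mu = float(one @ Vinv @ y / (one @ Vinv @ one))
        u = s2g * A @ Vinv @ (y - mu)
        assert fit.mu == pytest.approx(mu, abs=1e-8)
        np.testing.assert_allclose(fit.ebv.to_numpy(), u, atol=1e-8)


class TestEquivalenceTheorem:
    def _isotropic_setup(self, seed=21):
        sigma2 = 0.08
        cfg, data = _population(
            seed=seed,
            K_b=np.zeros((3, 3)),
            D=np.full(10, sigma2),
        )
        vc = VarianceComponents(cfg.K_a, np.zeros((3, 3)), cfg.D)
        basis = legendre_basis(10, 2)
        G, P = covariance_functions(vc, basis)
        eig = eigen_g(G)
        Ainv = a_inverse(data.pedigree)
        mme = build_mme(data.phenotypes, ModelSpec(), basis, vc, Ainv,
                        data.pedigree.ids)
        sol = solve_blup(mme)
        return cfg, data, vc, basis, G, P, eig, Ainv, sol, sigma2

    def test_summarized_equals_longitudinal_sbv(self):
        (cfg, data, vc, basis, G, P, eig, Ainv, sol, sigma2) = (
            self._isotropic_setup()
        )
        u = predict_weekly_ebv(sol)
        sbv_long = sbv_table(u, eig, 3)
        w = correct_phenotypes(data.phenotypes, sol)
        w_full, _ = impute_missing_weeks(w)
        for l in (1, 2, 3):
            L = eig.vector(l)
            y = summarize(w_full, L)
            fit = fit_summarized_blup(
                y, Ainv, data.pedigree.ids, float(eig.values[l - 1]), sigma2
            )
            np.testing.assert_allclose(
                fit.ebv.loc[sbv_long.index].to_numpy(),
                sbv_long[f"SBV{l}"].to_numpy(),
                atol=1e-8,
            )

    def test_comparison_statistics_are_null_in_isotropic_case(self):
        (cfg, data, vc, basis, G, P, eig, Ainv, sol, sigma2) = (
            self._isotropic_setup(seed=22)
        )
        u = predict_weekly_ebv(sol)
        sbv_long = sbv_table(u, eig, 3)
        w_full, _ = impute_missing_weeks(
            correct_phenotypes(data.phenotypes, sol)
        )
        fits = {
            l: fit_summarized_blup(
                summarize(w_full, eig.vector(l)), Ainv, data.pedigree.ids,
                float(eig.values[l - 1]), sigma2,
            )
            for l in (1, 2, 3)
        }
        stats = compare_predictions(
            sbv_long, fits, data.pedigree.genotyped_ids()
        )
        np.testing.assert_allclose(stats["bias"], 0.0, atol=1e-8)
        np.testing.assert_allclose(stats["dispersion"], 1.0, atol=1e-6)
        np.testing.assert_allclose(stats["correlation"], 1.0, atol=1e-8)


class TestFixedEffectVariant:
    def test_matches_precorrected_variant_without_fixed_effects(self):
        # all fixed-effect variances zero: the longitudinal model carries a
        # pure time profile, whose L-projection is one global constant that
        # the summarized model's mean absorbs
        cfg, data = _population(
            seed=31, sd_week_gen=0, sd_batch_sex=0, sd_herd=0, sd_pen=0,
            age_slope=0,
        )
        vc = VarianceComponents(cfg.K_a, cfg.K_b, cfg.D)
        basis = legendre_basis(10, 2)
        G, P = covariance_functions(vc, basis)
        eig = eigen_g(G)
        Ainv = a_inverse(data.pedigree)
        spec = ModelSpec(factors=("week",), covariates=())
        sol = solve_blup(
            build_mme(data.phenotypes, spec, basis, vc, Ainv,
                      data.pedigree.ids)
        )
        L = eig.vector(1)
        s2g = float(eig.values[0])
        s2e = float(L @ (P + np.diag(vc.D)) @ L)
        # variant A: pre-corrected for everything
        w_full, _ = impute_missing_weeks(
            correct_phenotypes(data.phenotypes, sol)
        )
        fit_a = fit_summarized_blup(
            summarize(w_full, L), Ainv, data.pedigree.ids, s2g, s2e
        )
        # variant B: only the trait regressions removed; no time-free fixed
        # effects left to estimate, so the model carries just the mean
        recs = data.phenotypes.loc[~data.phenotypes["missing"]].copy()
        bh = sol.fixed
        raw = recs["FI"].to_numpy(dtype=float)
        for c in ("MBW", "ADG", "BFT"):
            m = sol.design_info.covariate_means[c]
            raw = raw - bh[f"beta_{c}"] * (recs[c].to_numpy(dtype=float) - m)
        wtab = recs[["animal", "week"]].copy()
        wtab["w"] = raw
        wide = wtab.pivot_table(index="animal", columns="week", values="w")
        wide = wide.reindex(index=w_full.index, columns=range(1, 11))
        wide, _ = impute_missing_weeks(wide)
        y_raw = summarize(wide, L)
        animal_frame = recs.drop_duplicates("animal")[
            ["animal", "batch_sex", "herd", "pen", "age"]
        ]
        fit_b = fit_summarized_with_fixed_effects(
            y_raw, animal_frame, ModelSpec(factors=(), covariates=(),
                                           trait_covariates=()),
            Ainv, data.pedigree.ids, s2g, s2e,
        )
        np.testing.assert_allclose(
            fit_a.ebv.to_numpy(), fit_b.ebv.to_numpy(), atol=1e-6
        )

    def test_time_factor_rejected_in_reduced_model(self):
        cfg, data = _population(seed=32)
        ids = data.pedigree.ids
        y = pd.Series(np.zeros(3), index=ids[:3])
        with pytest.raises(ValueError):
            fit_summarized_with_fixed_effects(
                y, data.phenotypes, ModelSpec(factors=("week",)),
                a_inverse(data.pedigree), ids, 1.0, 1.0,
            )


class TestComparePredictions:
    def test_identical_inputs_give_null_statistics(self):
        rng = np.random.default_rng(6)
        ids = np.arange(1, 31)
        sbv = pd.DataFrame(
            rng.standard_normal((30, 1)), index=ids, columns=["SBV1"]
        )

        class FakeFit:
            ebv = pd.Series(sbv["SBV1"], index=ids)

        stats = compare_predictions(sbv, {1: FakeFit()}, ids)
        assert stats.loc[0, "bias"] == pytest.approx(0.0)
        assert stats.loc[0, "dispersion"] == pytest.approx(1.0)
        assert stats.loc[0, "correlation"] == pytest.approx(1.0)

    def test_empty_ids_rejected(self):
        with pytest.raises(ValueError):
            compare_predictions(pd.DataFrame(), {}, np.array([]))

    def test_leading_eigen_share_predicts_agreement(self, small_result):
        # SBV1 (largest genetic share) should agree at least as well as SBV3
        t2 = small_result.table2
        c1 = t2[t2["sbv"] == 1]["correlation"].mean()
        c3 = t2[t2["sbv"] == 3]["correlation"].mean()
        assert c1 >= c3 - 0.01


class TestImputationDegradesAgreement:
    def test_mean_correlation_not_improved_by_imputation(self):
        deltas = []
        for seed in (51, 52, 53, 54):
            corr = {}
            for miss in (False, True):
                cfg = RunConfig(
                    simulation=SimulationConfig(
                        n_generations=6, n_sires_per_gen=3, n_dams_per_gen=8,
                        progeny_per_mating=5, n_snps=40, seed=seed,
                        missing_animal_fraction=0.4, missing_week_rate=0.3,
                    ),
                    seed=seed, use_genomics=False, apply_missingness=miss,
                    n_cuts=1,
                )
                from longsbv.pipeline import run_pipeline

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = run_pipeline(cfg)
                corr[miss] = res.table2["correlation"].mean()
            deltas.append(corr[True] - corr[False])
        assert np.mean(deltas) <= 1e-6
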