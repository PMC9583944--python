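"""REML engine, covariance structures, inference and BLUP extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxeblup import simdata
from gxeblup.genomics import additive_grm, bend_grm
from gxeblup.mme import (
    FactorAnalytic,
    ModelSpec,
    TermSpec,
    chi2_mixture_sf,
    fa_expand,
    lrt_boundary,
    make_structure,
    reml_fit,
)
from gxeblup.types import GRM

from conftest import make_panel


def one_way_data(seed=1, q=20, n=5, vg=2.0, ve=1.0):
    rng = np.random.default_rng(seed)
    ids = [f"g{i}" for i in range(q)]
    u = rng.normal(0, np.sqrt(vg), q)
    rows = [{"individual": g, "trial": "T", "season": "s", "cell": "T:s",
             "value": 10 + u[i] + rng.normal(0, np.sqrt(ve))}
            for i, g in enumerate(ids) for _ in range(n)]
    return pd.DataFrame(rows), GRM(np.eye(q), ids, "additive")


class TestRemlOracles:
    def test_balanced_one_way_matches_anova(self):
        pheno, grm = one_way_data()
        spec = ModelSpec([TermSpec("G", "additive", grm)], fixed=(),
                         permanent_env=False, residual_by="single")
        fit = reml_fit(spec, pheno)
        q, n = 20, 5
        gm = pheno.groupby("individual")["value"].mean()
        msb = n * ((gm - pheno["value"].mean()) ** 2).sum() / (q - 1)
        msw = ((pheno["value"] - pheno["individual"].map(gm)) ** 2).sum() / (
            q * (n - 1))
        assert abs(fit.result.params_for("G")[0] - (msb - msw) / n) < 1e-6
        assert abs(fit.result.params_for("residual")[0] - msw) < 1e-6

    def test_zero_genetic_variance_pinned_at_boundary(self):
        pheno, grm = one_way_data(seed=2, vg=0.0)
        spec = ModelSpec([TermSpec("G", "additive", grm)], fixed=(),
                         permanent_env=False, residual_by="single")
        fit = reml_fit(spec, pheno)
        assert fit.result.params_for("G")[0] < 0.05
        vc = fit.variance_components()
        assert bool(vc.loc[vc.term == "G", "pinned"].iloc[0]) or \
            fit.result.params_for("G")[0] < 0.05

    def test_blups_match_henderson_equations(self):
        # tiny GBLUP system solved by dense mixed-model equations at the
        # converged variance components
        rng = np.random.default_rng(3)
        n = 5
        panel = make_panel(rng.binomial(2, 0.5, size=(n, 60)).astype(float))
        grm = bend_grm(additive_grm(panel), 1e-4)
        g = rng.multivariate_normal(np.zeros(n), 2.0 * grm.matrix)
        pheno = pd.DataFrame({
            "individual": panel.ids, "trial": "T", "season": "s",
            "cell": "T:s", "value": 10 + g + rng.normal(0, 0.3, n)})
        spec = ModelSpec([TermSpec("A", "additive", grm)], fixed=("cell",),
                         permanent_env=False, residual_by="single")
        vg, ve = 2.0, 0.09  # evaluate BLUP extraction at fixed components
        fit = reml_fit(spec, pheno, start=np.array([vg, ve]), max_iter=0)
        y = pheno["value"].to_numpy()
        X = np.ones((n, 1))
        Z = np.eye(n)
        Ginv = np.linalg.inv(grm.matrix)
        lam = ve / vg
        C = np.block([[X.T @ X, X.T @ Z],
                      [Z.T @ X, Z.T @ Z + Ginv * lam]])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(C, rhs)
        blup = fit.blup_pev(["A"])
        assert np.allclose(np.sort(blup["blup"].to_numpy()),
                           np.sort(sol[1:]), atol=1e-6)
        # PEVs from the inverse coefficient matrix, times ve
        Cinv = np.linalg.inv(C)
        pev_mme = np.diag(Cinv)[1:] * ve
        got = blup.set_index("individual").loc[panel.ids, "pev"].to_numpy()
        assert np.allclose(got, pev_mme, atol=1e-6)

    def test_clone_pair_and_isolated_individual(self):
        rng = np.random.default_rng(4)
        K = np.eye(6)
        K[0, 1] = K[1, 0] = 1.0  # clones
        ids = [f"i{k}" for k in range(6)]
        grm = bend_grm(GRM(K, ids, "additive"), 1e-8)
        pheno = pd.DataFrame({
            "individual": ids[:5], "trial": "T", "season": "s", "cell": "T:s",
            "value": rng.normal(0, 1, 5)})
        spec = ModelSpec([TermSpec("A", "additive", grm)], fixed=("cell",),
                         permanent_env=False, residual_by="single")
        fit = reml_fit(spec, pheno)
        bp = fit.blup_pev(["A"]).set_index("individual")
        # clones share the (bent-)GRM profile, hence the BLUP
        assert np.isclose(bp.loc["i0", "blup"], bp.loc["i1", "blup"], atol=1e-4)
        # i5 is unphenotyped and unrelated: no information
        vg = fit.result.params_for("A")[0]
        assert abs(bp.loc["i5", "blup"]) < 1e-8
        assert np.isclose(bp.loc["i5", "pev"], vg * K[5, 5], rtol=1e-6)


class TestFitInvariances:
    def _fit(self, pheno, grm):
        spec = ModelSpec([TermSpec("G", "additive", grm)], fixed=(),
                         permanent_env=False, residual_by="single")
        return reml_fit(spec, pheno)

    def test_row_permutation(self):
        pheno, grm = one_way_data(seed=5, q=10, n=3)
        fit = self._fit(pheno, grm)
        shuffled = pheno.sample(frac=1.0, random_state=0)
        fit2 = self._fit(shuffled, grm)
        assert abs(fit.loglik - fit2.loglik) < 1e-6
        assert np.allclose(fit.result.theta, fit2.result.theta, atol=1e-6)

    def test_response_scaling(self):
        pheno, grm = one_way_data(seed=6, q=10, n=3)
        fit = self._fit(pheno, grm)
        c = 3.0
        scaled = pheno.assign(value=pheno["value"] * c)
        fit2 = self._fit(scaled, grm)
        assert np.allclose(fit2.result.theta, fit.result.theta * c**2,
                           rtol=1e-4)
        n, p = len(pheno), 1
        assert abs(fit2.loglik - (fit.loglik - (n - p) * np.log(c))) < 1e-4

    def test_loglik_nondecreasing_over_iterations(self):
        pheno, grm = one_way_data(seed=7)
        fit = self._fit(pheno, grm)
        traj = np.array(fit.result.trajectory)
        assert (np.diff(traj) >= -1e-9).all()


class TestStructures:
    @pytest.mark.parametrize("kind,n_env", [
        ("uniform", 3), ("iid", 3), ("diagonal", 4), ("fa1", 4),
        ("fa2", 5), ("us", 3),
    ])
    def test_dsigma_matches_finite_differences(self, kind, n_env):
        s = make_structure(kind, n_env)
        rng = np.random.default_rng(0)
        theta = np.abs(rng.normal(1.0, 0.3, s.n_params))
        h = 1e-6
        for k in range(s.n_params):
            tp = theta.copy()
            tp[k] += h
            fd = (s.sigma(tp) - s.sigma(theta)) / h
            assert np.allclose(s.dsigma(theta, k), fd, atol=1e-4)

    def test_fa_expand_identity_and_rank_one(self):
        sigma, logdet, inv = fa_expand(np.zeros((2, 1)), np.ones(2))
        assert np.allclose(sigma, np.eye(2))
        sigma, _, _ = fa_expand(np.array([[1.0], [1.0]]), np.zeros(2))
        assert np.allclose(sigma, [[1, 1], [1, 1]])
        corr = sigma / np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
        assert np.allclose(corr, 1.0)

    def test_fa_expand_woodbury_matches_dense(self):
        rng = np.random.default_rng(1)
        L = rng.normal(size=(6, 2))
        psi = np.abs(rng.normal(1.0, 0.2, 6))
        sigma, logdet, inv = fa_expand(L, psi)
        assert np.allclose(inv, np.linalg.inv(sigma), atol=1e-10)
        assert abs(logdet - np.linalg.slogdet(sigma)[1]) < 1e-10

    def test_fa_sign_canonicalisation(self):
        L = np.array([[-0.5, 0.0], [0.3, -0.2], [0.1, 0.4]])
        C = FactorAnalytic.canonicalise(L)
        assert C[0, 0] >= 0 and C[1, 1] >= 0
        assert np.allclose(C @ C.T, L @ L.T)


class TestInference:
    def test_boundary_lrt_reference_values(self):
        assert lrt_boundary(-10.0, -10.0, 1) == (0.0, 1.0)
        T, p = lrt_boundary(-8.08, -10.0, 1)  # T = 3.84
        assert abs(p - 0.5 * stats.chi2.sf(3.84, 1)) < 1e-12
        assert abs(p - 0.025) < 1e-3
        assert abs(chi2_mixture_sf(3.84, 0, 1) - stats.chi2.sf(3.84, 1)) < 1e-12

    def test_mixture_with_free_and_boundary_params(self):
        T = 5.0
        p = chi2_mixture_sf(T, 2, 1)
        expect = (0.25 * stats.chi2.sf(T, 1) + 0.5 * stats.chi2.sf(T, 2)
                  + 0.25 * stats.chi2.sf(T, 3))
        assert abs(p - expect) < 1e-12

    def test_wald_arithmetic_and_null(self):
        pheno, grm = one_way_data(seed=8, q=10, n=4)
        pheno["season"] = np.tile(["a", "b"], len(pheno) // 2)
        pheno["cell"] = "T:" + pheno["season"]
        spec = ModelSpec([TermSpec("G", "additive", grm)], fixed=("season",),
                         permanent_env=False, residual_by="single")
        fit = reml_fit(spec, pheno)
        # inject a known coefficient block to check the quadratic form
        s = fit.fixed_slices["season"]
        fit.result.beta[s] = 2.0
        fit.result.beta_cov[s, s] = 1.0
        stat, df, p = fit.wald_test("season")
        assert df == 1 and abs(stat - 4.0) < 1e-12
        assert abs(p - stats.chi2.sf(4.0, 1)) < 1e-12
        fit.result.beta[s] = 0.0
        stat, _, p = fit.wald_test("season")
        assert stat == 0.0 and p == 1.0

    def test_strong_season_effect_detected(self):
        pheno, grm = one_way_data(seed=9, q=15, n=4)
        half = len(pheno) // 2
        pheno["season"] = ["a"] * half + ["b"] * half
        pheno["cell"] = "T:" + pheno["season"]
        pheno.loc[pheno.season == "b", "value"] += 3.0
        spec = ModelSpec([TermSpec("G", "additive", grm)], fixed=("season",),
                         permanent_env=False, residual_by="single")
        fit = reml_fit(spec, pheno)
        _, _, p = fit.wald_test("season")
        assert p < 0.001


class TestFactorAnalyticEquivalence:
    def test_full_order_fa_matches_unstructured_loglik(self):
        # FA(2) + Psi spans every PSD 3x3 covariance, so its optimum must
        # coincide with the unstructured fit on three-environment data
        pheno, panel, interval, truth = simdata.recovery_dataset(
            21, n_loci=400, n_fam=6, fam_size=15, n_seasons=3)
        grm = bend_grm(additive_grm(panel))
        cell_map = {c: c for c in sorted(pheno["cell"].unique())}
        mk = lambda structure: ModelSpec(
            [TermSpec("A", "additive", grm, cell_map, structure)],
            fixed=("cell",), permanent_env=False, residual_by="trial")
        us = reml_fit(mk("us"), pheno)
        fa = reml_fit(mk("fa2"), pheno)
        assert abs(fa.loglik - us.loglik) < 1e-4
        assert np.allclose(fa.env_cov("A"), us.env_cov("A"), atol=5e-2)
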