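"""Cohort construction, expected accuracy, adjusted phenotypes and CV."""

import numpy as np
import pandas as pd
import pytest

from gxeblup import accuracy as acc
from gxeblup import simdata
from gxeblup.genomics import additive_grm, bend_grm
from gxeblup.mme import ModelSpec, TermSpec, reml_fit


def _pheno(records):
    rows = []
    for ind, trial, season, value in records:
        rows.append({"individual": ind, "trial": trial, "season": season,
                     "cell": f"{trial}:{season}", "value": value})
    return pd.DataFrame(rows)


class TestAssignCohorts:
    ENV = {"F:1": "F", "F:2": "F", "S:1": "S"}

    def test_trivial_memberships(self):
        pheno = _pheno([("a", "F", "1", 1.0), ("b", "S", "1", 2.0)])
        cohorts = acc.assign_cohorts(pheno, self.ENV, ["a", "b", "c"])
        tab = cohorts.set_index(["trial", "env", "individual"])["cohort"]
        assert tab[("F", "F", "a")] == "TGE"
        assert tab[("F", "F", "b")] == "trial_untested"
        assert tab[("F", "F", "c")] == "trial_untested"
        assert tab[("S", "S", "b")] == "TGE"

    def test_trial_tested_requires_other_env_in_trial(self):
        env = {"F:1": "E1", "F:2": "E2"}
        pheno = _pheno([("a", "F", "1", 1.0), ("b", "F", "2", 2.0)])
        cohorts = acc.assign_cohorts(pheno, env, ["a", "b"])
        tab = cohorts.set_index(["trial", "env", "individual"])["cohort"]
        assert tab[("F", "E1", "a")] == "TGE"
        assert tab[("F", "E1", "b")] == "trial_tested"

    def test_partition_matches_set_algebra(self):
        pheno, panel, interval, truth, env_map = simdata.two_trial_dataset(
            13, background="divergent", n_loci=300, n_fam=4, fam_size=10,
            partial_last_cell=True)
        cohorts = acc.assign_cohorts(pheno, env_map, panel.ids)
        by_te = pheno.assign(env=pheno["cell"].map(env_map))
        for (trial, env), grp in cohorts.groupby(["trial", "env"]):
            # disjoint cover of all genotyped individuals
            assert len(grp) == len(panel.ids)
            assert grp["individual"].is_unique
            tge = set(by_te.loc[(by_te.trial == trial) & (by_te.env == env),
                                "individual"])
            in_trial = set(by_te.loc[by_te.trial == trial, "individual"])
            got_tge = set(grp.loc[grp.cohort == "TGE", "individual"])
            got_tt = set(grp.loc[grp.cohort == "trial_tested", "individual"])
            assert got_tge == tge
            assert got_tt == in_trial - tge


class TestExpectedAccuracy:
    def test_re_arithmetic(self):
        # sqrt(1 - PEV/v): PEV=0 -> 1; PEV=v -> 0; PEV=0.36, v=1 -> 0.8
        assert np.isclose(np.sqrt(1 - 0.36 / 1.0), 0.8)
        pheno, panel, interval, truth, env_map = simdata.two_trial_dataset(
            14, background="uniform", n_loci=300, n_fam=4, fam_size=10)
        grm = bend_grm(additive_grm(panel))
        spec = ModelSpec([TermSpec("A", "additive", grm)], fixed=("cell",),
                         permanent_env=True, residual_by="trial")
        fit = reml_fit(spec, pheno)
        cohorts = acc.assign_cohorts(pheno, env_map, panel.ids)
        rep = acc.expected_accuracy(fit, cohorts, {"AW": ["A"]}, env_map)
        ok = rep.dropna(subset=["rE"])
        assert ((ok["rE"] >= 0) & (ok["rE"] <= 1)).all()
        v = fit.result.params_for("A")[0]
        expect = np.sqrt(np.clip(1 - ok["mean_pev"] / v, 0, 1))
        assert np.allclose(ok["rE"], expect, atol=1e-12)

    def test_zero_variance_flagged(self):
        pheno, panel, interval, truth, env_map = simdata.two_trial_dataset(
            15, background="uniform", n_loci=300, n_fam=4, fam_size=10,
            vDW=0.0)
        from gxeblup.genomics import dominance_grm
        spec = ModelSpec(
            [TermSpec("A", "additive", bend_grm(additive_grm(panel))),
             TermSpec("D", "dominance", bend_grm(dominance_grm(panel)))],
            fixed=("cell",), permanent_env=True, residual_by="trial")
        fit = reml_fit(spec, pheno)
        if fit.result.params_for("D")[0] < 1e-10:
            cohorts = acc.assign_cohorts(pheno, env_map, panel.ids)
            rep = acc.expected_accuracy(fit, cohorts, {"DW": ["D"]}, env_map)
            assert rep["flagged"].all()
            assert rep["rE"].isna().all()


class TestAdjustedPhenotypes:
    def test_single_record_equals_centred_value(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 2, 12)
        pheno = _pheno([(f"i{k}", "T", "1", v) for k, v in enumerate(vals)])
        adj = acc.adjusted_phenotypes(pheno)
        assert np.allclose(adj["adjusted"], vals - vals.mean(), atol=1e-6)

    def test_cell_constant_absorbed(self):
        rng = np.random.default_rng(1)
        recs = [(f"i{k}", "T", s, rng.normal()) for k in range(10)
                for s in ("1", "2")]
        pheno = _pheno(recs)
        adj1 = acc.adjusted_phenotypes(pheno)
        shifted = pheno.copy()
        shifted.loc[shifted["cell"] == "T:1", "value"] += 100.0
        adj2 = acc.adjusted_phenotypes(shifted)
        assert np.allclose(adj1["adjusted"], adj2["adjusted"], atol=1e-6)

    def test_repeatability_limit(self):
        # correlation with the true individual effect follows the
        # repeatability formula sqrt(vG / (vG + vR/n_rec))
        rng = np.random.default_rng(2)
        n, nrec, vG, vR = 300, 2, 1.0, 0.5
        g = rng.normal(0, np.sqrt(vG), n)
        recs = []
        for k in range(n):
            for s in ("1", "2"):
                recs.append((f"i{k}", "T", s,
                             g[k] + rng.normal(0, np.sqrt(vR))))
        pheno = _pheno(recs)
        adj = acc.adjusted_phenotypes(pheno)
        per_ind = adj.groupby("individual")["adjusted"].mean()
        got = np.corrcoef(per_ind[[f"i{k}" for k in range(n)]], g)[0, 1]
        expect = np.sqrt(vG / (vG + vR / nrec))
        assert abs(got - expect) < 0.05


class TestCrossValidation:
    def _setup(self, seed=16, **kw):
        pheno, panel, interval, truth, env_map = simdata.two_trial_dataset(
            seed, background="uniform", n_loci=300, n_fam=4, fam_size=12, **kw)
        grm = bend_grm(additive_grm(panel))
        spec = ModelSpec([TermSpec("A", "additive", grm)], fixed=("cell",),
                         permanent_env=True, residual_by="trial")
        from gxeblup.summaries import heritability_table
        fit = reml_fit(spec, pheno)
        return pheno, spec, env_map, heritability_table(fit)

    def test_same_seed_reproducible(self):
        pheno, spec, env_map, herit = self._setup()
        kw = dict(term_sets={"additive": ["A"]}, divisors={"additive": "h2"},
                  scheme="WTCV", k=3, seed=11)
        a = acc.cross_validate(pheno, spec, env_map, herit, **kw)
        b = acc.cross_validate(pheno, spec, env_map, herit, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_null_additive_variance_centred_on_zero(self):
        pheno, panel, interval, truth, env_map = simdata.two_trial_dataset(
            17, background="uniform", n_loci=300, n_fam=4, fam_size=12,
            vAQ=0.0, vAB=0.0, vDW=0.0, vR=0.5)
        grm = bend_grm(additive_grm(panel))
        spec = ModelSpec([TermSpec("A", "additive", grm)], fixed=("cell",),
                         permanent_env=True, residual_by="trial")
        herit = pd.DataFrame({"trial": ["T1", "T2"], "env": ["all", "all"],
                              "h2": [1.0, 1.0]})
        cv = acc.cross_validate(pheno, spec, env_map, herit,
                                {"additive": ["A"]}, {"additive": "h2"},
                                scheme="XTCV", k=3, seed=5)
        if not cv.empty:
            assert cv["accuracy"].abs().mean() < 0.45

    def test_invalid_k_rejected(self):
        pheno, spec, env_map, herit = self._setup(seed=18)
        with pytest.raises(ValueError, match="k >= 2"):
            acc.cross_validate(pheno, spec, env_map, herit,
                               {"additive": ["A"]}, {"additive": "h2"}, k=1)
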