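"""Synthetic-data generator: structure, calibration and determinism."""

import numpy as np
import pandas as pd
import pytest

from gxeblup import genomics, simdata
from gxeblup.simdata import (
    BackgroundTruth,
    FamilySpec,
    PlanCell,
    SimConfig,
    VarianceTruth,
)


def _null_truth(cells=("T:1",)):
    return VarianceTruth(0.0, BackgroundTruth.uniform(0.0, list(cells)),
                         0.0, {}, {}, {})


def _config(seed=0, fst=0.1, n_pops=2, n_founders=10, families=(),
            n_loci=400, truth=None, plan=()):
    return SimConfig(n_pops, fst, n_founders, list(families), 8, n_loci,
                     30_000_000, (4, 1, 30_000_000), 8,
                     truth or _null_truth(), list(plan), seed)


class TestFounders:
    def test_same_seed_identical(self):
        a = simdata.simulate_founder_populations(_config(seed=7))
        b = simdata.simulate_founder_populations(_config(seed=7))
        assert np.array_equal(a.dosage, b.dosage)
        assert a.ids == b.ids

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="fst_target"):
            _config(fst=1.0)
        with pytest.raises(ValueError, match="positive"):
            _config(n_founders=0)
        with pytest.raises(ValueError, match="not among founders"):
            _config(families=[FamilySpec("P9_0", "P0_1", "F1", 5, "X")])

    def test_zero_divergence_gives_near_zero_fst(self):
        from gxeblup import diversity
        panel = simdata.simulate_founder_populations(
            _config(seed=1, fst=0.0, n_founders=40, n_loci=2000))
        f = diversity.pairwise_fst(panel)
        assert abs(f.iloc[0, 1]) < 0.01


class TestFamilies:
    def test_zero_recombination_mendelian_limit(self):
        # homozygous distinct parents, no crossovers -> all F1 identical hets
        cfg = _config(families=[FamilySpec("P0_0", "P0_1", "F1", 20, "F0")])
        cfg.morgans_per_bp = 0.0
        founders = simdata.simulate_founder_populations(cfg)
        founders.haplotypes[0] = 0
        founders.haplotypes[1] = 1
        founders.dosage[0] = 0.0
        founders.dosage[1] = 2.0
        panel = simdata.drop_families(founders, cfg)
        kids = panel.dosage[panel.n_individuals - 20:]
        assert (kids == 1.0).all()

    def test_f1_mean_dosage_near_midparent(self):
        cfg = _config(seed=3, families=[FamilySpec("P0_0", "P0_1", "F1",
                                                   200, "F0")])
        founders = simdata.simulate_founder_populations(cfg)
        panel = simdata.drop_families(founders, cfg)
        kids = panel.dosage[-200:]
        mid = (panel.dosage[0] + panel.dosage[1]) / 2.0
        # binomial SE per locus; compare standardised deviations
        se = np.sqrt(0.5 * 0.5 * 2 / 200)
        z = (kids.mean(axis=0) - mid) / se
        assert np.mean(np.abs(z) < 3) > 0.95

    def test_parent_offspring_relatedness(self):
        fams = [FamilySpec("P0_0", "P0_1", "F1", 150, "F0")]
        cfg = _config(seed=4, n_founders=30, n_loci=1500, families=fams)
        founders = simdata.simulate_founder_populations(cfg)
        panel = simdata.drop_families(founders, cfg)
        # base-population (founder) allele frequencies give the expected
        # numerator relationship; family-skewed frequencies would not
        grm = genomics.additive_grm(panel, freqs=founders.allele_frequencies())
        par = panel.ids.index("P0_0")
        kid_rows = [i for i, x in enumerate(panel.ids) if x.startswith("F0_")]
        rel = grm.matrix[par, kid_rows].mean()
        founder_rows = [i for i, x in enumerate(panel.ids)
                        if x.startswith("P0_")]
        half_diag = 0.5 * np.mean(np.diag(grm.matrix)[founder_rows])
        assert abs(rel - half_diag) < 0.1

    def test_unknown_parent_raises(self):
        cfg = _config(families=[FamilySpec("P0_0", "P0_1", "F1", 2, "F0")])
        founders = simdata.simulate_founder_populations(cfg)
        cfg.family_plan[0] = FamilySpec("P0_0", "nope", "F1", 2, "F0")
        with pytest.raises((KeyError, ValueError)):
            simdata.drop_families(founders, cfg)


class TestTruthEffects:
    def _panel(self, seed=5, n_loci=1500):
        fams = [FamilySpec(f"P0_{2*i}", f"P0_{2*i+1}", "F1", 40, f"F{i}")
                for i in range(5)]
        cfg = _config(seed=seed, n_founders=10, n_loci=n_loci, families=fams)
        return simdata.drop_families(
            simdata.simulate_founder_populations(cfg), cfg), cfg

    def test_all_zero_variances_give_zero_values(self):
        panel, cfg = self._panel()
        truth = _null_truth(["T:1", "T:2"])
        eff = simdata.assign_truth_effects(panel, truth, (4, 1, 30_000_000), 1)
        assert not eff.g_qtl.any()
        assert not eff.g_background.any()
        assert not eff.g_dominance.any()

    def test_qtl_share_of_additive_variance(self):
        panel, cfg = self._panel()
        chrom = panel.loci["chrom"].to_numpy()
        pos = panel.loci["pos"].to_numpy()
        on4 = pos[chrom == 4]
        interval = (4, int(on4[10]), int(on4[17]))
        cells = ["T:1"]
        shares = []
        for seed in range(6):
            truth = VarianceTruth(0.25, BackgroundTruth.uniform(0.75, cells),
                                  0.0, {}, {}, {})
            eff = simdata.assign_truth_effects(panel, truth, interval, seed)
            total = eff.additive("T:1")
            shares.append(np.var(eff.g_qtl) / np.var(total))
        assert abs(np.mean(shares) - 0.25) < 0.08

    def test_rank_one_background_perfectly_correlated(self):
        panel, cfg = self._panel()
        cells = ["T:1", "T:2", "T:3"]
        bg = BackgroundTruth(cells, np.array([[0.5], [0.7], [0.9]]),
                             np.zeros(3), {c: c for c in cells})
        truth = VarianceTruth(0.0, bg, 0.0, {}, {}, {})
        eff = simdata.assign_truth_effects(panel, truth, (4, 1, 30_000_000), 2)
        r = np.corrcoef(eff.g_background.T)
        assert np.allclose(r, 1.0, atol=1e-10)

    def test_empty_qtl_interval_rejected(self):
        panel, cfg = self._panel()
        truth = VarianceTruth(0.1, BackgroundTruth.uniform(0.0, ["T:1"]),
                              0.0, {}, {}, {})
        with pytest.raises(ValueError, match="no loci"):
            simdata.assign_truth_effects(panel, truth, (4, 5, 6), 1)


class TestPhenotypes:
    def test_zero_random_variances_equal_fixed_means(self):
        fams = [FamilySpec("P0_0", "P0_1", "F1", 10, "F0")]
        cfg = _config(seed=6, families=fams)
        panel = simdata.drop_families(
            simdata.simulate_founder_populations(cfg), cfg)
        cells = ["T:1", "T:2"]
        truth = VarianceTruth(0.0, BackgroundTruth.uniform(0.0, cells), 0.0,
                              {"T": 0.0}, {"T": 0.0},
                              {"T:1": 5.0, "T:2": 8.0})
        eff = simdata.assign_truth_effects(panel, truth, (4, 1, 30_000_000), 1)
        ids = [i for i in panel.ids if i.startswith("F0_")]
        plan = [PlanCell("T", "1", ids), PlanCell("T", "2", ids)]
        pheno = simdata.simulate_phenotypes(panel, eff, truth, plan, 9)
        assert (pheno.loc[pheno["cell"] == "T:1", "value"] == 5.0).all()
        assert (pheno.loc[pheno["cell"] == "T:2", "value"] == 8.0).all()

    def test_variance_bookkeeping(self):
        pheno, panel, interval, truth = simdata.recovery_dataset(
            11, n_loci=800, n_fam=10, fam_size=50, n_seasons=1)
        v = pheno.groupby("cell")["value"].var()
        expected = (truth.vAQ + truth.background.variances[0] + truth.vDW
                    + truth.vU_by_trial["T"] + truth.vR_by_trial["T"])
        # family structure inflates genetic variance relative to the HWE
        # calibration; allow a generous band around the component sum
        assert abs(v.iloc[0] - expected) / expected < 0.5

    def test_plan_individual_must_exist(self):
        fams = [FamilySpec("P0_0", "P0_1", "F1", 4, "F0")]
        cfg = _config(seed=6, families=fams)
        panel = simdata.drop_families(
            simdata.simulate_founder_populations(cfg), cfg)
        truth = _null_truth()
        eff = simdata.assign_truth_effects(panel, truth, (4, 1, 30_000_000), 1)
        with pytest.raises(KeyError, match="ghost"):
            simdata.simulate_phenotypes(panel, eff, truth,
                                        [PlanCell("T", "1", ["ghost"])], 2)

    def test_same_seed_identical_phenotypes(self):
        a = simdata.recovery_dataset(3, n_loci=300, n_fam=3, fam_size=10)[0]
        b = simdata.recovery_dataset(3, n_loci=300, n_fam=3, fam_size=10)[0]
        pd.testing.assert_frame_equal(a, b)


def test_study_like_config_builds_and_simulates():
    cfg = simdata.study_like_config(seed=0, n_loci=600, family_scale=0.2)
    result = simdata.simulate_dataset(cfg)
    pheno = result.phenotypes
    assert set(pheno["trial"]) == {"F", "G", "K", "S"}
    assert pheno.groupby("cell").size().min() >= 2
    assert int(result.panel.interval_mask(*result.qtl_interval).sum()) == 8
    # TAMU-like overlap: F and G share individuals, K and S do not overlap them
    f_ids = set(pheno.loc[pheno["trial"] == "F", "individual"])
    g_ids = set(pheno.loc[pheno["trial"] == "G", "individual"])
    k_ids = set(pheno.loc[pheno["trial"] == "K", "individual"])
    assert f_ids & g_ids
    assert not (f_ids | g_ids) & k_ids
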