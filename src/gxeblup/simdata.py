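"""Synthetic genotypes, genetic effects and phenotypes with the structure the
analysis assumes.

The generator emulates a set of divergent breeding populations evaluated in
unbalanced multi-trial, multi-season designs: founder populations drawn from a
Balding-Nichols model around common ancestral allele frequencies (so a target
pairwise F_ST can be dialled in), biparental F1/F2 families produced by
recombination of founder gametes (Haldane model, Poisson crossovers, uniform
genetic map), a large-effect additive QTL region, background polygenic
additive effects with a factor-analytic environment covariance, genome-wide
dominance deviations, permanent-environment effects per individual-by-trial,
and heterogeneous per-trial residuals.  A truth table accompanies every
simulated dataset for parameter-recovery testing.

All randomness flows from one master seed through named child streams, so a
configuration plus seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import GenotypePanel, make_cell

#: genetic map density: 1 cM per 200 kb
DEFAULT_MORGANS_PER_BP = 0.01 / 200_000


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    mother: str
    father: str
    ftype: str  # "F1" or "F2"
    n_offspring: int
    prefix: str


@dataclass
class BackgroundTruth:
    """Factor-analytic truth for background additive effects.

    ``loadings`` (q x k) and ``specific`` (q,) define the environment
    covariance Lambda Lambda' + Psi over ``env_labels``; ``env_of_cell`` maps
    each trial-by-season cell to one of those environments.
    """

    env_labels: list[str]
    loadings: np.ndarray
    specific: np.ndarray
    env_of_cell: dict[str, str]

    def __post_init__(self):
        self.loadings = np.atleast_2d(np.asarray(self.loadings, float))
        if self.loadings.shape[0] != len(self.env_labels):
            self.loadings = self.loadings.T
        self.specific = np.asarray(self.specific, float)
        if (self.specific < 0).any():
            raise ValueError("specific variances must be non-negative")

    @property
    def covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.specific)

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.covariance)

    @classmethod
    def uniform(cls, vAB: float, cells: Sequence[str]) -> "BackgroundTruth":
        """Single environment: homogeneous variance, correlation 1 everywhere."""
        return cls(["all"], np.array([[np.sqrt(vAB)]]), np.zeros(1),
                   {c: "all" for c in cells})


@dataclass
class VarianceTruth:
    vAQ: float
    background: BackgroundTruth
    vDW: float
    vU_by_trial: dict[str, float]
    vR_by_trial: dict[str, float]
    fixed_means: dict[str, float]

    def __post_init__(self):
        for name, v in (("vAQ", self.vAQ), ("vDW", self.vDW)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in (self.vU_by_trial, self.vR_by_trial):
            if any(v < 0 for v in d.values()):
                raise ValueError("variances must be >= 0")
        w = np.linalg.eigvalsh(self.background.covariance)
        if w.min() < -1e-8:
            raise ValueError("background environment covariance not PSD")


@dataclass
class PlanCell:
    trial: str
    season: str
    individuals: list[str]

    @property
    def cell(self) -> str:
        return make_cell(self.trial, self.season)


@dataclass
class SimConfig:
    n_populations: int
    fst_target: float
    n_founders_per_pop: int
    family_plan: list[FamilySpec]
    n_chromosomes: int
    n_loci: int
    chrom_length_bp: int
    qtl_interval: tuple  # (chrom, start_bp, end_bp)
    n_qtl_snps: int
    variance_truth: VarianceTruth
    trial_season_plan: list[PlanCell]
    seed: int
    morgans_per_bp: float = DEFAULT_MORGANS_PER_BP

    def __post_init__(self):
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if self.n_founders_per_pop < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")
        if not 1 <= self.qtl_interval[0] <= self.n_chromosomes:
            raise ValueError("QTL interval lies outside simulated chromosomes")
        founders = {
            f"P{p}_{i}"
            for p in range(self.n_populations)
            for i in range(self.n_founders_per_pop)
        }
        for fam in self.family_plan:
            for parent in (fam.mother, fam.father):
                if parent not in founders:
                    raise ValueError(f"family parent {parent!r} not among founders")


def locus_positions(n_loci: int, n_chromosomes: int, chrom_length_bp: int):
    """Evenly spaced 1-based positions; returns (chrom array, pos array)."""
    per = np.full(n_chromosomes, n_loci // n_chromosomes)
    per[: n_loci % n_chromosomes] += 1
    chroms, pos = [], []
    for c in range(n_chromosomes):
        m = per[c]
        step = chrom_length_bp / (m + 1)
        chroms.extend([c + 1] * m)
        pos.extend(int(round((j + 1) * step)) for j in range(m))
    return np.array(chroms), np.array(pos)


def qtl_interval_covering(panel: GenotypePanel, chrom: int, first_locus: int,
                          n_snps: int) -> tuple:
    """Interval (chrom, start, end) spanning ``n_snps`` consecutive loci."""
    on = panel.loci[panel.loci["chrom"] == chrom]
    block = on.iloc[first_locus : first_locus + n_snps]
    if len(block) < n_snps:
        raise ValueError("not enough loci on chromosome for QTL interval")
    return (chrom, int(block["pos"].iloc[0]), int(block["pos"].iloc[-1]))


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# founders and families
# ---------------------------------------------------------------------------

def simulate_founder_populations(config: SimConfig) -> GenotypePanel:
    """Balding-Nichols founders: per-population frequencies drawn Beta around
    common ancestral frequencies with divergence F = ``fst_target``."""
    rng = _streams(config.seed, 4)[0]
    m = config.n_loci
    chrom, pos = locus_positions(m, config.n_chromosomes, config.chrom_length_bp)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    F = config.fst_target
    haps, ids, pops = [], [], []
    for p in range(config.n_populations):
        if F == 0.0:
            p_pop = p_anc
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p_pop = rng.beta(a, b)
        h = rng.random((config.n_founders_per_pop, m, 2)) < p_pop[None, :, None]
        haps.append(h.astype(np.int8))
        ids += [f"P{p}_{i}" for i in range(config.n_founders_per_pop)]
        pops += [f"pop{p}"] * config.n_founders_per_pop
    hap = np.concatenate(haps, axis=0)
    loci = pd.DataFrame({"chrom": chrom, "pos": pos,
                         "ref": "A", "alt": "B"})
    indiv = pd.DataFrame({"id": ids, "population": pops})
    return GenotypePanel(hap.sum(axis=2).astype(float), loci, indiv, haplotypes=hap)


def _gamete(hap: np.ndarray, loci: pd.DataFrame, morgans_per_bp: float,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a phased parent (Haldane, no interference)."""
    out = np.empty(hap.shape[0], dtype=np.int8)
    for chrom, grp in loci.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        length_m = (pos[-1] - pos[0] + 1) * morgans_per_bp
        n_x = rng.poisson(length_m) if length_m > 0 else 0
        start = rng.integers(2)
        if n_x == 0:
            out[idx] = hap[idx, start]
            continue
        xpos = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
        phase = (start + np.searchsorted(xpos, pos)) % 2
        out[idx] = hap[idx, phase]
    return out


def drop_families(founders: GenotypePanel, config: SimConfig) -> GenotypePanel:
    """Produce F1/F2 offspring by recombination and append them to the panel.

    F2 families self a single simulated F1 of the parent pair.  Offspring
    inherit their mother's population label.
    """
    if founders.haplotypes is None:
        raise ValueError("founder panel must carry phased haplotypes")
    rng = _streams(config.seed, 4)[1]
    id_to_row = {v: i for i, v in enumerate(founders.ids)}
    loci = founders.loci
    mbp = config.morgans_per_bp
    haps = [founders.haplotypes]
    ids, pops = list(founders.ids), list(founders.populations)
    for fam in config.family_plan:
        for parent in (fam.mother, fam.father):
            if parent not in id_to_row:
                raise KeyError(f"unknown parent id {parent!r}")
        hm = founders.haplotypes[id_to_row[fam.mother]]
        hf = founders.haplotypes[id_to_row[fam.father]]
        if fam.ftype == "F2":
            f1 = np.stack([_gamete(hm, loci, mbp, rng),
                           _gamete(hf, loci, mbp, rng)], axis=1)
            hm = hf = f1
        elif fam.ftype != "F1":
            raise ValueError(f"unknown family type {fam.ftype!r}")
        kids = np.empty((fam.n_offspring, founders.n_loci, 2), dtype=np.int8)
        for j in range(fam.n_offspring):
            kids[j, :, 0] = _gamete(hm, loci, mbp, rng)
            kids[j, :, 1] = _gamete(hf, loci, mbp, rng)
        haps.append(kids)
        ids += [f"{fam.prefix}_{j}" for j in range(fam.n_offspring)]
        pops += [founders.populations[id_to_row[fam.mother]]] * fam.n_offspring
    hap = np.concatenate(haps, axis=0)
    indiv = pd.DataFrame({"id": ids, "population": pops})
    return GenotypePanel(hap.sum(axis=2).astype(float), loci, indiv, haplotypes=hap)


# ---------------------------------------------------------------------------
# true genetic effects
# ---------------------------------------------------------------------------

@dataclass
class EffectTable:
    """True genomic values per individual (and per background environment).

    Component variances are calibrated *in expectation*: marker effects are
    drawn with variance truth/denominator of the corresponding GRM, so the
    implied relationship-scaled component variance equals the truth value.
    """

    ids: list[str]
    env_labels: list[str]
    env_of_cell: dict[str, str]
    g_qtl: np.ndarray
    g_background: np.ndarray  # n x q
    g_dominance: np.ndarray

    def additive(self, cell: str) -> np.ndarray:
        e = self.env_labels.index(self.env_of_cell[cell])
        return self.g_qtl + self.g_background[:, e]

    def genomic_value(self, cell: str) -> np.ndarray:
        return self.additive(cell) + self.g_dominance

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"individual": self.ids, "g_qtl": self.g_qtl,
                           "g_dominance": self.g_dominance})
        for e, lab in enumerate(self.env_labels):
            df[f"g_background[{lab}]"] = self.g_background[:, e]
        return df


def assign_truth_effects(
    panel: GenotypePanel,
    truth: VarianceTruth,
    qtl_interval: tuple,
    seed: int,
) -> EffectTable:
    """Draw per-locus Gaussian effects realising the truth variances.

    QTL additive effects live on the interval loci, background additive
    effects on the remaining loci with the factor-analytic environment
    structure (factor and specific genomic deviates share the background
    relationship), and dominance deviations use the heterozygosity coding of
    the dominance GRM so that vDW is on the same scale as the fitted
    component.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    in_qtl = panel.interval_mask(*qtl_interval)
    if not in_qtl.any():
        raise ValueError("QTL interval contains no loci")
    freqs = panel.allele_frequencies()
    poly = (freqs > 0) & (freqs < 1)
    n = panel.n_individuals

    def additive_values(mask: np.ndarray, variance: float, size: int = 1):
        use = mask & poly
        p = freqs[use]
        denom = 2.0 * np.sum(p * (1 - p))
        Z = panel.dosage[:, use] - 2.0 * p
        a = rng.normal(0.0, np.sqrt(variance / denom), size=(use.sum(), size))
        return Z @ a

    g_qtl = additive_values(in_qtl, truth.vAQ)[:, 0] if truth.vAQ > 0 else np.zeros(n)

    bg = truth.background
    q, k = bg.loadings.shape
    factors = additive_values(~in_qtl, 1.0, size=k)  # unit-variance genomic factors
    g_bg = factors @ bg.loadings.T
    if (bg.specific > 0).any():
        spec = additive_values(~in_qtl, 1.0, size=q)
        g_bg = g_bg + spec * np.sqrt(bg.specific)[None, :]
    if not np.any(np.abs(bg.loadings) > 0) and not np.any(bg.specific > 0):
        g_bg = np.zeros((n, q))

    if truth.vDW > 0:
        use = poly
        p = freqs[use]
        qf = 1 - p
        M = panel.dosage[:, use]
        W = np.where(M == 0.0, -2.0 * p**2,
                     np.where(M == 1.0, 2.0 * p * qf, -2.0 * qf**2))
        denom = np.sum((2.0 * p * qf) ** 2)
        d = rng.normal(0.0, np.sqrt(truth.vDW / denom), size=use.sum())
        g_dom = W @ d
    else:
        g_dom = np.zeros(n)

    return EffectTable(panel.ids, list(bg.env_labels), dict(bg.env_of_cell),
                       g_qtl, g_bg, g_dom)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    panel: GenotypePanel,
    effects: EffectTable,
    truth: VarianceTruth,
    plan: Sequence[PlanCell],
    seed: int,
) -> pd.DataFrame:
    """y = cell mean + additive + dominance + permanent environment + residual.

    One permanent-environment draw per individual-by-trial, one residual draw
    per record; unbalanced plans are supported directly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    id_to_row = {v: i for i, v in enumerate(effects.ids)}
    pop_of = dict(zip(panel.ids, panel.populations))
    trials = sorted({pc.trial for pc in plan})
    pe: dict[tuple[str, str], float] = {}
    for t in trials:
        vU = truth.vU_by_trial.get(t, 0.0)
        inds = sorted({i for pc in plan if pc.trial == t for i in pc.individuals})
        draws = rng.normal(0.0, np.sqrt(vU), size=len(inds))
        pe.update({(i, t): d for i, d in zip(inds, draws)})
    rows = []
    for pc in plan:
        cell = pc.cell
        mu = truth.fixed_means.get(cell, 0.0)
        vR = truth.vR_by_trial.get(pc.trial, 0.0)
        g_cell = effects.genomic_value(cell)
        for ind in pc.individuals:
            if ind not in id_to_row:
                raise KeyError(f"individual {ind!r} in plan but not in panel")
            y = (mu + g_cell[id_to_row[ind]] + pe[(ind, pc.trial)]
                 + rng.normal(0.0, np.sqrt(vR)))
            rows.append({"individual": ind, "trial": pc.trial,
                         "season": pc.season, "cell": cell,
                         "population": pop_of.get(ind, "NA"), "value": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end helper and study-like defaults
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    panel: GenotypePanel
    effects: EffectTable
    phenotypes: pd.DataFrame
    qtl_interval: tuple


def simulate_dataset(config: SimConfig) -> SimResult:
    """Founders -> families -> effects -> phenotypes, all from ``config.seed``."""
    founders = simulate_founder_populations(config)
    panel = drop_families(founders, config)
    n_in = int(panel.interval_mask(*config.qtl_interval).sum())
    if n_in != config.n_qtl_snps:
        raise ValueError(
            f"QTL interval covers {n_in} loci, expected {config.n_qtl_snps}")
    child = np.random.SeedSequence(config.seed).spawn(4)
    effects = assign_truth_effects(panel, config.variance_truth,
                                   config.qtl_interval,
                                   seed=int(child[2].generate_state(1)[0] % 2**31))
    pheno = simulate_phenotypes(panel, effects, config.variance_truth,
                                config.trial_season_plan,
                                seed=int(child[3].generate_state(1)[0] % 2**31))
    return SimResult(config, panel, effects, pheno, config.qtl_interval)


# -- benchmark scenarios ----------------------------------------------------
#
# The scenario builders below pin down the simulation conditions used for
# parameter-recovery, model-selection and prediction-accuracy benchmarking:
# family-structured panels (F1 families from a common founder pool), a
# large-effect QTL region of 8 SNPs, background polygenic variance ~0.65,
# QTL variance ~0.13-0.25, dominance ~0.1, permanent-environment 0.05 and
# residual 0.30 per trial -- the magnitudes of the fitted study components.


def recovery_dataset(seed: int, n_loci: int = 2000, n_fam: int = 10,
                     fam_size: int = 20, n_seasons: int = 3,
                     vAQ: float = 0.25, vAB: float = 0.60, vDW: float = 0.10,
                     vU: float = 0.05, vR: float = 0.30):
    """One trial, ``n_seasons`` repeated records per individual, uniform
    background: the variance-component recovery benchmark.

    Returns (phenotypes, panel of phenotyped individuals, qtl_interval,
    truth).  Truth effects are calibrated on the phenotyped panel so that the
    fitted GRMs and the generating relationship agree.
    """
    nf = max(2 * n_fam, 4)
    fams = [FamilySpec(f"P0_{2*i}", f"P0_{2*i+1}", "F1", fam_size, f"F{i}")
            for i in range(n_fam)]
    seasons = [str(s) for s in range(1, n_seasons + 1)]
    cells = [make_cell("T", s) for s in seasons]
    bg = BackgroundTruth.uniform(vAB, cells)
    truth = VarianceTruth(vAQ=vAQ, background=bg, vDW=vDW,
                          vU_by_trial={"T": vU}, vR_by_trial={"T": vR},
                          fixed_means={c: 10.0 + i for i, c in enumerate(cells)})
    chrom, pos = locus_positions(n_loci, 8, 30_000_000)
    on4 = pos[chrom == 4]
    q0 = min(40, len(on4) - 8)
    cfg = SimConfig(1, 0.0, nf, fams, 8, n_loci, 30_000_000,
                    (4, int(on4[q0]), int(on4[q0 + 7])), 8, truth, [], seed)
    panel = drop_families(simulate_founder_populations(cfg), cfg)
    ids = [i for i in panel.ids if not i.startswith("P0_")]
    sub = panel.subset(individuals=ids)
    effects = assign_truth_effects(sub, truth, cfg.qtl_interval, seed=seed + 1)
    plan = [PlanCell("T", s, ids) for s in seasons]
    pheno = simulate_phenotypes(sub, effects, truth, plan, seed=seed + 2)
    return pheno, sub, cfg.qtl_interval, truth


def two_trial_dataset(seed: int, background: str = "uniform",
                      n_loci: int = 1200, n_fam: int = 10, fam_size: int = 30,
                      vAQ: float = 0.13, vAB: float = 0.65, vDW: float = 0.10,
                      vU: float = 0.05, vR: float = 0.30,
                      divergent_corr_share: float = 0.0025,
                      partial_last_cell: bool = False):
    """Two trials x two seasons, individuals split between trials.

    ``background`` is ``"uniform"`` (no G-by-E: correlation 1, equal
    variances everywhere), ``"divergent"`` (the last trial-by-season cell
    shares only ``divergent_corr_share`` of its background variance with the
    common factor, i.e. a background correlation of about
    sqrt(divergent_corr_share) with the main group) or ``"per_trial"``
    (three environments -- trial 1, and each season of trial 2 -- with
    pairwise background correlation 0.5).  ``partial_last_cell`` assesses
    only half the trial-2 individuals in the last cell, creating a
    trial-tested cohort.

    Returns (phenotypes, panel of phenotyped individuals, qtl_interval,
    truth, true environment map).
    """
    nf = max(2 * n_fam, 4)
    fams = [FamilySpec(f"P0_{2*i}", f"P0_{2*i+1}", "F1", fam_size, f"F{i}")
            for i in range(n_fam)]
    cells = [make_cell("T1", "a"), make_cell("T1", "b"),
             make_cell("T2", "a"), make_cell("T2", "b")]
    if background == "uniform":
        bg = BackgroundTruth.uniform(vAB, cells)
        env_map = {c: "all" for c in cells}
    elif background == "divergent":
        lam = np.array([[np.sqrt(vAB)]] * 3
                       + [[np.sqrt(vAB * divergent_corr_share)]])
        psi = np.array([0.0, 0.0, 0.0, vAB * (1.0 - divergent_corr_share)])
        bg = BackgroundTruth(cells, lam, psi, {c: c for c in cells})
        env_map = {cells[0]: "main", cells[1]: "main", cells[2]: "main",
                   cells[3]: "div"}
    elif background == "per_trial":
        env_labels = ["E1", "E2a", "E2b"]
        lam = np.full((3, 1), np.sqrt(0.5 * vAB))
        psi = np.full(3, 0.5 * vAB)
        e_of_c = {cells[0]: "E1", cells[1]: "E1",
                  cells[2]: "E2a", cells[3]: "E2b"}
        bg = BackgroundTruth(env_labels, lam, psi, e_of_c)
        env_map = dict(e_of_c)
    else:
        raise ValueError(f"unknown background scenario {background!r}")
    truth = VarianceTruth(vAQ=vAQ, background=bg, vDW=vDW,
                          vU_by_trial={"T1": vU, "T2": vU},
                          vR_by_trial={"T1": vR, "T2": vR},
                          fixed_means={c: 10.0 + i for i, c in enumerate(cells)})
    chrom, pos = locus_positions(n_loci, 8, 30_000_000)
    on4 = pos[chrom == 4]
    q0 = min(40, len(on4) - 9)
    cfg = SimConfig(1, 0.0, nf, fams, 8, n_loci, 30_000_000,
                    (4, int(on4[q0]), int(on4[q0 + 7])), 8, truth, [], seed)
    panel = drop_families(simulate_founder_populations(cfg), cfg)
    ids = [i for i in panel.ids if not i.startswith("P0_")]
    sub = panel.subset(individuals=ids)
    effects = assign_truth_effects(sub, truth, cfg.qtl_interval, seed=seed + 1)
    half = len(ids) // 2
    g1, g2 = ids[:half], ids[half:]
    plan = [PlanCell("T1", "a", g1), PlanCell("T1", "b", g1),
            PlanCell("T2", "a", g2),
            PlanCell("T2", "b", g2[: len(g2) // 2] if partial_last_cell else g2)]
    pheno = simulate_phenotypes(sub, effects, truth, plan, seed=seed + 2)
    return pheno, sub, cfg.qtl_interval, truth, env_map


def _subsample(rng, ids, frac):
    k = int(round(frac * len(ids)))
    return sorted(rng.choice(ids, size=k, replace=False).tolist())


def study_like_config(
    seed: int = 0,
    n_loci: int = 4500,
    founder_scale: float = 1.0,
    family_scale: float = 1.0,
) -> SimConfig:
    """A configuration emulating the study's population and trial structure.

    Three divergent breeding populations (pairwise F_ST about 0.10), nine
    F1 families for the first program evaluated in two trials (F, G) over two
    seasons each with strong overlap, six F1 families in trial K over three
    seasons (coded K0/K1/K2), and twelve F1 plus three F2 families in trial S
    over three seasons.  The background additive truth uses a rank-1 factor
    structure in which the last two S seasons are weakly correlated with the
    main group of environments, QTL and dominance effects are uniform across
    environments, and per-trial permanent-environment and residual variances
    are heterogeneous.
    """
    rng = np.random.default_rng(seed)
    nf = max(4, int(round(10 * founder_scale)))

    def fam(pop, idx, ftype, size):
        pair = rng.choice(nf, size=2, replace=False)
        return FamilySpec(f"P{pop}_{pair[0]}", f"P{pop}_{pair[1]}", ftype,
                          max(2, int(round(size * family_scale))), f"pop{pop}F{idx}")

    plan_sizes0 = [8, 12, 15, 20, 25, 30, 40, 60, 87]
    plan_sizes1 = [10, 15, 20, 25, 35, 44]
    plan_sizes2 = [6, 8, 10, 12, 14, 16, 18, 20, 22, 22, 22, 22]
    families = (
        [fam(0, i, "F1", s) for i, s in enumerate(plan_sizes0)]
        + [fam(1, i, "F1", s) for i, s in enumerate(plan_sizes1)]
        + [fam(2, i, "F1", s) for i, s in enumerate(plan_sizes2)]
        + [fam(2, 12 + i, "F2", s) for i, s in enumerate([22, 40, 66])]
    )

    cells = {
        "F": ["2011", "2012"], "G": ["2012", "2013"],
        "K": ["2010", "2011", "2012"], "S": ["2010", "2011", "2012"],
    }
    env_of_cell = {}
    for t, seasons in cells.items():
        for s in seasons:
            c = make_cell(t, s)
            if t in ("F", "G"):
                env_of_cell[c] = t
            elif t == "K":
                # first two K seasons share an environment with the last S season
                env_of_cell[c] = "K01S2" if s in ("2010", "2011") else "K2"
            else:
                env_of_cell[c] = {"2010": "S0", "2011": "S1", "2012": "K01S2"}[s]
    env_labels = ["F", "G", "K01S2", "K2", "S0", "S1"]
    vAB = {"F": 0.82, "G": 0.98, "K01S2": 0.48, "K2": 0.48, "S0": 0.50, "S1": 0.45}
    lam, psi = [], []
    for e in env_labels:
        share = 0.85 if e not in ("S0", "S1") else 0.08
        lam.append(np.sqrt(share * vAB[e]))
        psi.append((1 - share) * vAB[e])
    background = BackgroundTruth(env_labels, np.array([lam]).T, np.array(psi),
                                 env_of_cell)
    truth = VarianceTruth(
        vAQ=0.26, background=background, vDW=0.12,
        vU_by_trial={"F": 0.01, "G": 0.21, "K": 0.02, "S": 0.05},
        vR_by_trial={"F": 0.28, "G": 0.33, "K": 0.43, "S": 0.17},
        fixed_means={make_cell(t, s): m for t, seasons in cells.items()
                     for s, m in zip(seasons, {"F": [11.9, 11.8],
                                               "G": [12.3, 12.8],
                                               "K": [12.1, 16.0, 17.1],
                                               "S": [11.5, 12.3, 11.7]}[t])},
    )

    chrom_len = 30_000_000
    chrom, pos = locus_positions(n_loci, 8, chrom_len)
    on4 = pos[chrom == 4]
    i0 = len(on4) // 3
    qtl = (4, int(on4[i0]), int(on4[i0 + 7]))

    # trial-by-season assessment plan with Table-1A-like overlap
    pop_members = {p: [] for p in range(3)}
    for famspec in families:
        pop = int(famspec.prefix[3])
        pop_members[pop] += [f"{famspec.prefix}_{j}"
                             for j in range(max(2, int(round(
                                 famspec.n_offspring))))]
    plan = []
    tamu = pop_members[0]
    for t, fr in (("F", [0.75, 0.95]), ("G", [0.35, 0.8])):
        for s, f in zip(cells[t], fr):
            plan.append(PlanCell(t, s, _subsample(rng, tamu, f)))
    for t, pop, fr in (("K", 1, [0.4, 0.9, 0.9]), ("S", 2, [0.3, 0.9, 0.7])):
        for s, f in zip(cells[t], fr):
            plan.append(PlanCell(t, s, _subsample(rng, pop_members[pop], f)))

    return SimConfig(
        n_populations=3, fst_target=0.10, n_founders_per_pop=nf,
        family_plan=families, n_chromosomes=8, n_loci=n_loci,
        chrom_length_bp=chrom_len, qtl_interval=qtl, n_qtl_snps=8,
        variance_truth=truth, trial_season_plan=plan, seed=seed,
    )
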