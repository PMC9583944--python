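"""Genotype QC and genomic relationship matrices.

Additive GRMs follow VanRaden's first method, G = ZZ' / (2 * sum p_j q_j) with
Z the dosage matrix centred at twice the allele frequency.  Dominance GRMs
follow Vitezica's orthogonal parameterisation: genotype classes (0, 1, 2) are
coded (-2q^2, 2pq, -2p^2) and D = WW' / sum (2 p_j q_j)^2, which is orthogonal
to the additive GRM in expectation under Hardy-Weinberg equilibrium.

Allele frequencies default to the supplied panel but may be passed explicitly,
so that single-trial GRMs (frequencies from one trial's individuals) and
all-individual GRMs can be built from the same panel.  Near-singular GRMs are
made positive definite by *bending*: eigenvalues floored at a small epsilon
and the matrix reconstructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import GRM, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-rule removal counts from :func:`filter_snps`."""

    n_loci_in: int = 0
    n_individuals_in: int = 0
    n_loci_maf: int = 0
    n_loci_missing: int = 0
    n_individuals_missing: int = 0
    n_loci_out: int = 0
    n_individuals_out: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_snps(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    max_missing_locus: float = 1.0,
    max_missing_indiv: float = 1.0,
) -> tuple[GenotypePanel, QCReport]:
    """Remove loci with MAF strictly below ``maf_min`` or excess missingness.

    The MAF comparison is strict ("lower than"), so a locus at exactly the
    threshold is retained.  Individuals whose missing fraction exceeds
    ``max_missing_indiv`` are removed first, then locus rules are applied.
    """
    for name, v in (("maf_min", maf_min), ("max_missing_locus", max_missing_locus),
                    ("max_missing_indiv", max_missing_indiv)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    report = QCReport(n_loci_in=panel.n_loci, n_individuals_in=panel.n_individuals)

    miss_ind = np.isnan(panel.dosage).mean(axis=1)
    keep_ind = miss_ind <= max_missing_indiv
    report.n_individuals_missing = int((~keep_ind).sum())
    ids = [i for i, k in zip(panel.ids, keep_ind) if k]
    panel = panel.subset(individuals=ids)

    freqs = panel.allele_frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    miss_loc = np.isnan(panel.dosage).mean(axis=0)
    fail_maf = maf < maf_min
    fail_miss = miss_loc > max_missing_locus
    report.n_loci_maf = int(fail_maf.sum())
    report.n_loci_missing = int((fail_miss & ~fail_maf).sum())
    keep_loc = ~(fail_maf | fail_miss)
    if not keep_loc.any():
        raise ValueError("all loci removed by QC filters")
    panel = panel.subset(locus_mask=keep_loc)
    report.n_loci_out = panel.n_loci
    report.n_individuals_out = panel.n_individuals
    return panel, report


def impute_missing(
    panel: GenotypePanel, seed: int | None = None, mode: str = "sample"
) -> GenotypePanel:
    """Fill missing dosages.

    ``mode="sample"`` draws each missing dosage Binomial(2, p) at the locus
    allele frequency; ``mode="mean"`` uses the locus mean dosage
    deterministically.  A stand-in for haplotype-phasing-based imputation,
    adequate for GRM construction where only locus means/variances matter.
    """
    miss = np.isnan(panel.dosage)
    if not miss.any():
        return panel
    freqs = panel.allele_frequencies()
    if np.isnan(freqs).any():
        bad = np.where(np.isnan(freqs))[0]
        raise ValueError(f"loci entirely missing: {bad.tolist()}")
    dosage = panel.dosage.copy()
    if mode == "sample":
        rng = np.random.default_rng(seed)
        rows, cols = np.where(miss)
        dosage[rows, cols] = rng.binomial(2, freqs[cols]).astype(float)
    elif mode == "mean":
        rows, cols = np.where(miss)
        dosage[rows, cols] = 2.0 * freqs[cols]
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    return GenotypePanel(dosage, panel.loci, panel.individuals,
                         haplotypes=panel.haplotypes)


def _check_complete(panel: GenotypePanel) -> None:
    if np.isnan(panel.dosage).any():
        raise ValueError("dosage matrix has missing values; impute first")


def _usable_loci(freqs: np.ndarray) -> np.ndarray:
    """Loci with 0 < p < 1; monomorphic loci have undefined 2pq scaling."""
    usable = (freqs > 0.0) & (freqs < 1.0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("dropping %d monomorphic loci from GRM", n_dropped)
    if not usable.any():
        raise ValueError("no polymorphic loci available for GRM")
    return usable


def additive_grm(
    panel: GenotypePanel,
    freqs: np.ndarray | None = None,
    locus_scope: str = "genome-wide",
) -> GRM:
    """VanRaden (method 1) additive GRM: G = ZZ'/(2 sum p_j q_j), Z = M - 2p."""
    _check_complete(panel)
    if freqs is None:
        freqs = panel.allele_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    usable = _usable_loci(freqs)
    p = freqs[usable]
    Z = panel.dosage[:, usable] - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return GRM(G, panel.ids, effect_kind="additive", locus_scope=locus_scope,
               allele_freqs_used=freqs, n_loci=int(usable.sum()))


def dominance_grm(
    panel: GenotypePanel,
    freqs: np.ndarray | None = None,
    locus_scope: str = "genome-wide",
) -> GRM:
    """Dominance GRM, orthogonal coding: D = WW' / sum (2 p_j q_j)^2.

    Genotype classes (0, 1, 2 copies of the alternate allele at frequency p)
    are coded (-2p^2, 2pq, -2q^2), which has zero mean and is orthogonal to
    the additive contrast under Hardy-Weinberg proportions, with
    E[w^2] = (2pq)^2 so the diagonal averages 1.
    """
    _check_complete(panel)
    if freqs is None:
        freqs = panel.allele_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    usable = _usable_loci(freqs)
    p = freqs[usable]
    q = 1.0 - p
    M = panel.dosage[:, usable]
    W = np.where(M == 0.0, -2.0 * p**2, np.where(M == 1.0, 2.0 * p * q, -2.0 * q**2))
    denom = np.sum((2.0 * p * q) ** 2)
    D = (W @ W.T) / denom
    D = 0.5 * (D + D.T)
    return GRM(D, panel.ids, effect_kind="dominance", locus_scope=locus_scope,
               allele_freqs_used=freqs, n_loci=int(usable.sum()))


def partition_qtl_background(
    panel: GenotypePanel,
    interval: tuple,
    freqs: np.ndarray | None = None,
    effect_kind: str = "additive",
) -> tuple[GRM, GRM]:
    """Split loci at a (chrom, start_bp, end_bp) interval into QTL vs background GRMs.

    The two locus scopes are disjoint and their union is all loci.  The same
    constructor (additive or dominance) is used for both scopes.
    """
    chrom, start_bp, end_bp = interval
    in_qtl = panel.interval_mask(chrom, start_bp, end_bp)
    if not in_qtl.any():
        raise ValueError(f"no loci in QTL interval {interval}")
    if in_qtl.all():
        raise ValueError("QTL interval covers every locus; background set empty")
    build = additive_grm if effect_kind == "additive" else dominance_grm
    fq = None if freqs is None else np.asarray(freqs)[in_qtl]
    fb = None if freqs is None else np.asarray(freqs)[~in_qtl]
    g_qtl = build(panel.subset(locus_mask=in_qtl), freqs=fq, locus_scope="qtl")
    g_bg = build(panel.subset(locus_mask=~in_qtl), freqs=fb, locus_scope="background")
    return g_qtl, g_bg


def bend_grm(grm: GRM, epsilon: float = 1e-6) -> GRM:
    """Floor eigenvalues at ``epsilon`` and reconstruct (bending).

    Returns the input unchanged (``bent=False``) when already positive
    definite with smallest eigenvalue >= epsilon.
    """
    A = grm.matrix
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("bend_grm requires a symmetric matrix")
    w, V = np.linalg.eigh(A)
    if w[0] >= epsilon:
        return grm
    w_clipped = np.maximum(w, epsilon)
    B = (V * w_clipped) @ V.T
    B = 0.5 * (B + B.T)
    return grm.with_matrix(B, bent=True, bend_epsilon=epsilon)
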