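"""Population-structure and linkage-disequilibrium diagnostics.

F_ST between population pairs uses the Weir-Cockerham variance-components
estimator combined across loci as a ratio of sums (sum of `a` components over
sum of `a+b+c`), computed directly from dosage data (observed heterozygote
counts enter the `b`/`c` components).  LD is the squared Pearson correlation
of dosages (composite r^2; phase is out of scope) between intra-chromosomal
locus pairs, and its decay with physical distance is smoothed with a
second-order (locally quadratic) LOESS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _wc_components(d1: np.ndarray, d2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham per-locus a and a+b+c for two populations of dosages."""
    r = 2
    n1 = (~np.isnan(d1)).sum(axis=0).astype(float)
    n2 = (~np.isnan(d2)).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p1 = np.nanmean(d1, axis=0) / 2.0
        p2 = np.nanmean(d2, axis=0) / 2.0
        h1 = np.nanmean(d1 == 1.0, axis=0)
        h2 = np.nanmean(d2 == 1.0, axis=0)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, a + b + c


def pairwise_fst(panel: GenotypePanel, pop_labels=None) -> pd.DataFrame:
    """Multi-locus Weir-Cockerham F_ST for every population pair.

    Returns a symmetric DataFrame (population x population, 0 diagonal).
    Loci monomorphic across a pair contribute zero to both sums and thus
    drop out naturally.
    """
    labels = np.asarray(pop_labels if pop_labels is not None else panel.populations)
    pops = sorted(pd.unique(labels).tolist())
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for p in pops:
        if (labels == p).sum() < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    out = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            d1 = panel.dosage[labels == pops[i]]
            d2 = panel.dosage[labels == pops[j]]
            a, abc = _wc_components(d1, d2)
            ok = np.isfinite(a) & np.isfinite(abc)
            denom = np.sum(abc[ok])
            theta = np.sum(a[ok]) / denom if denom > 0 else 0.0
            out[i, j] = out[j, i] = theta
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# allele-frequency / GRM similarity with the pooled panel
# ---------------------------------------------------------------------------

@dataclass
class DivergenceReport:
    pairwise_fst: pd.DataFrame
    allele_freq_correlations: dict[str, float]
    grm_offdiag_correlations: dict[str, float]


def allele_freq_and_grm_correlations(
    panel: GenotypePanel, pop_labels=None
) -> DivergenceReport:
    """Similarity of each population with the pooled panel.

    The minor allele is defined on the *pooled* panel; each population's local
    frequency of that allele is correlated (Pearson) with the pooled frequency.
    GRM similarity is the correlation of off-diagonal entries of the
    population-local additive GRM (local frequencies) with the same entries of
    the pooled-frequency GRM restricted to that population's individuals.
    """
    from .genomics import additive_grm

    labels = np.asarray(pop_labels if pop_labels is not None else panel.populations)
    pops = sorted(pd.unique(labels).tolist())
    pooled = panel.allele_frequencies()
    # frequency of the pooled-minor allele
    flip = pooled > 0.5
    pooled_maf = np.where(flip, 1.0 - pooled, pooled)
    if np.allclose(pooled_maf, pooled_maf[0]):
        raise ValueError("pooled allele frequencies are constant; correlation undefined")

    pooled_grm = additive_grm(panel)
    fst = pairwise_fst(panel, labels) if len(pops) >= 2 else pd.DataFrame(
        [[0.0]], index=pops, columns=pops
    )
    freq_corr: dict[str, float] = {}
    grm_corr: dict[str, float] = {}
    for p in pops:
        mask = labels == p
        sub = panel.subset(individuals=[i for i, m in zip(panel.ids, mask) if m])
        local = sub.allele_frequencies()
        local_maf = np.where(flip, 1.0 - local, local)
        freq_corr[p] = float(np.corrcoef(local_maf, pooled_maf)[0, 1])
        local_grm = additive_grm(sub)
        pooled_sub = pooled_grm.align(sub.ids)
        iu = np.triu_indices(len(sub.ids), k=1)
        grm_corr[p] = float(np.corrcoef(local_grm.matrix[iu], pooled_sub[iu])[0, 1])
    return DivergenceReport(fst, freq_corr, grm_corr)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def loess_quadratic(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float = 0.3
) -> np.ndarray:
    """Locally weighted quadratic (degree-2) regression with tricube weights."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    k = max(int(np.ceil(span * n)), 5)
    fitted = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argpartition(d, min(k, n) - 1)[:k]
        dk = d[idx]
        h = dk.max()
        w = (1 - (dk / h) ** 3) ** 3 if h > 0 else np.ones_like(dk)
        X = np.vander(x[idx] - x0, 3, increasing=True)  # [1, dx, dx^2]
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y[idx], rcond=None)
        fitted[i] = beta[0]
    return fitted


@dataclass
class LDDecayResult:
    records: pd.DataFrame          # locus pair ids, distance bp, r2
    curve: pd.DataFrame | None     # grid distance, fitted r2
    mean_r2: float
    half_max_distance: float | None

    def fitted_at(self, distance_bp: float) -> float:
        if self.curve is None:
            raise ValueError("no LOESS curve available")
        return float(np.interp(distance_bp, self.curve["distance"], self.curve["r2"]))


def ld_decay(
    panel: GenotypePanel,
    max_distance_bp: int = 2_000_000,
    n_grid: int = 200,
    span: float = 0.3,
) -> LDDecayResult:
    """r^2 for intra-chromosomal pairs within ``max_distance_bp`` + LOESS decay curve.

    Monomorphic loci are excluded.  The half-max distance is where the fitted
    curve first falls to half its maximum (linear interpolation on the grid);
    None when the curve never reaches half-max or was omitted (<10 pairs).
    """
    _d = panel.dosage
    if np.isnan(_d).any():
        raise ValueError("impute missing dosages before LD computation")
    freqs = panel.allele_frequencies()
    poly = (freqs > 0) & (freqs < 1)
    records = []
    for chrom, grp in panel.loci.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        idx = idx[poly[idx]]
        if len(idx) < 2:
            continue
        pos = panel.loci["pos"].to_numpy()[idx]
        D = panel.dosage[:, idx]
        R = np.corrcoef(D.T)
        ii, jj = np.triu_indices(len(idx), k=1)
        dist = pos[jj] - pos[ii]
        keep = dist <= max_distance_bp
        records.append(pd.DataFrame({
            "chrom": chrom,
            "locus_i": idx[ii[keep]],
            "locus_j": idx[jj[keep]],
            "distance": dist[keep],
            "r2": R[ii[keep], jj[keep]] ** 2,
        }))
    if not records:
        raise ValueError("no intra-chromosomal locus pairs available")
    table = pd.concat(records, ignore_index=True)
    mean_r2 = float(table["r2"].mean())
    if len(table) < 10:
        logger.warning("fewer than 10 LD pairs; LOESS curve omitted")
        return LDDecayResult(table, None, mean_r2, None)
    grid = np.linspace(0, min(max_distance_bp, table["distance"].max()), n_grid)
    fitted = loess_quadratic(table["distance"], table["r2"], grid, span=span)
    curve = pd.DataFrame({"distance": grid, "r2": fitted})
    # distance at 50% of maximum LD, searched from the curve's peak outward
    peak = int(np.argmax(fitted))
    half = fitted[peak] / 2.0
    half_dist = None
    below = peak + np.where(fitted[peak:] <= half)[0]
    if len(below):
        i = int(below[0])
        if i == peak:
            half_dist = float(grid[peak])
        else:
            x0, x1, y0, y1 = grid[i - 1], grid[i], fitted[i - 1], fitted[i]
            half_dist = (float(x0 + (y0 - half) / (y0 - y1) * (x1 - x0))
                         if y0 != y1 else float(x1))
    return LDDecayResult(table, curve, mean_r2, half_dist)


# ---------------------------------------------------------------------------
# QTL joint genotypes
# ---------------------------------------------------------------------------

def unique_joint_genotypes(
    panel: GenotypePanel, interval: tuple, pop_labels=None
) -> pd.DataFrame:
    """Distinct joint-genotype classes over the interval loci, by population.

    Each individual maps to the tuple of dosages at the interval loci.  The
    returned population-by-population matrix holds the number of distinct
    classes within each population on the diagonal and the number of classes
    shared between the pair off-diagonal.
    """
    chrom, start_bp, end_bp = interval
    mask = panel.interval_mask(chrom, start_bp, end_bp)
    if not mask.any():
        raise ValueError(f"no loci in interval {interval}")
    D = panel.dosage[:, mask]
    if np.isnan(D).any():
        raise ValueError("missing dosages in interval; impute first")
    labels = np.asarray(pop_labels if pop_labels is not None else panel.populations)
    pops = sorted(pd.unique(labels).tolist())
    classes = {p: {tuple(row) for row in D[labels == p]} for p in pops}
    out = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for i, p in enumerate(pops):
        for j, q in enumerate(pops):
            out.iloc[i, j] = len(classes[p] & classes[q]) if i != j else len(classes[p])
    return out
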