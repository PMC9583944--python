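"""Genomic-architecture summaries: heritabilities, genomic correlations,
Ward dendrograms, and the environment/individual biplot.

Narrow-sense heritability h2 = vA / vP and broad-sense H2 = vGW / vP with
vGW = vA + vD and vP = vGW + vU + vR per trial-by-genomic-environment; the
identities hold to machine precision by construction.  Environment
correlation matrices come from the (FA-expanded) genomic covariance; the
dendrogram uses the Euclidean transform d = sqrt(2 (1 - r)) with Ward's
minimum-variance linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .mme.model import ModelFit

logger = logging.getLogger(__name__)


def heritability_from_components(vA: float, vD: float, vU: float, vR: float):
    """(vGW, vP, h2, H2) from the component identities."""
    vGW = vA + vD
    vP = vGW + vU + vR
    if vP <= 0:
        raise ValueError("phenotypic variance must be positive")
    return vGW, vP, vA / vP, vGW / vP


def heritability_table(fit: ModelFit) -> pd.DataFrame:
    """One record per trial x genomic environment with variance partitions.

    vA sums the environment variance of every additive term (QTL +
    background in a partitioned model), vD of every dominance term; vU and vR
    are the trial's permanent-environment and residual variances (0 when the
    model has no permanent-environment term).
    """
    add_terms = [t.name for t in fit.spec.terms if t.effect == "additive"]
    dom_terms = [t.name for t in fit.spec.terms if t.effect == "dominance"]
    target = fit.target_env_map(add_terms + dom_terms)
    vA = fit.env_variance(add_terms, target) if add_terms else None
    vD = fit.env_variance(dom_terms, target) if dom_terms else None

    vU = {}
    if fit.spec.permanent_env:
        t = fit.term("perm_env")
        theta = fit.result.params_for("perm_env")
        vU = dict(zip(t.env_labels, theta))
    tr = fit.term("residual")
    vR = dict(zip(tr.env_labels, fit.result.params_for("residual")))

    cells = fit.observed_cells()
    trial_of_cell = dict(zip(fit.pheno["cell"], fit.pheno["trial"]))
    rows = []
    seen = set()
    for c in cells:
        trial, env = trial_of_cell[c], target[c]
        if (trial, env) in seen:
            continue
        seen.add((trial, env))
        a = float(vA[env]) if vA is not None else 0.0
        d = float(vD[env]) if vD is not None else 0.0
        u = float(vU.get(trial, 0.0))
        r = float(vR.get(trial, vR.get("all", 0.0)))
        vGW, vP, h2, H2 = heritability_from_components(a, d, u, r)
        rows.append({"trial": trial, "env": env, "vA": a, "vD": d,
                     "vGW": vGW, "vU": u, "vR": r, "vP": vP,
                     "h2": h2, "H2": H2})
    return pd.DataFrame(rows)


def genomic_correlation_matrix(fit: ModelFit, effect: str = "additive") -> pd.DataFrame:
    """Environment correlation of genomic effects.

    ``effect`` is ``"additive"``, ``"dominance"`` or ``"total"``; covariances
    of the contributing terms are summed on the finest common environment
    grid before standardising.
    """
    if effect == "total":
        names = [t.name for t in fit.spec.terms if t.effect in ("additive", "dominance")]
    else:
        names = [t.name for t in fit.spec.terms if t.effect == effect]
    if not names:
        raise ValueError(f"no terms with effect {effect!r}")
    target = fit.target_env_map(names)
    envs = sorted(set(target.values()))
    S = np.zeros((len(envs), len(envs)))
    for name in names:
        t, ts = fit.term(name), fit.spec_term(name)
        sigma = fit.result.sigma_for(name)
        emap = fit._term_env_of_target(t, ts, target)
        idx = np.array([emap[e] for e in envs])
        S += sigma[np.ix_(idx, idx)]
    v = np.diag(S)
    if (v <= 0).any():
        bad = [e for e, vv in zip(envs, v) if vv <= 0]
        raise ValueError(f"zero genomic variance in environments {bad}")
    R = S / np.sqrt(np.outer(v, v))
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=envs, columns=envs)


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray

    def merge_order(self) -> list[tuple[frozenset, float]]:
        """Clusters in merge order with their heights."""
        clusters = {i: frozenset([self.labels[i]]) for i in range(len(self.labels))}
        out = []
        n = len(self.labels)
        for step, (a, b, h, _cnt) in enumerate(self.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + step] = merged
            out.append((merged, float(h)))
        return out

    def to_newick(self) -> str:
        node = {i: self.labels[i] for i in range(len(self.labels))}
        height = {i: 0.0 for i in range(len(self.labels))}
        n = len(self.labels)
        for step, (a, b, h, _c) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + step] = h
        return node[n + len(self.linkage) - 1] + ";"


def correlation_to_distance(corr: np.ndarray) -> np.ndarray:
    """d_ij = sqrt(2 (1 - r_ij)), the Euclidean transform of a correlation."""
    return np.sqrt(np.maximum(2.0 * (1.0 - np.asarray(corr, float)), 0.0))


def ward_dendrogram(corr: pd.DataFrame) -> Dendrogram:
    """Ward minimum-variance clustering of d = sqrt(2(1-r))."""
    R = corr.to_numpy()
    w = np.linalg.eigvalsh(0.5 * (R + R.T))
    if w.min() < -1e-8:
        logger.warning("correlation matrix is not PSD (min eigenvalue %.3g)", w.min())
    D = correlation_to_distance(R)
    iu = np.triu_indices(len(D), k=1)
    Z = hierarchy.linkage(D[iu], method="ward")
    return Dendrogram(list(corr.index), Z)


@dataclass
class BiplotResult:
    loadings: pd.DataFrame      # env x 2, scaled by component variance
    scores: pd.DataFrame        # individual x 2, rescaled to [-1, 1]
    explained: np.ndarray       # variance fraction per component
    projections: pd.DataFrame   # rank-2 reconstruction, individuals x envs
    rankings: pd.DataFrame      # per-env rank of individuals (1 = best)


def biplot_decomposition(
    values: pd.DataFrame, standardise: str = "center"
) -> BiplotResult:
    """First two principal components of a genomic-value-by-environment matrix.

    ``standardise="center"`` removes environment means; ``"zscore"``
    additionally scales each environment to unit variance.  Loadings are
    scaled by their component's variance and scores rescaled so the largest
    absolute score per axis is 1; projections are the rank-2 reconstruction
    on the original scale and drive the per-environment rankings (ties broken
    by individual id).
    """
    if values.shape[1] < 2 or values.shape[0] < 3:
        raise ValueError("need >=2 environments and >=3 individuals")
    M = values.to_numpy(float)
    mean = M.mean(axis=0)
    C = M - mean
    scale = np.ones(M.shape[1])
    if standardise == "zscore":
        scale = C.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        C = C / scale
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    if (s[:2] <= 1e-12 * max(s[0], 1e-300)).any():
        logger.warning("rank-deficient input; second biplot axis is zero")
    n = M.shape[0]
    comp_var = s**2 / (n - 1)
    explained = comp_var / comp_var.sum() if comp_var.sum() > 0 else comp_var
    load = Vt[:2].T * comp_var[:2]
    raw_scores = U[:, :2] * s[:2]
    denom = np.abs(raw_scores).max(axis=0)
    denom[denom == 0] = 1.0
    scores = raw_scores / denom
    recon = (U[:, :2] * s[:2]) @ Vt[:2] * scale + mean
    proj = pd.DataFrame(recon, index=values.index, columns=values.columns)
    ranks = proj.apply(
        lambda col: col.to_frame("v").assign(id=proj.index)
        .sort_values(["v", "id"], ascending=[False, True])
        .assign(rank=range(1, len(col) + 1))
        .sort_index()["rank"]
    )
    return BiplotResult(
        loadings=pd.DataFrame(load, index=values.columns, columns=["PC1", "PC2"]),
        scores=pd.DataFrame(scores, index=values.index, columns=["PC1", "PC2"]),
        explained=explained[:2],
        projections=proj,
        rankings=ranks,
    )
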