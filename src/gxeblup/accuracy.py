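"""Expected and realised prediction accuracy.

Expected accuracy of a genomic effect for an individual cohort is
sqrt(1 - mean(PEV) / v) with v the effect's variance in the target
environment: the classic reliability-based accuracy, evaluated separately
for three cohorts per trial-by-genomic-environment (tested in that
trial-environment; tested in the trial but a different environment; tested
only in other trials).

Realised accuracy comes from k-fold cross-validation: validation phenotypes
are masked, the model refitted with the full relationship matrix (reference
plus validation individuals), and the correlation between predicted genomic
values and adjusted phenotypes (prediction ability) divided by the square
root of narrow-sense (additive predictions) or broad-sense (total
predictions) heritability.  Validation sets are sampled across trials (XTCV,
new-accession scenario) or within each trial (WTCV, locally-untested
scenario).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mme import ModelFit, ModelSpec, reml_fit
from .types import validate_phenotypes

logger = logging.getLogger(__name__)

COHORTS = ("TGE", "trial_tested", "trial_untested")


def assign_cohorts(
    pheno: pd.DataFrame,
    env_map: Mapping[str, str],
    genotyped_ids: Sequence[str],
) -> pd.DataFrame:
    """Cohort membership per (trial, genomic environment).

    TGE: phenotyped in that trial-environment; trial_tested: phenotyped in
    the trial but only in other environments; trial_untested: phenotyped only
    elsewhere (genotyped individuals with no phenotype anywhere are counted
    here too, since for every target they carry no trial data).  Cohorts are
    disjoint and cover all genotyped individuals; empty cohorts are allowed.
    """
    pheno = validate_phenotypes(pheno)
    missing = sorted(set(pheno["cell"]) - set(env_map))
    if missing:
        raise ValueError(f"environment map does not cover cells: {missing}")
    pheno = pheno.assign(env=pheno["cell"].map(env_map))
    tested_te = pheno.groupby(["trial", "env"])["individual"].agg(set)
    tested_t = pheno.groupby("trial")["individual"].agg(set)
    rows = []
    for (trial, env), in_te in tested_te.items():
        in_t = tested_t[trial]
        for ind in genotyped_ids:
            if ind in in_te:
                cohort = "TGE"
            elif ind in in_t:
                cohort = "trial_tested"
            else:
                cohort = "trial_untested"
            rows.append({"trial": trial, "env": env, "cohort": cohort,
                         "individual": ind})
    return pd.DataFrame(rows)


def expected_accuracy(
    fit: ModelFit,
    cohorts: pd.DataFrame,
    term_sets: Mapping[str, Sequence[str]] | None = None,
    env_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """rE = sqrt(1 - mean PEV / v) per effect x trial x environment x cohort.

    ``term_sets`` names each reported effect and lists the model terms it
    sums (e.g. ``{"AW": ["A"], "DW": ["D"]}``); default is one effect per
    genomic term.  Cells whose effect variance is pinned at zero are flagged
    and get no estimate; a negative 1 - PEV/v is clipped at zero with a
    warning.
    """
    if term_sets is None:
        term_sets = {ts.name: [ts.name] for ts in fit.spec.terms}
    if env_map is None:
        env_map = fit.target_env_map(
            [n for ns in term_sets.values() for n in ns])
    rows = []
    for effect, names in term_sets.items():
        bp = fit.blup_pev(list(names), target_map=dict(env_map))
        bp = bp.set_index(["individual", "env"])
        for (trial, env, cohort), grp in cohorts.groupby(
                ["trial", "env", "cohort"], sort=True):
            inds = grp["individual"].tolist()
            sub = bp.loc[[(i, env) for i in inds]] if inds else bp.iloc[:0]
            n = len(sub)
            if n == 0:
                rows.append({"effect": effect, "trial": trial, "env": env,
                             "cohort": cohort, "n": 0, "mean_pev": np.nan,
                             "variance": np.nan, "rE": np.nan,
                             "flagged": False})
                continue
            v = float(fit.env_variance(list(names), dict(env_map))[env])
            mean_pev = float(sub["pev"].mean())
            if v <= 1e-10:
                rows.append({"effect": effect, "trial": trial, "env": env,
                             "cohort": cohort, "n": n, "mean_pev": mean_pev,
                             "variance": v, "rE": np.nan, "flagged": True})
                continue
            ratio = 1.0 - mean_pev / v
            if ratio < 0:
                logger.warning("negative 1 - PEV/v for %s %s %s; clipped",
                               effect, trial, env)
                ratio = 0.0
            rows.append({"effect": effect, "trial": trial, "env": env,
                         "cohort": cohort, "n": n, "mean_pev": mean_pev,
                         "variance": v, "rE": float(np.sqrt(ratio)),
                         "flagged": False})
    return pd.DataFrame(rows)


def adjusted_phenotypes(
    pheno: pd.DataFrame, residual_by: str = "trial", **reml_kwargs
) -> pd.DataFrame:
    """Genomic-term-free adjustment: BLUP(permanent env) + residual per record.

    Fits trial-by-season means + permanent-environment + residual (no genomic
    terms), then sums the predicted permanent-environment effect and the
    residual for each observational unit.  Fixed trial/season effects are
    absorbed, so adding a constant to a cell leaves adjusted values unchanged.
    """
    pheno = validate_phenotypes(pheno).reset_index(drop=True)
    spec = ModelSpec(terms=[], fixed=("cell",), permanent_env=True,
                     residual_by=residual_by)
    fit = reml_fit(spec, pheno, **reml_kwargs)
    pe = fit.perm_env_blups().set_index(["individual", "trial"])["pe_blup"]
    out = fit.pheno.copy()
    out["adjusted"] = (
        pe.loc[list(zip(out["individual"], out["trial"]))].to_numpy()
        + fit.residuals()
    )
    return out


def _fold_assignments(pheno, scheme, k, seed):
    """Per-fold sets of (trial, individual) records to mask."""
    rng = np.random.default_rng(seed)
    folds = [set() for _ in range(k)]
    if scheme == "XTCV":
        strata = (pheno.drop_duplicates("individual")
                  .groupby(pheno.drop_duplicates("individual")["individual"]
                           .map(dict(zip(pheno["individual"],
                                         pheno.get("population",
                                                   pheno["trial"]))))))
        for _, grp in strata:
            ids = sorted(grp["individual"])
            rng.shuffle(ids)
            for i, ind in enumerate(ids):
                folds[i % k].update(
                    (t, ind) for t in pheno.loc[pheno["individual"] == ind,
                                                "trial"].unique())
    elif scheme == "WTCV":
        for trial, grp in pheno.groupby("trial"):
            ids = sorted(grp["individual"].unique())
            rng.shuffle(ids)
            for i, ind in enumerate(ids):
                folds[i % k].add((trial, ind))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return folds


def cross_validate(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    env_map: Mapping[str, str],
    heritabilities: pd.DataFrame,
    term_sets: Mapping[str, Sequence[str]],
    divisors: Mapping[str, str],
    scheme: str = "XTCV",
    k: int = 5,
    seed: int = 0,
    min_validation: int = 3,
    **reml_kwargs,
) -> pd.DataFrame:
    """k-fold realised accuracy per effect x trial x genomic environment.

    ``term_sets`` names the prediction targets (e.g. additive = background +
    QTL terms; total = those + dominance); ``divisors`` maps each target to
    ``"h2"`` or ``"H2"`` columns of ``heritabilities`` (a
    :func:`gxeblup.summaries.heritability_table` frame from the most
    parsimonious model).  Fold assignment is stratified by population (XTCV)
    or trial (WTCV); cells with fewer than ``min_validation`` validation
    individuals are omitted with a warning.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    pheno = validate_phenotypes(pheno).reset_index(drop=True)
    adj = adjusted_phenotypes(pheno, residual_by=spec.residual_by,
                              **reml_kwargs)
    adj["env"] = adj["cell"].map(dict(env_map))
    adj_agg = (adj.groupby(["individual", "trial", "env"])["adjusted"]
               .mean().rename("adjusted"))
    h2 = heritabilities.set_index(["trial", "env"])
    folds = _fold_assignments(pheno, scheme, k, seed)
    key = list(zip(pheno["trial"], pheno["individual"]))
    rows = []
    for f, masked in enumerate(folds):
        keep = np.array([kv not in masked for kv in key])
        if keep.all() or not keep.any():
            continue
        train = pheno.loc[keep].reset_index(drop=True)
        fit = reml_fit(spec, train, **reml_kwargs)
        preds, variances = {}, {}
        for eff, names in term_sets.items():
            preds[eff] = (fit.blup_pev(list(names), target_map=dict(env_map))
                          .set_index(["individual", "env"]))
            variances[eff] = fit.env_variance(list(names), dict(env_map))
        masked_df = pd.DataFrame(sorted(masked), columns=["trial", "individual"])
        for (trial, env), grp in adj_agg.groupby(level=["trial", "env"]):
            val_ids = sorted(
                set(masked_df.loc[masked_df["trial"] == trial, "individual"])
                & set(grp.index.get_level_values("individual")))
            if len(val_ids) < min_validation:
                if val_ids:
                    logger.warning(
                        "fold %d: <%d validation individuals for %s/%s; omitted",
                        f, min_validation, trial, env)
                continue
            y_adj = grp.loc[[(i, trial, env) for i in val_ids]].to_numpy()
            for eff, names in term_sets.items():
                block = preds[eff].loc[[(i, env) for i in val_ids]]
                g_hat = block["blup"].to_numpy()
                if np.std(g_hat) == 0 or np.std(y_adj) == 0:
                    continue
                ability = float(np.corrcoef(g_hat, y_adj)[0, 1])
                div_col = divisors[eff]
                div = float(np.sqrt(h2.loc[(trial, env), div_col]))
                # PEV-based expected accuracy of the same masked cohort,
                # from the same refit: the model-consistent counterpart of
                # the realised accuracy
                v = float(variances[eff][env])
                exp_acc = (float(np.sqrt(max(
                    1.0 - block["pev"].mean() / v, 0.0))) if v > 1e-10
                    else np.nan)
                rows.append({"scheme": scheme, "effect": eff, "trial": trial,
                             "env": env, "fold": f, "n": len(val_ids),
                             "ability": ability, "divisor": div,
                             "accuracy": ability / div if div > 0 else np.nan,
                             "expected": exp_acc})
    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        return per_fold
    agg = (per_fold.groupby(["scheme", "effect", "trial", "env"])
           .agg(n=("n", "mean"), ability=("ability", "mean"),
                divisor=("divisor", "first"), accuracy=("accuracy", "mean"),
                accuracy_sd=("accuracy", "std"),
                expected=("expected", "mean"), n_folds=("fold", "count"))
           .reset_index())
    agg.attrs["per_fold"] = per_fold
    return agg
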