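"""Structured model selection for genomic-by-environment interaction.

The strategy moves from single-trial to multi-trial models and from anonymous
genome-wide to QTL-partitioned genomic effects:

1. STGWU - single-trial univariate models (genomic main effect + iid
   genomic-by-season interaction) per trial, testing the additive x season
   and dominance x season components at the configured threshold.
2. STGWM - where interaction is significant, a multivariate (unstructured)
   single-trial model identifies the parsimonious within-trial environment
   grouping via Ward-guided merges.
3. MTGWU - multi-trial univariate model on the combined data with the
   all-individual GRM and the environment map assembled from the single-trial
   results; tests additive x environment and dominance x environment.
4. MTGWM - multivariate multi-trial models (unstructured for <=3
   environments, factor-analytic above, order chosen by likelihood-ratio
   tests); Ward-guided environment merges tested constrained vs
   unconstrained, accepted while not significantly worse, stopping after a
   configured number of consecutive rejections.
5. MTQBU - genomic effects separated into QTL and background relationship
   matrices; tests the QTL x environment interaction and the dominance QTL
   component.
6. MTQBM - final parsimonious multivariate QTL + background model and the
   final environment map per effect.

Every fitted model, test and accept/reject decision is recorded in the
result's audit trail.  Tie-breaks are deterministic (dendrogram merge order;
environment labels sorted lexicographically), so the strategy is reproducible
given data and configuration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import additive_grm, bend_grm, dominance_grm, partition_qtl_background
from .mme import DEFAULT_ALPHA, ModelFit, ModelSpec, RemlError, TermSpec, lrt_boundary, reml_fit
from .summaries import genomic_correlation_matrix, ward_dendrogram
from .types import GenotypePanel, validate_phenotypes

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phenotype scaling
# ---------------------------------------------------------------------------

def scale_phenotypes(pheno: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide each record by its trial-by-season phenotypic SD.

    Returns the scaled table and a scale table (cell, sd) for
    back-transformation with :func:`unscale_phenotypes`.
    """
    pheno = validate_phenotypes(pheno)
    sds = pheno.groupby("cell")["value"].std(ddof=1)
    if (counts := pheno.groupby("cell").size()).min() < 2:
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with <2 records cannot be scaled: {bad}")
    if (sds <= 0).any():
        bad = sds[sds <= 0].index.tolist()
        raise ValueError(f"zero phenotypic SD in cells: {bad}")
    out = pheno.copy()
    out["value"] = out["value"] / out["cell"].map(sds)
    return out, sds.rename("sd").reset_index()


def unscale_phenotypes(pheno: pd.DataFrame, scale_table: pd.DataFrame) -> pd.DataFrame:
    sds = scale_table.set_index("cell")["sd"]
    out = pheno.copy()
    out["value"] = out["value"] * out["cell"].map(sds)
    return out


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _data_fingerprint(fit: ModelFit) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(fit.result.y).tobytes())
    h.update(",".join(fit.pheno["cell"].astype(str)).encode())
    return h.hexdigest()


@dataclass
class Comparison:
    full: str
    reduced: str
    statistic: float
    df: int
    n_boundary: int
    p_value: float
    aic_full: float
    aic_reduced: float
    prefer_reduced: bool


def compare_models(
    fit_full: ModelFit,
    fit_reduced: ModelFit,
    n_boundary: int = 0,
    alpha: float = DEFAULT_ALPHA,
    names: tuple[str, str] = ("full", "reduced"),
) -> Comparison:
    """Boundary-aware LRT (when nested) plus AIC parsimony comparison.

    Nesting is inferred from the covariance-parameter counts; the reduced
    model must not have more parameters than the full one.  The verdict
    prefers the reduced model unless the LRT rejects at ``alpha``.
    """
    if _data_fingerprint(fit_full) != _data_fingerprint(fit_reduced):
        raise ValueError("models were fitted to different data")
    df = len(fit_full.result.theta) - len(fit_reduced.result.theta)
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    n_free = max(df - n_boundary, 0)
    T, p = lrt_boundary(fit_full.loglik, fit_reduced.loglik, n_boundary, n_free)
    return Comparison(
        full=names[0], reduced=names[1], statistic=T, df=df,
        n_boundary=n_boundary, p_value=p,
        aic_full=fit_full.aic, aic_reduced=fit_reduced.aic,
        prefer_reduced=not (p < alpha),
    )


# ---------------------------------------------------------------------------
# Ward-guided merge proposals
# ---------------------------------------------------------------------------

def propose_merges(fit: ModelFit, effect: str = "additive") -> list[dict[str, str]]:
    """Candidate coarsened environment maps in dendrogram merge order.

    Environments are clustered (Ward on sqrt(2(1-r)) of the effect's genomic
    correlation matrix); candidate m applies the first m dendrogram merges.
    Merged environments get the lexicographically sorted joined label.
    """
    corr = genomic_correlation_matrix(fit, effect)
    if len(corr) < 2:
        return []
    names = [t.name for t in fit.spec.terms
             if (t.effect == effect or effect == "total")]
    base_map = fit.target_env_map(names)
    dend = ward_dendrogram(corr)
    candidates = []
    for m in range(1, len(dend.linkage) + 1):
        groups: list[frozenset] = []
        for merged, _h in dend.merge_order()[:m]:
            groups = [g for g in groups if not g <= merged] + [merged]
        label_of = {}
        for g in groups:
            lab = "+".join(sorted(g))
            for e in g:
                label_of[e] = lab
        cand = {c: label_of.get(e, e) for c, e in base_map.items()}
        candidates.append(cand)
    return candidates


# ---------------------------------------------------------------------------
# strategy
# ---------------------------------------------------------------------------

@dataclass
class StrategyConfig:
    alpha: float = DEFAULT_ALPHA
    max_fa_order: int = 2
    stop_after_rejections: int = 2
    bend_epsilon: float = 1e-6
    scale: bool = True
    aic_convention: str = "all"
    reml_options: dict = field(default_factory=dict)


@dataclass
class ModelRecord:
    name: str
    stage: str
    description: str
    fit: ModelFit | None = None
    comparison: Comparison | None = None
    accepted: bool | None = None
    error: str | None = None


@dataclass
class StrategyResult:
    records: list[ModelRecord]
    env_maps: dict[str, dict[str, str]]
    selected: str
    final_fit: ModelFit | None
    scale_table: pd.DataFrame | None = None

    def record(self, name: str) -> ModelRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def audit_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "name": r.name, "stage": r.stage, "description": r.description,
                "loglik": r.fit.loglik if r.fit else np.nan,
                "aic": r.fit.aic if r.fit else np.nan,
                "p_value": r.comparison.p_value if r.comparison else np.nan,
                "accepted": r.accepted, "error": r.error,
            })
        return pd.DataFrame(rows)


def _grms(panel: GenotypePanel, ids, epsilon, interval=None):
    """Bent additive/dominance (and optionally QTL/background) GRMs."""
    sub = panel.subset(individuals=ids) if ids is not None else panel
    out = {
        "A": bend_grm(additive_grm(sub), epsilon),
        "D": bend_grm(dominance_grm(sub), epsilon),
    }
    if interval is not None:
        gq, gb = partition_qtl_background(sub, interval)
        out["AQ"] = bend_grm(gq, epsilon)
        out["AB"] = bend_grm(gb, epsilon)
    return out


class _Runner:
    """Shared state for one strategy execution."""

    def __init__(self, pheno, panel, interval, config: StrategyConfig):
        self.pheno = validate_phenotypes(pheno)
        self.panel = panel
        self.interval = interval
        self.cfg = config
        self.records: list[ModelRecord] = []

    def fit(self, name, stage, desc, spec, pheno) -> ModelFit | None:
        rec = ModelRecord(name=name, stage=stage, description=desc)
        self.records.append(rec)
        try:
            rec.fit = reml_fit(spec, pheno,
                               aic_convention=self.cfg.aic_convention,
                               **self.cfg.reml_options)
        except RemlError as exc:
            rec.error = str(exc)
            logger.warning("fit %s failed: %s", name, exc)
            return None
        return rec.fit

    def compare(self, name, full_fit, red_fit, n_boundary, names):
        cmp_ = compare_models(full_fit, red_fit, n_boundary=n_boundary,
                              alpha=self.cfg.alpha, names=names)
        self.records[-1].comparison = cmp_
        return cmp_


def _multivariate_structure(n_env: int, order: int) -> str:
    return "us" if n_env <= 3 else f"fa{order}"


def run_selection_strategy(
    pheno: pd.DataFrame,
    panel: GenotypePanel,
    qtl_interval: tuple,
    config: StrategyConfig | None = None,
) -> StrategyResult:
    """Execute the full STGWU -> ... -> MTQBM model-selection sequence."""
    cfg = config or StrategyConfig()
    pheno = validate_phenotypes(pheno)
    scale_table = None
    if cfg.scale:
        pheno, scale_table = scale_phenotypes(pheno)
    run = _Runner(pheno, panel, qtl_interval, cfg)
    alpha = cfg.alpha
    trials = sorted(pheno["trial"].unique().tolist())

    # ------------------------------------------------------------------ ST
    env_map_additive: dict[str, str] = {}
    for trial in trials:
        ptr = pheno[pheno["trial"] == trial].reset_index(drop=True)
        cells = sorted(ptr["cell"].unique().tolist())
        ids = sorted(ptr["individual"].unique().tolist())
        grms = _grms(run.panel, ids, cfg.bend_epsilon)
        season_map = {c: c for c in cells}
        tA = TermSpec("A", "additive", grms["A"])
        tAxS = TermSpec("AxS", "additive", grms["A"], season_map, "iid")
        tD = TermSpec("D", "dominance", grms["D"])
        tDxS = TermSpec("DxS", "dominance", grms["D"], season_map, "iid")
        mk = lambda terms: ModelSpec(terms, fixed=("season",),
                                     permanent_env=len(cells) > 1,
                                     residual_by="single")
        # backward elimination: dominance x season first, then additive x season
        full = run.fit(f"STGWU_{trial}", "STGWU",
                       f"single-trial univariate, trial {trial}",
                       mk([tA, tAxS, tD, tDxS]), ptr)
        a_sig = d_sig = False
        base, base_name = full, f"STGWU_{trial}"
        if full is not None:
            noD = run.fit(f"STGWU_{trial}_noDxS", "STGWU",
                          "drop dominance x season", mk([tA, tAxS, tD]), ptr)
            if noD is not None:
                d_sig = not run.compare(f"STGWU_{trial}", full, noD, 1,
                                        (f"STGWU_{trial}",
                                         f"STGWU_{trial}_noDxS")).prefer_reduced
                run.records[-1].accepted = d_sig
                if not d_sig:
                    base, base_name = noD, f"STGWU_{trial}_noDxS"
            noA = run.fit(f"STGWU_{trial}_noAxS", "STGWU",
                          "drop additive x season",
                          mk([tA, tD] + ([tDxS] if d_sig else [])), ptr)
            if noA is not None:
                a_sig = not run.compare(base_name, base, noA, 1,
                                        (base_name,
                                         f"STGWU_{trial}_noAxS")).prefer_reduced
                run.records[-1].accepted = a_sig

        # within-trial environment grouping for additive effects
        if not a_sig or len(cells) < 2:
            for c in cells:
                env_map_additive[c] = trial
            continue
        # STGWM: multivariate over seasons, Ward-guided merging
        cur_map = {c: c for c in cells}
        struct = _multivariate_structure(len(cells), 1)
        spec_mv = ModelSpec(
            [TermSpec("A", "additive", grms["A"], cur_map, struct), tD]
            + ([tDxS] if d_sig else []),
            fixed=("season",), permanent_env=True, residual_by="single")
        mv = run.fit(f"STGWM_{trial}", "STGWM",
                     f"single-trial multivariate, trial {trial}", spec_mv, ptr)
        if mv is None:
            for c in cells:
                env_map_additive[c] = f"{trial}{c}"
            continue
        best, best_name = mv, f"STGWM_{trial}"
        rejections = 0
        for i, cand in enumerate(propose_merges(mv, "additive"), start=1):
            n_env = len(set(cand.values()))
            struct_c = _multivariate_structure(n_env, 1) if n_env > 1 else "uniform"
            spec_c = spec_mv.with_terms(
                [TermSpec("A", "additive", grms["A"],
                          cand if n_env > 1 else None, struct_c), tD]
                + ([tDxS] if d_sig else []))
            red = run.fit(f"STGWM_{trial}_merge{i}", "STGWM",
                          f"merge candidate {i}: {sorted(set(cand.values()))}",
                          spec_c, ptr)
            if red is None:
                rejections += 1
            else:
                cmp_ = run.compare(f"STGWM_{trial}_merge{i}", best, red, 0,
                                   (best_name, f"STGWM_{trial}_merge{i}"))
                run.records[-1].accepted = cmp_.prefer_reduced
                if cmp_.prefer_reduced:
                    best, best_name = red, f"STGWM_{trial}_merge{i}"
                    cur_map = cand
                    rejections = 0
                else:
                    rejections += 1
            if rejections >= cfg.stop_after_rejections:
                break
        for c in cells:
            env_map_additive[c] = f"{trial}:{cur_map[c]}" \
                if len(set(cur_map.values())) > 1 else trial

    # ------------------------------------------------------------------ MT
    if len(trials) < 2:
        raise ValueError("multi-trial stages require >= 2 trials")
    all_ids = sorted(pheno["individual"].unique().tolist())
    grms = _grms(run.panel, all_ids, cfg.bend_epsilon, interval=run.interval)
    amap = dict(env_map_additive)
    n_aenv = len(set(amap.values()))

    tA = TermSpec("A", "additive", grms["A"])
    tAxE = TermSpec("AxE", "additive", grms["A"], amap, "iid")
    tD = TermSpec("D", "dominance", grms["D"])
    tDxE = TermSpec("DxE", "dominance", grms["D"], amap, "iid")
    mk = lambda terms: ModelSpec(terms, fixed=("cell",), permanent_env=True,
                                 residual_by="trial")
    mtgwu = run.fit("MTGWU01", "MTGWU", "multi-trial univariate",
                    mk([tA, tAxE, tD, tDxE]), pheno)
    a_sig = d_sig = False
    if mtgwu is None:
        raise RemlError("multi-trial univariate model failed to converge")
    # dominance x environment tested and eliminated first
    base, base_name = mtgwu, "MTGWU01"
    noD = run.fit("MTGWU02_noDxE", "MTGWU", "drop dominance x environment",
                  mk([tA, tAxE, tD]), pheno)
    if noD is not None:
        d_sig = not run.compare("MTGWU02", mtgwu, noD, 1,
                                ("MTGWU01", "MTGWU02_noDxE")).prefer_reduced
        run.records[-1].accepted = d_sig
        if not d_sig:
            base, base_name = noD, "MTGWU02_noDxE"
    noA = run.fit("MTGWU01_noAxE", "MTGWU", "drop additive x environment",
                  mk([tA, tD] + ([tDxE] if d_sig else [])), pheno)
    if noA is not None:
        a_sig = not run.compare(base_name, base, noA, 1,
                                (base_name, "MTGWU01_noAxE")).prefer_reduced
        run.records[-1].accepted = a_sig

    dom_terms = lambda: ([TermSpec("D", "dominance", grms["D"])]
                         + ([TermSpec("DxE", "dominance", grms["D"], amap, "iid")]
                            if d_sig else []))

    # MTGWM: multivariate additive structure and merge search
    final_gw_fit = noA if (not a_sig and noA is not None) else mtgwu
    final_gw_name = "MTGWU01_noAxE" if (not a_sig and noA is not None) else "MTGWU01"
    if not a_sig:
        amap = {c: "all" for c in amap}
    else:
        order = 1
        struct = _multivariate_structure(n_aenv, order)
        spec_mv = mk([TermSpec("A", "additive", grms["A"], amap, struct)]
                     + dom_terms())
        mv = run.fit("MTGWM02", "MTGWM",
                     f"multi-trial multivariate additive ({struct})",
                     spec_mv, pheno)
        if mv is not None and struct.startswith("fa"):
            while order < min(cfg.max_fa_order, n_aenv - 1):
                spec_hi = mk([TermSpec("A", "additive", grms["A"], amap,
                                       f"fa{order+1}")] + dom_terms())
                hi = run.fit(f"MTGWM0{2+order}", "MTGWM",
                             f"factor-analytic order {order+1}", spec_hi, pheno)
                if hi is None:
                    break
                cmp_ = run.compare(f"MTGWM0{2+order}", hi, mv, 0,
                                   (f"MTGWM0{2+order}", f"MTGWM0{1+order}"))
                run.records[-1].accepted = not cmp_.prefer_reduced
                if cmp_.prefer_reduced:
                    break
                mv, order = hi, order + 1
        if mv is not None:
            best, best_name = mv, "MTGWM02"
            rejections, i = 0, 0
            for cand in propose_merges(mv, "additive"):
                i += 1
                n_env = len(set(cand.values()))
                struct_c = (_multivariate_structure(n_env, order)
                            if n_env > 1 else "uniform")
                spec_c = mk([TermSpec("A", "additive", grms["A"],
                                      cand if n_env > 1 else None, struct_c)]
                            + dom_terms())
                red = run.fit(f"MTGWM_merge{i}", "MTGWM",
                              f"merge candidate: {sorted(set(cand.values()))}",
                              spec_c, pheno)
                if red is None:
                    rejections += 1
                else:
                    cmp_ = run.compare(f"MTGWM_merge{i}", best, red, 0,
                                       (best_name, f"MTGWM_merge{i}"))
                    run.records[-1].accepted = cmp_.prefer_reduced
                    if cmp_.prefer_reduced:
                        best, best_name, amap = red, f"MTGWM_merge{i}", cand
                        rejections = 0
                    else:
                        rejections += 1
                if rejections >= cfg.stop_after_rejections:
                    break
            final_gw_fit, final_gw_name = best, best_name

    # ------------------------------------------------------------------ QB
    n_aenv = len(set(amap.values()))
    a_struct = (_multivariate_structure(n_aenv, 1) if (a_sig and n_aenv > 1)
                else "uniform")
    ab_map = amap if (a_sig and n_aenv > 1) else None
    mk_qb = lambda extra, ab_struct=a_struct, ab_env=ab_map: mk(
        [TermSpec("AQ", "additive", grms["AQ"]),
         TermSpec("AB", "additive", grms["AB"], ab_env, ab_struct)]
        + extra + dom_terms())
    mtqbu = run.fit("MTQBU01", "MTQBU", "QTL + background univariate split",
                    mk_qb([]), pheno)
    final_fit, final_name = final_gw_fit, final_gw_name
    if mtqbu is not None:
        # QTL x environment
        with_qxe = run.fit("MTQBU_QxE", "MTQBU", "add QTL x environment",
                           mk_qb([TermSpec("AQxE", "additive", grms["AQ"],
                                           dict(env_map_additive), "iid")]),
                           pheno)
        if with_qxe is not None:
            cmp_ = run.compare("MTQBU_QxE", with_qxe, mtqbu, 1,
                               ("MTQBU_QxE", "MTQBU01"))
            qxe_sig = not cmp_.prefer_reduced
            run.records[-1].accepted = qxe_sig
            if qxe_sig:
                mtqbu = with_qxe
        # dominance QTL component
        dq, db = partition_qtl_background(
            run.panel.subset(individuals=all_ids), run.interval,
            effect_kind="dominance")
        dq, db = bend_grm(dq, cfg.bend_epsilon), bend_grm(db, cfg.bend_epsilon)
        with_dq = run.fit(
            "MTQBU_DQ", "MTQBU", "split dominance into QTL + background",
            mk([TermSpec("AQ", "additive", grms["AQ"]),
                TermSpec("AB", "additive", grms["AB"], ab_map, a_struct),
                TermSpec("DQ", "dominance", dq),
                TermSpec("DB", "dominance", db)]
               + ([TermSpec("DxE", "dominance", grms["D"], amap, "iid")]
                  if d_sig else [])), pheno)
        if with_dq is not None:
            cmp_ = run.compare("MTQBU_DQ", with_dq, mtqbu, 1,
                               ("MTQBU_DQ", "MTQBU01"))
            run.records[-1].accepted = not cmp_.prefer_reduced
            if not cmp_.prefer_reduced:
                mtqbu = with_dq
        final_fit = mtqbu
        final_name = next(r.name for r in reversed(run.records)
                          if r.fit is mtqbu)

        # MTQBM: final merge pass on the background structure
        if a_sig and n_aenv > 1:
            best, best_name = mtqbu, final_name
            rejections, i = 0, 0
            for cand in propose_merges(mtqbu, "additive"):
                i += 1
                n_env = len(set(cand.values()))
                struct_c = (_multivariate_structure(n_env, 1)
                            if n_env > 1 else "uniform")
                spec_c = mk_qb([], ab_struct=struct_c,
                               ab_env=cand if n_env > 1 else None)
                red = run.fit(f"MTQBM_merge{i}", "MTQBM",
                              f"merge candidate: {sorted(set(cand.values()))}",
                              spec_c, pheno)
                if red is None:
                    rejections += 1
                else:
                    cmp_ = run.compare(f"MTQBM_merge{i}", best, red, 0,
                                       (best_name, f"MTQBM_merge{i}"))
                    run.records[-1].accepted = cmp_.prefer_reduced
                    if cmp_.prefer_reduced:
                        best, best_name, amap = red, f"MTQBM_merge{i}", cand
                        rejections = 0
                    else:
                        rejections += 1
                if rejections >= cfg.stop_after_rejections:
                    break
            final_fit, final_name = best, best_name

    env_maps = {
        "additive": dict(amap),
        "dominance": {c: ("all" if not d_sig else amap[c]) for c in amap},
    }
    env_maps["total"] = dict(env_maps["additive"])
    return StrategyResult(records=run.records, env_maps=env_maps,
                          selected=final_name, final_fit=final_fit,
                          scale_table=scale_table)
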