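"""Model specification, fitting, and BLUP/PEV extraction.

A :class:`ModelSpec` binds fixed factors (columns of the phenotype table),
genomic random terms (GRM + environment map + covariance structure), an
optional permanent-environment term (per-trial variances over
individual-within-trial levels) and per-trial heterogeneous residuals.
:func:`reml_fit` assembles the observation-level terms and maximises the
restricted likelihood; the returned :class:`ModelFit` exposes variance
components, AIC, Wald tests for fixed factors, and BLUPs with their
prediction-error variances for any subset of genomic terms (including the
total additive + dominance effect, with posterior cross-covariances taken
from the same projection matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ..types import GRM, validate_phenotypes
from .reml import REMLResult, RemlError, Term, reml
from .structures import FactorAnalytic, make_structure


@dataclass
class TermSpec:
    """One genomic random term.

    ``effect`` is ``"additive"`` or ``"dominance"`` (used by architecture
    summaries); ``env_of_cell`` maps trial-by-season cells to genomic
    environment labels, or None for a single environment (main effect);
    ``structure`` is ``uniform | diagonal | faK | us``.
    """

    name: str
    effect: str
    grm: GRM
    env_of_cell: Mapping[str, str] | None = None
    structure: str = "uniform"


@dataclass
class ModelSpec:
    terms: list[TermSpec]
    fixed: tuple[str, ...] = ("cell",)
    permanent_env: bool = True
    residual_by: str = "trial"  # 'trial' or 'single'

    def with_terms(self, terms: list[TermSpec]) -> "ModelSpec":
        return replace(self, terms=terms)


def build_fixed_design(pheno: pd.DataFrame, fixed: Sequence[str]):
    """Intercept + treatment-coded dummies per factor; returns (X, slices)."""
    n = len(pheno)
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    slices: dict[str, slice] = {}
    off = 1
    for fac in fixed:
        levels = pd.unique(pheno[fac])
        dummies = pd.get_dummies(pd.Categorical(pheno[fac], categories=levels),
                                 drop_first=True, dtype=float)
        k = dummies.shape[1]
        if k:
            cols.append(dummies.to_numpy())
            names += [f"{fac}[{c}]" for c in dummies.columns]
            slices[fac] = slice(off, off + k)
            off += k
        else:
            slices[fac] = slice(off, off)
    return np.hstack(cols), names, slices


def _env_assignment(pheno: pd.DataFrame, env_of_cell: Mapping[str, str] | None):
    if env_of_cell is None:
        return np.zeros(len(pheno), dtype=int), ["all"]
    cells = pheno["cell"].to_numpy()
    missing = sorted({c for c in np.unique(cells) if c not in env_of_cell})
    if missing:
        raise ValueError(f"environment map does not cover cells: {missing}")
    labels = sorted(set(env_of_cell[c] for c in np.unique(cells)))
    lookup = {lab: i for i, lab in enumerate(labels)}
    return np.array([lookup[env_of_cell[c]] for c in cells]), labels


def _build_terms(spec: ModelSpec, pheno: pd.DataFrame) -> list[Term]:
    terms: list[Term] = []
    indiv = pheno["individual"].tolist()
    for ts in spec.terms:
        env_idx, env_labels = _env_assignment(pheno, ts.env_of_cell)
        structure = make_structure(ts.structure, len(env_labels))
        obs_idx = ts.grm.indexer(indiv)
        K_full = ts.grm.matrix
        K_obs = K_full[np.ix_(obs_idx, obs_idx)]
        terms.append(Term(
            name=ts.name, kind=ts.effect, structure=structure,
            env_idx=env_idx, env_labels=env_labels, K_obs=K_obs,
            K_full=K_full, level_ids=list(ts.grm.ids), obs_level_idx=obs_idx,
        ))

    trials = pheno["trial"].to_numpy()
    trial_labels = sorted(pd.unique(trials).tolist())
    trial_idx = np.array([trial_labels.index(t) for t in trials])

    if spec.permanent_env:
        lev = pd.Series(list(zip(pheno["individual"], pheno["trial"])))
        codes = lev.astype("category").cat.codes.to_numpy()
        K_obs = (codes[:, None] == codes[None, :]).astype(float)
        terms.append(Term(
            name="perm_env", kind="perm_env",
            structure=make_structure("diagonal", len(trial_labels)),
            env_idx=trial_idx, env_labels=trial_labels, K_obs=K_obs,
        ))

    if spec.residual_by == "trial":
        r_idx, r_labels = trial_idx, trial_labels
    else:
        r_idx, r_labels = np.zeros(len(pheno), dtype=int), ["all"]
    terms.append(Term(
        name="residual", kind="residual",
        structure=make_structure("diagonal", len(r_labels)),
        env_idx=r_idx, env_labels=r_labels, K_obs=np.eye(len(pheno)),
    ))
    return terms


@dataclass
class ModelFit:
    """A converged REML solution with its data binding."""

    spec: ModelSpec
    pheno: pd.DataFrame
    result: REMLResult
    fixed_names: list[str]
    fixed_slices: dict[str, slice]
    aic_convention: str = "all"

    # -- likelihood-level summaries ---------------------------------------
    @property
    def loglik(self) -> float:
        return self.result.loglik

    @property
    def n_params(self) -> int:
        if self.aic_convention == "free":
            return int((~self.result.pinned).sum())
        return len(self.result.theta)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def term(self, name: str) -> Term:
        for t in self.result.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}")

    def env_cov(self, name: str) -> pd.DataFrame:
        """FA-expanded (or direct) environment covariance of a term."""
        t = self.term(name)
        sigma = self.result.sigma_for(name)
        return pd.DataFrame(sigma, index=t.env_labels, columns=t.env_labels)

    def fa_structure(self, name: str):
        """(loadings, specific) of an FA term, sign-canonicalised."""
        t = self.term(name)
        if not isinstance(t.structure, FactorAnalytic):
            raise ValueError(f"term {name!r} has no factor-analytic structure")
        L, psi = t.structure.unpack(self.result.params_for(name))
        return FactorAnalytic.canonicalise(L), psi

    def variance_components(self) -> pd.DataFrame:
        rows = []
        for t, s in zip(self.result.terms, self.result.slices):
            for pname, val, pin in zip(
                t.structure.param_names(), self.result.theta[s], self.result.pinned[s]
            ):
                rows.append({"term": t.name, "kind": t.kind, "param": pname,
                             "value": float(val), "pinned": bool(pin)})
        return pd.DataFrame(rows)

    # -- fixed effects -----------------------------------------------------
    def wald_test(self, factor: str) -> tuple[float, int, float]:
        """Wald chi-square test that all coefficients of ``factor`` are zero."""
        if factor not in self.fixed_slices:
            raise KeyError(f"fixed factor {factor!r} not in model")
        s = self.fixed_slices[factor]
        b = self.result.beta[s]
        C = self.result.beta_cov[s, s]
        df = len(b)
        if df == 0:
            return 0.0, 0, 1.0
        stat = float(b @ np.linalg.solve(C, b))
        return stat, df, float(stats.chi2.sf(stat, df))

    # -- environment bookkeeping -------------------------------------------
    def observed_cells(self) -> list[str]:
        return sorted(pd.unique(self.pheno["cell"]).tolist())

    def target_env_map(self, term_names: Sequence[str]) -> dict[str, str]:
        """Finest cell->env map across the named terms (their common refinement)."""
        cells = self.observed_cells()
        keys = []
        for c in cells:
            key = tuple(
                (self.spec_term(n).env_of_cell or {}).get(c, "all")
                for n in term_names
            )
            keys.append(key)
        uniq = {}
        for c, k in zip(cells, keys):
            uniq.setdefault(k, []).append(c)
        # label each group by joining term env labels (drop 'all')
        out = {}
        for k, cs in uniq.items():
            parts = [p for p in k if p != "all"]
            label = "/".join(dict.fromkeys(parts)) if parts else "all"
            for c in cs:
                out[c] = label
        return out

    def spec_term(self, name: str) -> TermSpec:
        for ts in self.spec.terms:
            if ts.name == name:
                return ts
        raise KeyError(name)

    def _term_env_of_target(self, term: Term, ts: TermSpec,
                            target_map: Mapping[str, str]) -> dict[str, int]:
        """Map each target env label to the term's env index (must be unique)."""
        out: dict[str, int] = {}
        for c in self.observed_cells():
            tgt = target_map[c]
            tenv = 0 if ts.env_of_cell is None else term.env_labels.index(
                ts.env_of_cell[c])
            if tgt in out and out[tgt] != tenv:
                raise ValueError(
                    f"target environment map does not refine term {ts.name!r}")
            out[tgt] = tenv
        return out

    def env_variance(self, term_names: Sequence[str],
                     target_map: Mapping[str, str] | None = None) -> pd.Series:
        """Summed effect variance per target environment for the named terms."""
        if target_map is None:
            target_map = self.target_env_map(term_names)
        env_labels = sorted(set(target_map.values()))
        v = pd.Series(0.0, index=env_labels)
        for name in term_names:
            t, ts = self.term(name), self.spec_term(name)
            sigma = self.result.sigma_for(name)
            emap = self._term_env_of_target(t, ts, target_map)
            for e in env_labels:
                v[e] += sigma[emap[e], emap[e]]
        return v

    # -- BLUP / PEV ---------------------------------------------------------
    def blup_pev(
        self,
        term_names: Sequence[str],
        target_map: Mapping[str, str] | None = None,
        ids: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Predicted effects and PEVs per individual x target environment.

        When several terms are named their BLUPs are summed (e.g. total =
        additive + dominance) and the PEV includes the posterior
        cross-covariances, since both come from the same projection of y.
        """
        if target_map is None:
            target_map = self.target_env_map(term_names)
        env_labels = sorted(set(target_map.values()))
        first = self.spec_term(term_names[0]).grm
        all_ids = list(first.ids) if ids is None else list(ids)
        res = self.result
        rows = []
        for e in env_labels:
            C = np.zeros((len(all_ids), len(res.y)))
            var = np.zeros(len(all_ids))
            for name in term_names:
                t, ts = self.term(name), self.spec_term(name)
                sigma = self.result.sigma_for(name)
                emap = self._term_env_of_target(t, ts, target_map)
                ge = emap[e]
                idx_all = ts.grm.indexer(all_ids)
                K_cross = t.K_full[np.ix_(idx_all, t.obs_level_idx)]
                C += K_cross * sigma[ge, t.env_idx][None, :]
                var += sigma[ge, ge] * t.K_full[idx_all, idx_all]
            blup = C @ res.Py
            CP = C @ res.P
            pev = var - np.einsum("ij,ij->i", CP, C)
            for i, ind in enumerate(all_ids):
                rows.append({"individual": ind, "env": e,
                             "blup": float(blup[i]),
                             "pev": float(max(pev[i], 0.0)),
                             "variance": float(var[i])})
        return pd.DataFrame(rows)

    def perm_env_blups(self) -> pd.DataFrame:
        """BLUPs of the permanent-environment effect per (individual, trial)."""
        t = self.term("perm_env")
        sigma = self.result.sigma_for("perm_env")
        # cov(u_level, y_j) = vU[trial] * 1{level_j == level}
        v_obs = sigma[t.env_idx, t.env_idx]
        contrib = t.K_obs * v_obs[None, :]  # row i: cov(u at obs-i's level, y)
        u_obs = contrib @ self.result.Py
        df = self.pheno[["individual", "trial"]].copy()
        df["pe_blup"] = u_obs
        return df.drop_duplicates(["individual", "trial"]).reset_index(drop=True)

    def residuals(self) -> np.ndarray:
        """BLUP residuals e_hat = R @ Py."""
        t = self.term("residual")
        sigma = self.result.sigma_for("residual")
        return sigma[t.env_idx, t.env_idx] * self.result.Py


def _warm_start_for_us(spec: ModelSpec, pheno: pd.DataFrame,
                       terms: list[Term], **reml_kwargs):
    """Start values for unstructured terms from a factor-analytic pre-fit.

    Element-wise unstructured updates crawl when the optimum sits on the
    singular boundary of the covariance cone (environment correlations near
    one); an FA(q-1)+Psi fit reaches that boundary smoothly and its expanded
    covariance is an excellent starting point.
    """
    from .structures import Unstructured

    us_names = [t.name for t in terms if isinstance(t.structure, Unstructured)
                and t.structure.n_env >= 2]
    if not us_names:
        return None
    pre_terms = []
    for ts in spec.terms:
        if ts.name in us_names:
            n_env = len({ts.env_of_cell[c] for c in pheno["cell"].unique()})
            pre_terms.append(replace(ts, structure=f"fa{n_env - 1}"))
        else:
            pre_terms.append(ts)
    try:
        pre = reml_fit(spec.with_terms(pre_terms), pheno, **reml_kwargs)
    except RemlError:
        return None
    start = []
    for t in terms:
        if t.name in us_names:
            S = pre.env_cov(t.name).to_numpy()
            start.extend(S[r, c] for r, c in t.structure.idx)
        else:
            start.extend(pre.result.params_for(t.name))
    return np.asarray(start)


def reml_fit(
    spec: ModelSpec,
    pheno: pd.DataFrame,
    start: np.ndarray | None = None,
    aic_convention: str = "all",
    **reml_kwargs,
) -> ModelFit:
    """Assemble terms from the spec and maximise the restricted likelihood."""
    pheno = validate_phenotypes(pheno).reset_index(drop=True)
    X, names, slices = build_fixed_design(pheno, spec.fixed)
    terms = _build_terms(spec, pheno)
    if start is None:
        start = _warm_start_for_us(spec, pheno, terms, **reml_kwargs)
    result = reml(pheno["value"].to_numpy(float), X, terms, start=start,
                  **reml_kwargs)
    return ModelFit(spec=spec, pheno=pheno, result=result,
                    fixed_names=names, fixed_slices=slices,
                    aic_convention=aic_convention)
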