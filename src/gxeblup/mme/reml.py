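"""Average-information REML for dense multi-term variance models.

The model is ``y = X beta + sum_t u_t`` with each random term contributing
``Sigma_t[env_i, env_j] * K_t[level_i, level_j]`` to ``V = var(y)``; the
residual is itself a term (identity relationship, per-trial variances), so
every covariance parameter is handled uniformly.

The likelihood is maximised on the observation-level covariance (dense V),
which is the right regime for the study scale of ~10^3 records.  Updates are
average-information steps with a step-halving line search; candidate steps
are projected onto the parameter bounds (variances >= 0) and components
pinned at the boundary with an outward gradient are profiled out of the
update.  When no damped AI step improves the restricted log-likelihood a
scaled-gradient fallback step is attempted.  Accepted iterations therefore
never decrease the log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .structures import CovStructure

logger = logging.getLogger(__name__)


class RemlError(RuntimeError):
    pass


@dataclass
class Term:
    """One random term bound to the observations.

    ``K_obs`` is the level relationship expanded to observations; ``env_idx``
    maps each observation to the term's environment (all zeros for a uniform
    main effect).  ``K_full``/``level_ids``/``obs_level_idx`` carry the full
    relationship (including unphenotyped individuals) for BLUP prediction and
    are optional for residual-like terms.
    """

    name: str
    kind: str
    structure: CovStructure
    env_idx: np.ndarray
    env_labels: list[str]
    K_obs: np.ndarray
    K_full: np.ndarray | None = None
    level_ids: list[str] | None = None
    obs_level_idx: np.ndarray | None = None

    def expand(self, small: np.ndarray) -> np.ndarray:
        """Expand an env-by-env matrix to observation-by-observation."""
        return small[np.ix_(self.env_idx, self.env_idx)]


@dataclass
class REMLResult:
    terms: list[Term]
    theta: np.ndarray
    slices: list[slice]
    loglik: float
    converged: bool
    n_iter: int
    pinned: np.ndarray
    beta: np.ndarray
    beta_cov: np.ndarray
    Py: np.ndarray
    P: np.ndarray
    y: np.ndarray
    X: np.ndarray
    trajectory: list[float] = field(default_factory=list)

    def params_for(self, name: str) -> np.ndarray:
        for t, s in zip(self.terms, self.slices):
            if t.name == name:
                return self.theta[s]
        raise KeyError(name)

    def sigma_for(self, name: str) -> np.ndarray:
        for t, s in zip(self.terms, self.slices):
            if t.name == name:
                return t.structure.sigma(self.theta[s])
        raise KeyError(name)


def _loglik(y, X, terms, slices, theta, resid_floor):
    """Restricted log-likelihood and the by-products the update step needs."""
    n, p = X.shape
    V = np.zeros((n, n))
    for t, s in zip(terms, slices):
        V += t.expand(t.structure.sigma(theta[s])) * t.K_obs
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    try:
        cx = linalg.cho_factor(XtVinvX, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
    B = linalg.cho_solve(cx, VinvX.T, check_finite=False)  # (X'VinvX)^-1 X'Vinv
    P = Vinv - VinvX @ B
    P = 0.5 * (P + P.T)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    beta = B @ y
    beta_cov = linalg.cho_solve(cx, np.eye(p), check_finite=False)
    return ll, P, Py, beta, beta_cov


def reml(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[Term],
    start: np.ndarray | None = None,
    max_iter: int = 200,
    tol_loglik: float = 1e-9,
    tol_param: float = 1e-6,
    verbose: bool = False,
) -> REMLResult:
    """Fit variance parameters by average-information REML.

    Raises :class:`RemlError` on non-convergence (the trajectory is attached
    to the exception) or a singular fixed-effect coefficient matrix.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RemlError("fixed-effect design matrix is rank deficient (aliased term)")

    slices: list[slice] = []
    off = 0
    for t in terms:
        slices.append(slice(off, off + t.structure.n_params))
        off += t.structure.n_params
    n_par = off

    vy = float(np.var(y)) or 1.0
    resid_floor = 1e-8 * vy
    lb = np.concatenate([t.structure.lower_bounds() for t in terms])
    # keep residual variances strictly positive so V stays factorisable
    for t, s in zip(terms, slices):
        if t.kind == "residual":
            lb[s] = resid_floor

    def _project(t):
        t = np.maximum(t, lb)
        for tm, s in zip(terms, slices):
            t[s] = tm.structure.project(t[s])
        return np.maximum(t, lb)

    if start is None:
        n_random = max(1, sum(1 for t in terms if t.kind != "residual"))
        theta = np.empty(n_par)
        for t, s in zip(terms, slices):
            v0 = 0.5 * vy if t.kind == "residual" else 0.5 * vy / n_random
            theta[s] = t.structure.init_params(v0)
    else:
        theta = np.asarray(start, float).copy()
    theta = _project(theta)

    state = _loglik(y, X, terms, slices, theta, resid_floor)
    if state is None:
        raise RemlError("covariance matrix not positive definite at start values")
    ll, P, Py, beta, beta_cov = state
    trajectory = [ll]
    converged = max_iter == 0  # max_iter=0: evaluate at the supplied values
    it = 0

    for it in range(1, max_iter + 1):
        # score and AI on all parameters
        tr_PdV = np.empty(n_par)
        W = np.empty((n, n_par))
        for t, s in zip(terms, slices):
            for j in range(t.structure.n_params):
                k = s.start + j
                dV = t.expand(t.structure.dsigma(theta[s], j)) * t.K_obs
                tr_PdV[k] = float(np.sum(P * dV))
                W[:, k] = dV @ Py
        score = -0.5 * (tr_PdV - Py @ W)
        AI = 0.5 * (W.T @ P @ W)

        at_bound = theta <= lb + 1e-12
        pinned = at_bound & (score < 0)
        free = ~pinned
        if not free.any():
            converged = True
            break
        if np.max(np.abs(score[free])) < 1e-8 * max(1.0, abs(ll)):
            converged = True
            break

        AIf = AI[np.ix_(free, free)]
        ridge = 1e-8 * max(np.trace(AIf) / max(AIf.shape[0], 1), 1e-12)
        accepted = False
        for attempt in range(25):
            try:
                delta = np.linalg.solve(
                    AIf + ridge * np.eye(AIf.shape[0]), score[free]
                )
            except np.linalg.LinAlgError:
                ridge *= 10
                continue
            step = 1.0
            for _half in range(20):
                cand = theta.copy()
                cand[free] = theta[free] + step * delta
                cand = _project(cand)
                st = _loglik(y, X, terms, slices, cand, resid_floor)
                if st is not None and st[0] >= ll - 1e-12:
                    theta_new, state_new = cand, st
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                break
            ridge *= 10  # damp towards a gradient-like step
        if not accepted:
            # scaled-gradient fallback
            g = score.copy()
            g[pinned] = 0.0
            scale = np.abs(theta) + 0.1 * vy
            step = 0.1
            for _half in range(25):
                cand = _project(
                    theta + step * scale * g / (np.abs(g).max() + 1e-30))
                st = _loglik(y, X, terms, slices, cand, resid_floor)
                if st is not None and st[0] > ll + 1e-12:
                    theta_new, state_new = cand, st
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            converged = True  # no ascent direction left: at a (boundary) optimum
            break

        d_ll = state_new[0] - ll
        theta = theta_new
        ll, P, Py, beta, beta_cov = state_new
        trajectory.append(ll)
        if verbose:
            logger.info("iter %d loglik %.8f", it, ll)
        # likelihood-change criterion: parameter drift along flat ridges of
        # over-parameterised structures must not block convergence
        if d_ll < tol_loglik:
            converged = True
            break

    if not converged:
        err = RemlError(f"REML did not converge in {max_iter} iterations")
        err.trajectory = trajectory  # type: ignore[attr-defined]
        raise err

    at_bound = theta <= lb + 1e-10
    return REMLResult(
        terms=terms, theta=theta, slices=slices, loglik=ll, converged=True,
        n_iter=it, pinned=at_bound, beta=beta, beta_cov=beta_cov,
        Py=Py, P=P, y=y, X=X, trajectory=trajectory,
    )
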