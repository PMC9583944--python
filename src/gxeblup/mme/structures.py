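"""Environment covariance structures for genomic-by-environment terms.

Each structure parameterises the covariance of a random effect across genomic
environments.  A genomic term contributes Sigma[env_i, env_j] * K[ind_i, ind_j]
to the phenotypic covariance, so the REML engine only needs Sigma(theta) and
its derivatives with respect to each parameter.

Available structures:

``Uniform``
    single variance, correlation 1 across environments (main effect).
``Diagonal``
    independent variance per environment (interaction / heterogeneous term).
``FactorAnalytic(k)``
    Sigma = Lambda Lambda' + Psi with Lambda lower-triangular (identifiability)
    and Psi a non-negative diagonal.
``Unstructured``
    free symmetric covariance, parameterised by variances and covariances.
"""

from __future__ import annotations

import numpy as np


class CovStructure:
    name = "base"

    def __init__(self, n_env: int):
        if n_env < 1:
            raise ValueError("need at least one environment")
        self.n_env = n_env

    @property
    def n_params(self) -> int:
        raise NotImplementedError

    def param_names(self) -> list[str]:
        raise NotImplementedError

    def lower_bounds(self) -> np.ndarray:
        """Lower bound per parameter (0 for variances, -inf otherwise)."""
        raise NotImplementedError

    def init_params(self, v0: float) -> np.ndarray:
        """Starting values giving environment variances about ``v0``."""
        raise NotImplementedError

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dsigma(self, theta: np.ndarray, k: int) -> np.ndarray:
        raise NotImplementedError

    def project(self, theta: np.ndarray) -> np.ndarray:
        """Project candidate parameters onto the valid region (default: none)."""
        return theta


class Uniform(CovStructure):
    """One variance, correlation 1 everywhere: Sigma = v * J."""

    name = "uniform"

    @property
    def n_params(self) -> int:
        return 1

    def param_names(self):
        return ["v"]

    def lower_bounds(self):
        return np.zeros(1)

    def init_params(self, v0):
        return np.array([v0])

    def sigma(self, theta):
        return theta[0] * np.ones((self.n_env, self.n_env))

    def dsigma(self, theta, k):
        return np.ones((self.n_env, self.n_env))


class IdentityScaled(CovStructure):
    """One variance, independent across environments: Sigma = v * I.

    The classical univariate interaction structure (main effect + iid
    deviation per environment).
    """

    name = "iid"

    @property
    def n_params(self) -> int:
        return 1

    def param_names(self):
        return ["v"]

    def lower_bounds(self):
        return np.zeros(1)

    def init_params(self, v0):
        return np.array([v0])

    def sigma(self, theta):
        return theta[0] * np.eye(self.n_env)

    def dsigma(self, theta, k):
        return np.eye(self.n_env)


class Diagonal(CovStructure):
    """Independent variance per environment: Sigma = diag(v_1..v_q)."""

    name = "diagonal"

    @property
    def n_params(self) -> int:
        return self.n_env

    def param_names(self):
        return [f"v{i}" for i in range(self.n_env)]

    def lower_bounds(self):
        return np.zeros(self.n_env)

    def init_params(self, v0):
        return np.full(self.n_env, v0)

    def sigma(self, theta):
        return np.diag(theta)

    def dsigma(self, theta, k):
        d = np.zeros((self.n_env, self.n_env))
        d[k, k] = 1.0
        return d


class FactorAnalytic(CovStructure):
    """Sigma = Lambda Lambda' + Psi, Lambda (n_env x k) lower-triangular."""

    name = "fa"

    def __init__(self, n_env: int, k: int):
        super().__init__(n_env)
        if not 1 <= k < n_env:
            raise ValueError("FA order k must satisfy 1 <= k < n_env")
        self.k = k
        # (row, col) of the free loading entries, column-major lower triangle
        self.loading_idx = [(r, c) for c in range(k) for r in range(c, n_env)]

    @property
    def n_loadings(self) -> int:
        return len(self.loading_idx)

    @property
    def n_params(self) -> int:
        return self.n_loadings + self.n_env

    def param_names(self):
        return [f"lambda{r}{c}" for r, c in self.loading_idx] + [
            f"psi{i}" for i in range(self.n_env)
        ]

    def lower_bounds(self):
        lb = np.full(self.n_params, -np.inf)
        lb[self.n_loadings:] = 0.0
        return lb

    def init_params(self, v0):
        theta = np.zeros(self.n_params)
        lam = np.sqrt(v0 / 2.0)
        for i, (r, c) in enumerate(self.loading_idx):
            theta[i] = lam if c == 0 else 0.1 * lam
        theta[self.n_loadings:] = v0 / 2.0
        return theta

    def unpack(self, theta) -> tuple[np.ndarray, np.ndarray]:
        L = np.zeros((self.n_env, self.k))
        for i, (r, c) in enumerate(self.loading_idx):
            L[r, c] = theta[i]
        psi = np.asarray(theta[self.n_loadings:], float)
        return L, psi

    def sigma(self, theta):
        L, psi = self.unpack(theta)
        return L @ L.T + np.diag(psi)

    def dsigma(self, theta, k):
        n = self.n_env
        if k < self.n_loadings:
            r, c = self.loading_idx[k]
            L, _ = self.unpack(theta)
            d = np.zeros((n, n))
            d[r, :] += L[:, c]
            d[:, r] += L[:, c]
            return d
        d = np.zeros((n, n))
        i = k - self.n_loadings
        d[i, i] = 1.0
        return d

    @staticmethod
    def canonicalise(L: np.ndarray) -> np.ndarray:
        """Sign convention: first nonzero loading of each factor >= 0."""
        L = L.copy()
        for c in range(L.shape[1]):
            nz = np.nonzero(np.abs(L[:, c]) > 1e-12)[0]
            if len(nz) and L[nz[0], c] < 0:
                L[:, c] = -L[:, c]
        return L


class Unstructured(CovStructure):
    """Free symmetric Sigma (variances + covariances), kept PSD by projection.

    Candidate parameter vectors whose implied Sigma has negative eigenvalues
    are projected back onto the covariance cone (eigenvalues clipped at
    zero): an unconstrained Sigma can otherwise wander into indefinite
    matrices that still yield a factorisable V and a spuriously high
    likelihood.
    """

    name = "us"

    def __init__(self, n_env: int):
        super().__init__(n_env)
        self.idx = [(r, c) for r in range(n_env) for c in range(r + 1)]

    @property
    def n_params(self) -> int:
        return len(self.idx)

    def param_names(self):
        return [f"s{r}{c}" for r, c in self.idx]

    def lower_bounds(self):
        return np.array([0.0 if r == c else -np.inf for r, c in self.idx])

    def init_params(self, v0):
        return np.array([v0 if r == c else 0.5 * v0 for r, c in self.idx])

    def sigma(self, theta):
        S = np.zeros((self.n_env, self.n_env))
        for t, (r, c) in zip(theta, self.idx):
            S[r, c] = S[c, r] = t
        return S

    def dsigma(self, theta, k):
        r, c = self.idx[k]
        d = np.zeros((self.n_env, self.n_env))
        d[r, c] = d[c, r] = 1.0
        return d

    def project(self, theta):
        S = self.sigma(theta)
        w, V = np.linalg.eigh(S)
        if w[0] >= 0:
            return theta
        S = (V * np.maximum(w, 0.0)) @ V.T
        return np.array([S[r, c] for r, c in self.idx])


def make_structure(kind: str, n_env: int) -> CovStructure:
    """Factory from a short structure code: uniform | diagonal | faK | us."""
    if kind == "uniform":
        return Uniform(n_env)
    if kind == "iid":
        return IdentityScaled(n_env)
    if kind == "diagonal":
        return Diagonal(n_env)
    if kind == "us":
        return Unstructured(n_env)
    if kind.startswith("fa"):
        return FactorAnalytic(n_env, int(kind[2:]))
    raise ValueError(f"unknown covariance structure {kind!r}")


def fa_expand(loadings: np.ndarray, specific: np.ndarray):
    """Expand an FA parameterisation to its covariance matrix.

    Returns ``(sigma, logdet, inverse)`` with the log-determinant and inverse
    computed through the Woodbury/matrix-determinant identities, which stay
    cheap when the number of factors is small relative to the number of
    environments.  ``specific`` entries must be non-negative; exact zeros are
    handled by a dense fallback.
    """
    L = np.atleast_2d(np.asarray(loadings, float))
    if L.shape[0] == 1 and L.shape[1] > 1:
        L = L.T
    psi = np.asarray(specific, float)
    if (psi < 0).any():
        raise ValueError("specific variances must be non-negative")
    sigma = L @ L.T + np.diag(psi)
    if (psi <= 0).any():
        # Woodbury needs invertible Psi; fall back to dense algebra
        sign, logdet = np.linalg.slogdet(sigma)
        inv = np.linalg.pinv(sigma) if sign <= 0 else np.linalg.inv(sigma)
        return sigma, logdet, inv
    psi_inv = 1.0 / psi
    k = L.shape[1]
    core = np.eye(k) + (L.T * psi_inv) @ L
    core_inv = np.linalg.inv(core)
    inv = np.diag(psi_inv) - (psi_inv[:, None] * L) @ core_inv @ (L.T * psi_inv)
    logdet = float(np.linalg.slogdet(core)[1] + np.sum(np.log(psi)))
    return sigma, logdet, inv
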