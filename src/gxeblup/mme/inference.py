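"""Likelihood-ratio tests with boundary corrections.

Testing a variance component against zero places the null hypothesis on the
boundary of the parameter space, so the LRT statistic is asymptotically a
mixture of chi-square distributions rather than a single chi-square.  For
``m`` boundary parameters plus ``f`` unconstrained parameters the p-value is
computed from the binomial 50:50 mixture

    p = sum_i C(m, i) 2^{-m} P(chi2_{f+i} >= T),

which reduces to the familiar 0.5 * P(chi2_1 >= T) for a single variance
component (chi2_0 is a point mass at zero).
"""

from __future__ import annotations

import logging
import math

from scipy import stats

logger = logging.getLogger(__name__)

#: default significance threshold for variance-component tests
DEFAULT_ALPHA = 0.01


def chi2_mixture_sf(T: float, n_boundary: int, n_free: int = 0) -> float:
    """Upper tail of the chi-square mixture at T (T already clipped >= 0)."""
    if T <= 0:
        return 1.0
    if n_boundary == 0:
        df = max(n_free, 1)
        return float(stats.chi2.sf(T, df))
    m = n_boundary
    p = 0.0
    for i in range(m + 1):
        w = math.comb(m, i) * 0.5**m
        df = n_free + i
        tail = 0.0 if df == 0 else float(stats.chi2.sf(T, df))
        p += w * tail
    return p


def lrt_boundary(
    loglik_full: float,
    loglik_reduced: float,
    n_boundary_params: int,
    n_free_params: int = 0,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Boundary-adjusted likelihood-ratio test between nested REML fits.

    Returns ``(statistic, p_value)``.  A full-model log-likelihood below the
    reduced one beyond ``tol`` indicates a convergence problem; it is warned
    about and the statistic clipped at zero.
    """
    T = 2.0 * (loglik_full - loglik_reduced)
    if T < -tol:
        logger.warning(
            "full-model loglik %.6f below reduced %.6f; convergence suspect",
            loglik_full, loglik_reduced,
        )
    T = max(T, 0.0)
    return T, chi2_mixture_sf(T, n_boundary_params, n_free_params)
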