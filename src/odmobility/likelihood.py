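"""Censored Poisson log-likelihood shared by every model in the package.

Operator anonymity withholds trip counts below a threshold T (50 in the
data the package emulates).  A censored cell contributes
``log P(Y <= T - 1 | mu)`` to the likelihood instead of a point mass; the
Poisson CDF is evaluated through the regularized upper incomplete gamma
function, with a log-sum-exp fallback where the direct evaluation
underflows (large mu), keeping the computation stable for mu up to 1e7
and beyond.
"""

from __future__ import annotations

import numpy as np
from scipy import special

_TINY = 1e-300


def poisson_logpmf(y, mu) -> np.ndarray:
    """log Poisson pmf, valid for non-negative real y (mean-mode data are real)."""
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), _TINY)
    return y * np.log(mu) - mu - special.gammaln(y + 1.0)


def poisson_logcdf(k, mu) -> np.ndarray:
    """log P(Y <= k) for Y ~ Poisson(mu), numerically stable.

    Uses ``P(Y <= k) = Q(k + 1, mu)`` (regularized upper incomplete gamma).
    Where that underflows, the result is recomputed as a log-sum-exp over
    the k + 1 pmf terms.
    """
    scalar = np.isscalar(k) and np.isscalar(mu)
    k = np.atleast_1d(np.asarray(k, float))
    mu = np.atleast_1d(np.asarray(mu, float))
    k, mu = np.broadcast_arrays(k, mu)
    q = special.gammaincc(k + 1.0, mu)
    with np.errstate(divide="ignore"):
        out = np.log(q)
    small = q < 1e-280
    if small.any():
        ks = k[small].astype(int)
        mus = mu[small]
        vals = np.empty(ks.shape, float)
        for kk in np.unique(ks):
            rows = ks == kk
            j = np.arange(kk + 1.0)
            terms = poisson_logpmf(j[None, :], mus[rows][:, None])
            vals[rows] = special.logsumexp(terms, axis=1)
        out[small] = vals
    return float(out[0]) if scalar else out


def censored_poisson_loglik(
    y,
    mu,
    threshold: int = 50,
    censored=None,
    bound=None,
    strict: bool = False,
) -> np.ndarray:
    """Log-likelihood of trip-count cells under censoring.

    Observed cells (``censored`` false) contribute the Poisson log-pmf of
    ``y``; censored cells contribute ``log P(Y <= bound)`` where ``bound``
    defaults to ``threshold - 1``.  ``y`` may be NaN on censored cells.
    ``mu = 0`` is admitted only with ``y = 0`` or censoring (any other
    combination returns -inf).  In ``strict`` mode an observed count below
    the threshold raises, since real operator data never shows one.
    """
    y = np.atleast_1d(np.asarray(y, float))
    mu = np.broadcast_to(np.asarray(mu, float), y.shape).astype(float)
    if (mu < 0).any():
        raise ValueError("negative Poisson mean")
    if censored is None:
        censored = np.isnan(y)
    censored = np.broadcast_to(np.asarray(censored, bool), y.shape)
    if strict and threshold > 0:
        low = ~censored & (y < threshold)
        if low.any():
            raise ValueError("observed count below censor threshold in strict mode")
    if bound is None:
        bound = np.full(y.shape, threshold - 1, float)
    else:
        bound = np.broadcast_to(np.asarray(bound, float), y.shape).astype(float)
    out = np.empty(y.shape, float)
    obs = ~censored
    out[obs] = poisson_logpmf(y[obs], mu[obs])
    out[censored] = poisson_logcdf(bound[censored], mu[censored])
    return out


def censored_poisson_dloglik_dmu(y, mu, censored, bound) -> np.ndarray:
    """d/dmu of :func:`censored_poisson_loglik` per cell.

    Observed: y/mu - 1.  Censored: -pmf(bound; mu)/CDF(bound; mu),
    evaluated in log space for stability.
    """
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), _TINY)
    censored = np.asarray(censored, bool)
    bound = np.asarray(bound, float)
    out = np.empty(y.shape, float)
    obs = ~censored
    out[obs] = y[obs] / mu[obs] - 1.0
    if censored.any():
        b, m = bound[censored], mu[censored]
        out[censored] = -np.exp(poisson_logpmf(b, m) - poisson_logcdf(b, m))
    return out
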