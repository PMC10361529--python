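"""Gravity-baseline variant of the decline model and BIC model comparison.

The gravity model replaces the free per-route baseline rates with the
power law

    r_ija = theta * p_ia^alpha * pbar_j^delta * d(i, j)^gamma,

where p_ia is the origin's subscriber count in age group a, pbar_j the
destination's census population (a proxy for attractiveness) and d(i, j)
the centroid distance.  Only four baseline parameters are learned instead
of one per directed route and age, so a Bayesian information criterion
comparison against the free-baseline model asks whether that parametric
structure is rich enough to describe observed travel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .decline import (
    DeclineData,
    FitResult,
    OptimizerConfig,
    PriorConfig,
    _core_nll_grad,
    _normal_nlp,
    build_decline_data,
    laplace_sds,
)
from .io_prep import CovariateSet, TripPanel, ValidationError, ZipTable


def gravity_rate(theta, alpha, delta, gamma, p_ia, pbar_j, d_ij):
    """Baseline trip rate theta * p^alpha * pbar^delta * d^gamma.

    ``d_ij`` must be positive: the within-zip diagonal is excluded from
    every model in this package.
    """
    p_ia = np.asarray(p_ia, float)
    pbar_j = np.asarray(pbar_j, float)
    d_ij = np.asarray(d_ij, float)
    if theta <= 0:
        raise ValidationError("gravity scale theta must be positive")
    if (d_ij <= 0).any():
        raise ValidationError("gravity rate undefined at zero distance (i = j)")
    if (p_ia <= 0).any() or (pbar_j <= 0).any():
        raise ValidationError("gravity rate requires positive populations")
    return theta * p_ia**alpha * pbar_j**delta * d_ij**gamma


def _gravity_objective(x: np.ndarray, D: DeclineData, priors: PriorConfig):
    """Negative log posterior for [log_theta, alpha, delta, gamma, log_c, beta, beta_a]."""
    n_c, n_b = D.n_c, D.X1.shape[1]
    g4 = x[:4]
    log_c = x[4 : 4 + n_c]
    beta = x[4 + n_c : 4 + n_c + n_b]
    beta_a = x[4 + n_c + n_b :]
    log_r = g4[0] + g4[1] * D.log_p_sub + g4[2] * D.log_pop_dest + g4[3] * D.log_dist
    nll, g_r, g_c, g_b, g_a = _core_nll_grad(log_r, log_c, beta, beta_a, D)
    g_grav = np.array(
        [
            g_r.sum(),
            float(g_r @ D.log_p_sub),
            float(g_r @ D.log_pop_dest),
            float(g_r @ D.log_dist),
        ]
    )
    if not priors.flat:
        v, g = _normal_nlp(g4, 0.0, priors.gravity_sd)
        nll += v
        g_grav = g_grav + g
        if n_c:
            v, g = _normal_nlp(log_c, priors.log_c_mean, priors.log_c_sd)
            nll += v
            g_c = g_c + g
        v, g = _normal_nlp(beta, 0.0, priors.beta_sd)
        nll += v
        g_b = g_b + g
        if beta_a.size:
            v, g = _normal_nlp(beta_a, 0.0, priors.beta_a_sd)
            nll += v
            g_a = g_a + g
    return nll, np.concatenate([g_grav, g_c, g_b, g_a])


def fit_gravity_decline(
    panel: TripPanel,
    covs: CovariateSet,
    ziptable: ZipTable,
    priors: PriorConfig | None = None,
    baseline_weeks: int = 4,
    max_week: int | None = 9,
    optimizer: OptimizerConfig | None = None,
    compute_sds: bool = True,
    data: DeclineData | None = None,
) -> FitResult:
    """MAP fit of the decline model with a gravity-structured baseline.

    Identical likelihood and decline structure to the free-baseline model;
    only the baseline rates are re-parameterized as the four-parameter
    power law (on the log scale for optimizer stability), so the parameter
    count is 4 + |c| + |beta| + |beta_a|.
    """
    priors = priors or PriorConfig()
    opt = optimizer or OptimizerConfig()
    # gravity rates are inherently directed (origin subscribers, destination population)
    D = data if data is not None else build_decline_data(
        panel, covs, ziptable, baseline_weeks, max_week, rate_structure="directed"
    )
    if D.rate_structure != "directed":
        raise ValidationError("gravity fit requires directed rate structure")
    n_b = D.X1.shape[1]
    # start theta at the level matching the mean empirical baseline rate
    lt0 = float(np.mean(D.log_r_init - 0.5 * D.log_p_sub - 0.5 * D.log_pop_dest + 1.0 * D.log_dist))
    x0 = np.concatenate(
        [[lt0, 0.5, 0.5, -1.0], np.full(D.n_c, np.log(0.05)), np.zeros(n_b), np.zeros(len(D.ages) - 1)]
    )

    def obj(x):
        return _gravity_objective(x, D, priors)

    res = optimize.minimize(
        obj,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": opt.maxiter,
            "maxfun": opt.maxfun,
            "gtol": opt.pgtol,
            "ftol": opt.factr * np.finfo(float).eps,
        },
    )
    x = res.x
    logpost_val, grad = obj(x)
    grad_norm = float(np.abs(grad).max())
    n_c = D.n_c
    log_r = x[0] + x[1] * D.log_p_sub + x[2] * D.log_pop_dest + x[3] * D.log_dist
    nll_lik, *_ = _core_nll_grad(log_r, x[4 : 4 + n_c], x[4 + n_c : 4 + n_c + n_b], x[4 + n_c + n_b :], D)
    sd_vec = None
    if compute_sds:
        sd_vec, _ok = laplace_sds(lambda z: obj(z)[1], x)
    names = covs.names
    gnames = ["log_theta", "alpha", "delta", "gamma"]
    est = {
        "gravity": pd.Series(x[:4], index=gnames),
        "log_c": pd.Series(x[4 : 4 + n_c], index=D.decline_weeks),
        "c": pd.Series(np.exp(x[4 : 4 + n_c]), index=D.decline_weeks),
        "beta": pd.Series(x[4 + n_c : 4 + n_c + n_b], index=names),
        "beta_a": pd.Series(x[4 + n_c + n_b :], index=D.ages[1:]),
        "log_r": pd.Series(log_r, index=D.r_index),
    }
    sds = {}
    if sd_vec is not None:
        sds = {
            "gravity": pd.Series(sd_vec[:4], index=gnames),
            "log_c": pd.Series(sd_vec[4 : 4 + n_c], index=D.decline_weeks),
            "beta": pd.Series(sd_vec[4 + n_c : 4 + n_c + n_b], index=names),
            "beta_a": pd.Series(sd_vec[4 + n_c + n_b :], index=D.ages[1:]),
        }
    loglik = -nll_lik
    n_params = 4 + n_c + n_b + (len(D.ages) - 1)
    return FitResult(
        model="decline_gravity",
        estimates=est,
        sds=sds,
        loglik=loglik,
        logpost=-logpost_val,
        n_params=n_params,
        n_obs=D.n_cells,
        bic=n_params * float(np.log(D.n_cells)) - 2.0 * loglik,
        converged=grad_norm < opt.grad_tol,
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        x=x,
        meta={"covariate_names": names, "baseline_weeks": baseline_weeks},
    )


def compare_bic(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted models on the same data by BIC (lower preferred).

    All fits must share ``n_obs``; raises otherwise.  Returns a table of
    parameter counts, log-likelihoods, BIC and delta-BIC versus the best.
    """
    if len({f.n_obs for f in fits}) > 1:
        raise ValidationError("BIC comparison requires fits on identical data (equal n_obs)")
    rows = [
        {
            "model": f.model,
            "n_params": f.n_params,
            "n_obs": f.n_obs,
            "loglik": f.loglik,
            "bic": f.bic,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows)
    out["delta_bic"] = out["bic"] - out["bic"].min()
    out["preferred"] = out["delta_bic"] == 0.0
    return out.sort_values("bic").reset_index(drop=True)
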