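"""Model of summer travel relative to the pre-pandemic baseline.

After the initial decline, travel stabilised; this model relates the trip
rate over a stable multi-week block to the baseline route rates:

    lambda_ija = n_weeks * exp(-(beta0 + beta' X_ij + beta_a)) * r_ija,

with r_ija the per-subscriber baseline weekly rates learned by the
decline model (treated as fixed plug-in values; their uncertainty is not
propagated), beta0 a global log-reduction, and X_ij the route/zip
covariates (distance quartile, higher-income subscriber proportion,
standardized median income — no case rate).  The observed count per route
and age pools both directions as in the decline model, and the shared
censored Poisson likelihood applies with the bound scaled to the
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .decline import (
    FitResult,
    OptimizerConfig,
    PriorConfig,
    _normal_nlp,
    laplace_sds,
)
from .io_prep import (
    AGE_GROUPS,
    CovariateSet,
    SUBSCRIBER_COLUMNS,
    TripPanel,
    ValidationError,
    ZipTable,
    canonical_pair,
)
from .likelihood import censored_poisson_dloglik_dmu, censored_poisson_loglik


@dataclass
class SummerParams:
    """Parameter vector of the summer model (reference age fixed at 0)."""

    beta0: float
    beta: pd.Series
    beta_a: pd.Series
    n_weeks: int

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValidationError("n_weeks must be at least 1")


@dataclass
class SummerData:
    """Vectorized per-(route, age) arrays for the aggregated summer block."""

    pairs: list[tuple[str, str]]
    ages: list[str]
    n_weeks: int
    y: np.ndarray
    censored: np.ndarray
    bound: np.ndarray
    r1: np.ndarray  # baseline rate, direction i->j
    r2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    age_idx: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.y)


def aggregate_summer_panel(
    panel: TripPanel,
    weeks: set[int] | None = None,
    censored_policy: str = "midpoint",
) -> TripPanel:
    """Collapse a weekly panel to one cell per (route, age) over a window.

    ``n_weeks`` is the number of distinct non-missing weeks in the window.
    Censored weekly cells contribute the midpoint ``threshold / 2`` to the
    sum (``censored_policy='midpoint'``) or are dropped (``'drop'``); a
    cell is fully censored only when every contributing week was, in which
    case its count is unknown but at most ``n_weeks * (threshold - 1)``
    (recorded in a ``censor_bound`` column).  Already-aggregate input
    passes through.
    """
    if panel.resolution == "aggregate":
        return panel
    if panel.resolution != "weekly":
        raise ValidationError("aggregate_summer_panel expects a weekly panel")
    if censored_policy not in ("midpoint", "drop"):
        raise ValidationError(f"unknown censored_policy {censored_policy!r}")
    df = panel.df
    if weeks is not None:
        df = df[df["week"].isin(weeks)]
    df = df[~df["week"].isin(panel.data_loss_weeks)]
    n_weeks = df["week"].nunique()
    if n_weeks == 0:
        raise ValidationError("no usable weeks in the summer window")
    thr = panel.censor_threshold
    work = df.copy()
    if censored_policy == "midpoint":
        work["count"] = work["count"].fillna(thr / 2.0)
    else:
        work = work[~work["censored"]]
    agg = (
        work.groupby(["origin", "dest", "age_group"], sort=True)
        .agg(count=("count", "sum"), all_censored=("censored", "all"))
        .reset_index()
    )
    agg["censored"] = agg["all_censored"]
    agg.loc[agg["censored"], "count"] = np.nan
    agg["censor_bound"] = np.where(agg["censored"], float(n_weeks * (thr - 1)), np.nan)
    agg = agg.drop(columns="all_censored")
    return TripPanel(
        df=agg,
        resolution="aggregate",
        censor_threshold=thr,
        n_weeks=n_weeks,
    )


def build_summer_data(
    panel: TripPanel,
    baseline_log_r: pd.Series,
    covs: CovariateSet,
    ziptable: ZipTable,
) -> SummerData:
    """Assemble arrays from an aggregated summer panel and plug-in rates."""
    if panel.resolution != "aggregate":
        raise ValidationError("fit_summer expects an aggregated panel (see aggregate_summer_panel)")
    if panel.n_weeks is None:
        raise ValidationError("aggregated panel must declare n_weeks")
    if covs.rel_case is not None:
        covs = CovariateSet(
            covs.quartile_of_pair,
            covs.quartile_bounds,
            covs.zip_static,
            None,
            covs.reference_quartile,
        )
    df = panel.df.copy()
    pk = [canonical_pair(o, d) for o, d in zip(df["origin"], df["dest"])]
    df["pair_i"] = [p[0] for p in pk]
    df["pair_j"] = [p[1] for p in pk]
    cells = (
        df.groupby(["pair_i", "pair_j", "age_group"], sort=True)
        .agg(
            count=("count", "sum"),
            censored=("censored", "any"),
            bound=("censor_bound", "max") if "censor_bound" in df.columns else ("count", "size"),
        )
        .reset_index()
    )
    if "censor_bound" not in df.columns:
        cells["bound"] = np.nan
    cells.loc[cells["censored"], "count"] = np.nan
    thr = panel.censor_threshold
    cells["bound"] = cells["bound"].fillna(float(thr - 1))

    ages = [a for a in AGE_GROUPS if a in set(cells["age_group"])]
    age_pos = {a: k for k, a in enumerate(ages)}
    pairs = sorted(set(zip(cells["pair_i"], cells["pair_j"])))
    subs = ziptable.df[[SUBSCRIBER_COLUMNS[a] for a in ages]].to_numpy(float)
    zpos = {z: k for k, z in enumerate(ziptable.df.index)}
    age_idx = cells["age_group"].map(age_pos).to_numpy()
    i_pos = cells["pair_i"].map(zpos).to_numpy()
    j_pos = cells["pair_j"].map(zpos).to_numpy()
    cell_pairs = list(zip(cells["pair_i"], cells["pair_j"]))
    X1 = covs.design_matrix(cells["pair_i"].to_numpy(), cell_pairs, None)
    X2 = covs.design_matrix(cells["pair_j"].to_numpy(), cell_pairs, None)

    key1 = list(zip(cells["pair_i"], cells["pair_j"], cells["age_group"]))
    key2 = list(zip(cells["pair_j"], cells["pair_i"], cells["age_group"]))
    missing = [k for k in key1 + key2 if k not in baseline_log_r.index]
    if missing:
        raise ValidationError(f"baseline rate missing for routes: {missing[:5]}")
    r1 = np.exp(baseline_log_r.loc[key1].to_numpy(float))
    r2 = np.exp(baseline_log_r.loc[key2].to_numpy(float))
    return SummerData(
        pairs=pairs,
        ages=ages,
        n_weeks=int(panel.n_weeks),
        y=cells["count"].to_numpy(float),
        censored=cells["censored"].to_numpy(bool),
        bound=cells["bound"].to_numpy(float),
        r1=r1,
        r2=r2,
        p1=subs[i_pos, age_idx],
        p2=subs[j_pos, age_idx],
        X1=X1,
        X2=X2,
        age_idx=age_idx,
    )


def expected_summer_trips(params: SummerParams, data: SummerData) -> np.ndarray:
    """Expected pooled count per (route, age) cell under the summer model."""
    beta = params.beta.to_numpy(float)
    beta_a = np.concatenate([[0.0], params.beta_a.to_numpy(float)])
    eta1 = params.beta0 + data.X1 @ beta + beta_a[data.age_idx]
    eta2 = params.beta0 + data.X2 @ beta + beta_a[data.age_idx]
    return params.n_weeks * (
        data.p1 * data.r1 * np.exp(-eta1) + data.p2 * data.r2 * np.exp(-eta2)
    )


def _summer_objective(x: np.ndarray, D: SummerData, priors: PriorConfig):
    n_b = D.X1.shape[1]
    beta0 = x[0]
    beta = x[1 : 1 + n_b]
    beta_a_free = x[1 + n_b :]
    beta_a = np.concatenate([[0.0], beta_a_free])
    eta1 = np.clip(beta0 + D.X1 @ beta + beta_a[D.age_idx], -40.0, 40.0)
    eta2 = np.clip(beta0 + D.X2 @ beta + beta_a[D.age_idx], -40.0, 40.0)
    m1 = D.n_weeks * D.p1 * D.r1 * np.exp(-eta1)
    m2 = D.n_weeks * D.p2 * D.r2 * np.exp(-eta2)
    mu = m1 + m2
    ll = censored_poisson_loglik(D.y, mu, censored=D.censored, bound=D.bound, threshold=0)
    nll = -float(ll.sum())
    w = censored_poisson_dloglik_dmu(D.y, mu, D.censored, D.bound)
    a1, a2 = w * m1, w * m2
    g_beta0 = float(np.sum(a1 + a2))  # d mu / d beta0 = -mu
    g_beta = D.X1.T @ a1 + D.X2.T @ a2
    g_ba = np.bincount(D.age_idx, weights=a1 + a2, minlength=len(D.ages))[1:]
    if not priors.flat:
        v, g = _normal_nlp(np.array([beta0]), priors.beta0_mean, priors.beta0_sd)
        nll += v
        g_beta0 += float(g[0])
        v, g = _normal_nlp(beta, 0.0, priors.beta_sd)
        nll += v
        g_beta = g_beta + g
        if beta_a_free.size:
            v, g = _normal_nlp(beta_a_free, 0.0, priors.beta_a_sd)
            nll += v
            g_ba = g_ba + g
    return nll, np.concatenate([[g_beta0], g_beta, g_ba])


def fit_summer(
    panel: TripPanel,
    baseline_log_r: pd.Series,
    covs: CovariateSet,
    ziptable: ZipTable,
    priors: PriorConfig | None = None,
    optimizer: OptimizerConfig | None = None,
    init: np.ndarray | None = None,
    compute_sds: bool = True,
    data: SummerData | None = None,
) -> FitResult:
    """MAP + Laplace fit of the summer model on an aggregated panel.

    Baseline rates are plug-in point values (typically the decline fit's
    ``log_r`` estimates); their uncertainty is not propagated, which the
    result's metadata flags.
    """
    priors = priors or PriorConfig()
    opt = optimizer or OptimizerConfig()
    D = data if data is not None else build_summer_data(panel, baseline_log_r, covs, ziptable)
    n_b = D.X1.shape[1]
    x0 = np.zeros(1 + n_b + len(D.ages) - 1) if init is None else np.asarray(init, float).copy()

    def obj(x):
        return _summer_objective(x, D, priors)

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
    nll_lik, _ = _summer_objective(x, D, PriorConfig.flat_priors())
    sd_vec = None
    if compute_sds:
        sd_vec, _ok = laplace_sds(lambda z: obj(z)[1], x)
    names = [n for n in covs.names if n != "relative_case_rate"]
    est = {
        "beta0": float(x[0]),
        "beta": pd.Series(x[1 : 1 + n_b], index=names),
        "beta_a": pd.Series(x[1 + n_b :], index=D.ages[1:]),
    }
    sds = {}
    if sd_vec is not None:
        sds = {
            "beta0": float(sd_vec[0]),
            "beta": pd.Series(sd_vec[1 : 1 + n_b], index=names),
            "beta_a": pd.Series(sd_vec[1 + n_b :], index=D.ages[1:]),
        }
    loglik = -nll_lik
    n_params = len(x)
    return FitResult(
        model="summer",
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
        meta={
            "covariate_names": names,
            "n_weeks": D.n_weeks,
            "baseline_rates": "plug-in point estimates; uncertainty not propagated",
        },
    )
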