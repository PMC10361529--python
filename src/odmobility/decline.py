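"""Bayesian model of the early-pandemic decline in zip-to-zip travel.

The trip rate from zip i to zip j in age group a and week t is

    lambda_ijat = r_ija * q_ijat,

where r_ija is a per-subscriber baseline weekly rate learned per directed
route and the decline fraction obeys

    log q_ijat = - exp(beta' X_ijt + beta_a) * sum_{k <= t} c_k,

with c_k >= 0 the city-wide weekly decrease increments (zero during the
baseline month, so q = 1 there) and X_ijt the route/zip covariates of the
origin zip (distance quartile, proportion of higher-income subscribers,
relative case rate, standardized median income).  Because the data cannot
attribute a trip to a home zip, the observed count between i and j pools
both directions:

    Y_ijat ~ Poisson(p_ia * lambda_ijat + p_ja * lambda_jiat),

with p_ia the subscriber count, and counts below the anonymity threshold
entering through the censored Poisson likelihood.

Inference is maximum a posteriori by quasi-Newton minimization of the
negative log posterior with analytic gradients, followed by a Laplace
approximation: parameter standard deviations are square roots of the
diagonal of the inverse Hessian at the mode (so the uncertainty of the
covariate effects accounts for their coupling with the baseline rates and
the weekly decrements).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .io_prep import (
    AGE_GROUPS,
    CovariateSet,
    SUBSCRIBER_COLUMNS,
    TripPanel,
    ValidationError,
    ZipTable,
    canonical_pair,
    haversine_km,
)
from .likelihood import censored_poisson_dloglik_dmu, censored_poisson_loglik

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Priors and optimizer configuration
# ---------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Weakly-informative Normal priors, centered on no effect.

    Baseline log rates are centered on the empirical baseline rate of each
    route (SD 1); log weekly decrements on -3 (c ~ 0.05, SD 1.5 on the log
    scale); covariate and age effects on 0 (SD 1); the summer intercept on
    0 (SD 2); gravity parameters on 0 (SD 5).  ``flat = True`` switches
    every prior off, turning MAP into maximum likelihood.
    """

    log_r_sd: float = 1.0
    log_c_mean: float = -3.0
    log_c_sd: float = 1.5
    beta_sd: float = 1.0
    beta_a_sd: float = 1.0
    beta0_mean: float = 0.0
    beta0_sd: float = 2.0
    gravity_sd: float = 5.0
    flat: bool = False

    @classmethod
    def flat_priors(cls) -> "PriorConfig":
        return cls(flat=True)


@dataclass
class OptimizerConfig:
    maxiter: int = 5000
    maxfun: int = 20000
    pgtol: float = 1e-8
    factr: float = 10.0
    grad_tol: float = 0.1  # sup-norm defining the 'converged' flag


def _normal_nlp(x: np.ndarray, mean, sd) -> tuple[float, np.ndarray]:
    """Negative log density of independent Normals and its gradient."""
    z = (x - mean) / sd
    val = 0.5 * float(np.sum(z * z)) + float(np.sum(np.log(sd) * np.ones_like(x))) + 0.5 * _LOG_2PI * x.size
    return val, z / sd


# ---------------------------------------------------------------------------
# Data assembly
# ---------------------------------------------------------------------------


@dataclass
class DeclineData:
    """Vectorized observation arrays for one city's decline window."""

    pairs: list[tuple[str, str]]
    ages: list[str]
    weeks: list[int]
    decline_weeks: list[int]
    # per cell
    y: np.ndarray
    censored: np.ndarray
    bound: np.ndarray
    idx1: np.ndarray  # index into the directed log-r vector, direction i->j
    idx2: np.ndarray  # direction j->i
    logp1: np.ndarray
    logp2: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    age_idx: np.ndarray
    cum_idx: np.ndarray  # position among decline weeks; -1 for baseline weeks
    # per baseline-rate entry (one per pair/age when pooled, two when directed)
    r_index: pd.MultiIndex  # (origin, dest, age_group)
    log_r_init: np.ndarray
    # gravity covariates per rate entry (log origin subscribers, log dest census pop, log distance)
    log_p_sub: np.ndarray
    log_pop_dest: np.ndarray
    log_dist: np.ndarray
    rate_structure: str = "pooled"  # "pooled" | "directed"

    @property
    def n_cells(self) -> int:
        return len(self.y)

    @property
    def n_r(self) -> int:
        return len(self.log_r_init)

    @property
    def n_c(self) -> int:
        return len(self.decline_weeks)


def build_decline_data(
    panel: TripPanel,
    covs: CovariateSet,
    ziptable: ZipTable,
    baseline_weeks: int = 4,
    max_week: int | None = None,
    rate_structure: str = "pooled",
) -> DeclineData:
    """Assemble model arrays from a weekly panel.

    Storage is undirected: one observation per (unordered pair, age, week).
    Records present in both directions are pooled (counts summed; the cell
    is censored if either direction is).  ``max_week`` restricts the panel
    to the decline window (e.g. 9 weeks).

    ``rate_structure`` selects the baseline-rate parameterization.  The
    default, ``"pooled"``, learns one per-subscriber rate per unordered
    pair and age — the identifiable choice given that the observations
    pool directions; a free per-direction split behaves as an incidental
    nuisance parameter and biases direction-differentiating covariate
    effects.  ``"directed"`` keeps distinct r_ija and r_jia.
    """
    if rate_structure not in ("pooled", "directed"):
        raise ValidationError(f"unknown rate_structure {rate_structure!r}")
    if panel.resolution != "weekly":
        raise ValidationError("decline model expects a weekly panel")
    df = panel.df.copy()
    if max_week is not None:
        df = df[df["week"] <= max_week]
    known = set(ziptable.df.index)
    bad = (set(df["origin"]) | set(df["dest"])) - known
    if bad:
        raise ValidationError(f"routes reference unknown zips: {sorted(bad)[:5]}")
    pk = [canonical_pair(o, d) for o, d in zip(df["origin"], df["dest"])]
    df["pair_i"] = [p[0] for p in pk]
    df["pair_j"] = [p[1] for p in pk]
    cells = (
        df.groupby(["pair_i", "pair_j", "age_group", "week"], sort=True)
        .agg(count=("count", "sum"), censored=("censored", "any"))
        .reset_index()
    )
    cells.loc[cells["censored"], "count"] = np.nan

    pairs = sorted(set(zip(cells["pair_i"], cells["pair_j"])))
    pair_pos = {p: k for k, p in enumerate(pairs)}
    ages = [a for a in AGE_GROUPS if a in set(cells["age_group"])]
    age_pos = {a: k for k, a in enumerate(ages)}
    n_ages = len(ages)
    weeks = sorted(cells["week"].unique())
    decline_weeks = [w for w in weeks if w > baseline_weeks]
    dw_pos = {w: k for k, w in enumerate(decline_weeks)}

    pair_idx = np.array([pair_pos[p] for p in zip(cells["pair_i"], cells["pair_j"])])
    age_idx = cells["age_group"].map(age_pos).to_numpy()
    if rate_structure == "pooled":
        idx1 = pair_idx * n_ages + age_idx
        idx2 = idx1
    else:
        idx1 = (pair_idx * 2 + 0) * n_ages + age_idx
        idx2 = (pair_idx * 2 + 1) * n_ages + age_idx
    cum_idx = cells["week"].map(lambda w: dw_pos.get(w, -1)).to_numpy()

    subs = ziptable.df[[SUBSCRIBER_COLUMNS[a] for a in ages]].to_numpy(float)
    zpos = {z: k for k, z in enumerate(ziptable.df.index)}
    i_pos = cells["pair_i"].map(zpos).to_numpy()
    j_pos = cells["pair_j"].map(zpos).to_numpy()
    p1 = subs[i_pos, age_idx]
    p2 = subs[j_pos, age_idx]
    if (p1 <= 0).any() or (p2 <= 0).any():
        raise ValidationError("zero subscriber counts on modelled routes")

    cell_pairs = list(zip(cells["pair_i"], cells["pair_j"]))
    wk = cells["week"].to_numpy()
    X1 = covs.design_matrix(cells["pair_i"].to_numpy(), cell_pairs, wk)
    X2 = covs.design_matrix(cells["pair_j"].to_numpy(), cell_pairs, wk)

    # empirical baseline per-subscriber rate per pair/age: mean baseline count
    # split evenly per subscriber across the two directions
    base = cells[cells["week"] <= baseline_weeks]
    base_counts = base["count"].fillna(panel.censor_threshold / 2.0)
    key = list(zip(base["pair_i"], base["pair_j"], base["age_group"]))
    base_mean = base_counts.groupby(pd.Index(key)).mean()

    n_dir = 1 if rate_structure == "pooled" else 2
    n_r = len(pairs) * n_dir * n_ages
    r_tuples: list[tuple[str, str, str] | None] = [None] * n_r
    log_r_init = np.empty(n_r)
    log_p_sub = np.empty(n_r)
    log_pop_dest = np.empty(n_r)
    log_dist = np.empty(n_r)
    pop = ziptable.df["pop_total"].to_numpy(float)
    lat = ziptable.df["lat"].to_numpy(float)
    lon = ziptable.df["lon"].to_numpy(float)

    for (pi, pj), kpair in pair_pos.items():
        d = float(haversine_km(lat[zpos[pi]], lon[zpos[pi]], lat[zpos[pj]], lon[zpos[pj]]))
        if d <= 0:
            raise ValidationError(f"zero centroid distance for route {pi}-{pj}")
        for a, ka in age_pos.items():
            m = float(base_mean.get((pi, pj, a), panel.censor_threshold / 2.0))
            m = max(m, 0.5)
            denom = subs[zpos[pi], ka] + subs[zpos[pj], ka]
            r0 = np.log(m / denom)
            for direction, (zo, zd) in enumerate(((pi, pj), (pj, pi))[:n_dir]):
                k = (kpair * n_dir + direction) * n_ages + ka
                r_tuples[k] = (zo, zd, a)
                log_r_init[k] = r0
                log_p_sub[k] = np.log(subs[zpos[zo], ka])
                log_pop_dest[k] = np.log(pop[zpos[zd]])
                log_dist[k] = np.log(d)

    bound = np.full(len(cells), float(panel.censor_threshold - 1))

    return DeclineData(
        pairs=pairs,
        ages=ages,
        weeks=weeks,
        decline_weeks=decline_weeks,
        y=cells["count"].to_numpy(float),
        censored=cells["censored"].to_numpy(bool),
        bound=bound,
        idx1=idx1,
        idx2=idx2,
        logp1=np.log(p1),
        logp2=np.log(p2),
        X1=X1,
        X2=X2,
        age_idx=age_idx,
        cum_idx=cum_idx,
        r_index=pd.MultiIndex.from_tuples(r_tuples, names=["origin", "dest", "age_group"]),
        log_r_init=log_r_init,
        log_p_sub=log_p_sub,
        log_pop_dest=log_pop_dest,
        log_dist=log_dist,
        rate_structure=rate_structure,
    )


# ---------------------------------------------------------------------------
# Model kernel
# ---------------------------------------------------------------------------


def compute_q(
    c: np.ndarray,
    beta: np.ndarray,
    beta_a: float,
    x: np.ndarray,
    t: int,
    baseline_weeks: int = 4,
    first_decline_week: int | None = None,
) -> float:
    """Decline fraction q for one route/age/week.

    ``c`` holds the weekly decrement for each decline week (week
    ``baseline_weeks + 1`` onwards); q is exactly 1 during baseline weeks.
    """
    if t <= baseline_weeks:
        return 1.0
    first = baseline_weeks + 1 if first_decline_week is None else first_decline_week
    csum = float(np.sum(np.asarray(c, float)[: t - first + 1]))
    eta = float(np.dot(np.asarray(beta, float), np.asarray(x, float)) + beta_a)
    return float(np.exp(-np.exp(np.clip(eta, -40.0, 40.0)) * csum))


def _core_nll_grad(
    log_r: np.ndarray,
    log_c: np.ndarray,
    beta: np.ndarray,
    beta_a_free: np.ndarray,
    D: DeclineData,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Negative log likelihood and its gradient blocks.

    Returns (nll, g_log_r, g_log_c, g_beta, g_beta_a_free); the log-r
    gradient is per directed-route-age entry so alternative baseline
    parameterizations (gravity) can chain through it.
    """
    n_ages = len(D.ages)
    beta_a = np.concatenate([[0.0], beta_a_free])
    c = np.exp(log_c)
    cumc = np.concatenate([[0.0], np.cumsum(c)])  # prepend for baseline index -1 -> 0
    C = cumc[D.cum_idx + 1]

    eta1 = np.clip(D.X1 @ beta + beta_a[D.age_idx], -40.0, 40.0)
    eta2 = np.clip(D.X2 @ beta + beta_a[D.age_idx], -40.0, 40.0)
    E1, E2 = np.exp(eta1), np.exp(eta2)
    logq1, logq2 = -E1 * C, -E2 * C
    mu1 = np.exp(D.logp1 + log_r[D.idx1] + logq1)
    mu2 = np.exp(D.logp2 + log_r[D.idx2] + logq2)
    mu = mu1 + mu2

    ll = censored_poisson_loglik(D.y, mu, censored=D.censored, bound=D.bound, threshold=0)
    nll = -float(ll.sum())
    w = censored_poisson_dloglik_dmu(D.y, mu, D.censored, D.bound)

    a1, a2 = w * mu1, w * mu2
    g_log_r = np.zeros(D.n_r)
    np.add.at(g_log_r, D.idx1, -a1)
    np.add.at(g_log_r, D.idx2, -a2)

    t1, t2 = a1 * logq1, a2 * logq2
    g_beta = -(D.X1.T @ t1 + D.X2.T @ t2)
    g_ba_full = -np.bincount(D.age_idx, weights=t1 + t2, minlength=n_ages)
    g_beta_a = g_ba_full[1:]

    if D.n_c:
        s = a1 * E1 + a2 * E2
        dec = D.cum_idx >= 0
        S = np.bincount(D.cum_idx[dec], weights=s[dec], minlength=D.n_c)
        tail = np.cumsum(S[::-1])[::-1]
        g_log_c = c * tail
    else:
        g_log_c = np.zeros(0)
    return nll, g_log_r, g_log_c, g_beta, g_beta_a


def negative_log_posterior(
    x: np.ndarray, D: DeclineData, priors: PriorConfig
) -> tuple[float, np.ndarray]:
    """Negative log posterior of the free-baseline decline model and gradient.

    Parameter vector layout: [log_r (directed routes x ages), log_c, beta,
    beta_a (non-reference ages)].  With flat priors the value is the pure
    negative log likelihood.
    """
    n_r, n_c, n_b = D.n_r, D.n_c, D.X1.shape[1]
    log_r = x[:n_r]
    log_c = x[n_r : n_r + n_c]
    beta = x[n_r + n_c : n_r + n_c + n_b]
    beta_a = x[n_r + n_c + n_b :]
    nll, g_r, g_c, g_b, g_a = _core_nll_grad(log_r, log_c, beta, beta_a, D)
    if not priors.flat:
        v, g = _normal_nlp(log_r, D.log_r_init, priors.log_r_sd)
        nll += v
        g_r = g_r + g
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
    return nll, np.concatenate([g_r, g_c, g_b, g_a])


# ---------------------------------------------------------------------------
# Fit result container
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """MAP estimates with Laplace-approximate uncertainty and fit metadata."""

    model: str
    estimates: dict
    sds: dict
    loglik: float
    logpost: float
    n_params: int
    n_obs: int
    bic: float
    converged: bool
    grad_norm: float
    n_iter: int
    x: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Point estimates, SDs and 95% intervals for the inferential blocks."""
        rows = []
        for block in ("log_c", "beta", "beta_a", "gravity", "beta0"):
            if block not in self.estimates:
                continue
            est = self.estimates[block]
            sd = self.sds.get(block)
            if isinstance(est, pd.Series):
                names = [f"{block}:{k}" for k in est.index]
                vals = est.to_numpy(float)
            elif np.isscalar(est):
                names, vals = [block], np.array([est], float)
            else:
                vals = np.asarray(est, float)
                names = [f"{block}[{k}]" for k in range(len(vals))]
            sdv = np.full(len(vals), np.nan) if sd is None else np.asarray(sd, float)
            for n, v, s in zip(names, vals, sdv):
                rows.append(
                    {
                        "param": n,
                        "estimate": v,
                        "sd": s,
                        "ci_low": v - 1.959963984540054 * s,
                        "ci_high": v + 1.959963984540054 * s,
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        def enc(v):
            if isinstance(v, pd.Series):
                return {"index": [list(i) if isinstance(i, tuple) else i for i in v.index], "values": v.to_list()}
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        payload = {
            "model": self.model,
            "estimates": {k: enc(v) for k, v in self.estimates.items()},
            "sds": {k: enc(v) for k, v in self.sds.items()},
            "loglik": self.loglik,
            "logpost": self.logpost,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "convergence": {
                "converged": bool(self.converged),
                "grad_norm": self.grad_norm,
                "n_iter": int(self.n_iter),
            },
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        d = json.loads(Path(path).read_text())

        def dec(k, v):
            if isinstance(v, dict) and set(v) == {"index", "values"}:
                idx = [tuple(i) if isinstance(i, list) else i for i in v["index"]]
                if idx and isinstance(idx[0], tuple):
                    return pd.Series(v["values"], index=pd.MultiIndex.from_tuples(idx))
                return pd.Series(v["values"], index=idx)
            if isinstance(v, list):
                return np.asarray(v, float)
            return v

        return cls(
            model=d["model"],
            estimates={k: dec(k, v) for k, v in d["estimates"].items()},
            sds={k: dec(k, v) for k, v in d["sds"].items()},
            loglik=d["loglik"],
            logpost=d["logpost"],
            n_params=d["n_params"],
            n_obs=d["n_obs"],
            bic=d["bic"],
            converged=d["convergence"]["converged"],
            grad_norm=d["convergence"]["grad_norm"],
            n_iter=d["convergence"]["n_iter"],
            meta=d.get("meta", {}),
        )


def finite_difference_hessian(grad_fn, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Symmetrized central-difference Hessian from an analytic gradient."""
    n = len(x)
    H = np.empty((n, n))
    for k in range(n):
        h = rel_step * max(1.0, abs(x[k]))
        xp = x.copy()
        xp[k] += h
        xm = x.copy()
        xm[k] -= h
        H[:, k] = (grad_fn(xp) - grad_fn(xm)) / (2 * h)
    return 0.5 * (H + H.T)


def laplace_sds(grad_fn, x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Laplace-approximate SDs: sqrt of diag of the inverse Hessian at the mode.

    Returns (sds, ok).  A Hessian that is not positive definite is jittered
    once; if the inverse still has non-positive diagonal entries the
    affected SDs are NaN and ok is False.
    """
    H = finite_difference_hessian(grad_fn, x)
    for jitter in (0.0, 1e-8 * max(1.0, float(np.abs(np.diag(H)).max()))):
        try:
            cov = np.linalg.inv(H + jitter * np.eye(len(x)))
        except np.linalg.LinAlgError:
            continue
        d = np.diag(cov)
        if (d > 0).all():
            return np.sqrt(d), True
    with np.errstate(invalid="ignore"):
        d = np.diag(np.linalg.pinv(H))
        sds = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    warnings.warn("Hessian not positive definite at the mode; some SDs are NaN")
    return sds, False


def _pack_decline_result(
    model: str,
    x: np.ndarray,
    sd_vec: np.ndarray | None,
    D: DeclineData,
    nll_lik: float,
    logpost: float,
    n_params: int,
    res,
    grad_norm: float,
    tol: float,
    meta: dict,
) -> FitResult:
    n_r, n_c, n_b = D.n_r, D.n_c, D.X1.shape[1]
    names = meta["covariate_names"]

    def r_series(vals: np.ndarray) -> pd.Series:
        s = pd.Series(vals, index=D.r_index)
        if D.rate_structure == "pooled":
            # expose the pooled rate under both directed keys for plug-in use
            rev = pd.MultiIndex.from_tuples(
                [(d, o, a) for o, d, a in D.r_index], names=D.r_index.names
            )
            s = pd.concat([s, pd.Series(vals, index=rev)])
        return s

    est = {
        "log_r": r_series(x[:n_r]),
        "log_c": pd.Series(x[n_r : n_r + n_c], index=D.decline_weeks),
        "c": pd.Series(np.exp(x[n_r : n_r + n_c]), index=D.decline_weeks),
        "beta": pd.Series(x[n_r + n_c : n_r + n_c + n_b], index=names),
        "beta_a": pd.Series(x[n_r + n_c + n_b :], index=D.ages[1:]),
    }
    sds = {}
    if sd_vec is not None:
        sds = {
            "log_r": r_series(sd_vec[:n_r]),
            "log_c": pd.Series(sd_vec[n_r : n_r + n_c], index=D.decline_weeks),
            "beta": pd.Series(sd_vec[n_r + n_c : n_r + n_c + n_b], index=names),
            "beta_a": pd.Series(sd_vec[n_r + n_c + n_b :], index=D.ages[1:]),
        }
    loglik = -nll_lik
    return FitResult(
        model=model,
        estimates=est,
        sds=sds,
        loglik=loglik,
        logpost=logpost,
        n_params=n_params,
        n_obs=D.n_cells,
        bic=n_params * float(np.log(D.n_cells)) - 2.0 * loglik,
        converged=grad_norm < tol,
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        x=x,
        meta=meta,
    )


def fit_decline(
    panel: TripPanel,
    covs: CovariateSet,
    ziptable: ZipTable,
    priors: PriorConfig | None = None,
    baseline_weeks: int = 4,
    max_week: int | None = 9,
    optimizer: OptimizerConfig | None = None,
    init: np.ndarray | None = None,
    compute_sds: bool = True,
    rate_structure: str = "pooled",
    data: DeclineData | None = None,
) -> FitResult:
    """MAP fit of the free-baseline decline model with Laplace uncertainty.

    Deterministic initialization: log r at the empirical baseline rates,
    c at 0.05, beta and beta_a at 0 (override via ``init`` for warm
    starts).  The reported log-likelihood excludes the prior; BIC counts
    every fitted parameter, baseline rates included.
    """
    priors = priors or PriorConfig()
    opt = optimizer or OptimizerConfig()
    D = data if data is not None else build_decline_data(
        panel, covs, ziptable, baseline_weeks, max_week, rate_structure
    )
    if len(D.decline_weeks) < 2:
        raise ValidationError("need at least 2 post-baseline weeks to fit the decline")
    n_b = D.X1.shape[1]
    if init is None:
        x0 = np.concatenate(
            [
                D.log_r_init,
                np.full(D.n_c, np.log(0.05)),
                np.zeros(n_b),
                np.zeros(len(D.ages) - 1),
            ]
        )
    else:
        x0 = np.asarray(init, float).copy()

    def obj(x):
        return negative_log_posterior(x, D, priors)

    res = optimize.minimize(
        obj,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": opt.maxiter, "maxfun": opt.maxfun, "gtol": opt.pgtol, "ftol": opt.factr * np.finfo(float).eps},
    )
    x = res.x
    logpost_val, grad = obj(x)
    grad_norm = float(np.abs(grad).max())
    n_r, n_c = D.n_r, D.n_c
    nll_lik, *_ = _core_nll_grad(
        x[:n_r], x[n_r : n_r + n_c], x[n_r + n_c : n_r + n_c + n_b], x[n_r + n_c + n_b :], D
    )
    sd_vec = None
    if compute_sds:
        sd_vec, _ok = laplace_sds(lambda z: obj(z)[1], x)
    meta = {
        "covariate_names": covs.names,
        "baseline_weeks": baseline_weeks,
        "rate_structure": D.rate_structure,
    }
    return _pack_decline_result(
        "decline_free",
        x,
        sd_vec,
        D,
        nll_lik,
        -logpost_val,
        n_params=len(x),
        res=res,
        grad_norm=grad_norm,
        tol=opt.grad_tol,
        meta=meta,
    )
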