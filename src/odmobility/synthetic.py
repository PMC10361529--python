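"""Seeded synthetic cities and trip panels with the models' generative structure.

The real operator data is proprietary, so every downstream stage is
exercised on synthetic origin-destination panels that emulate its
statistical shape: a small city of zip codes (~6,000 residents each) whose
subscriber base skews older, per-subscriber baseline route rates following
a gravity law with lognormal route-level heterogeneity, a four-week
baseline period at full mobility, covariate-driven weekly declines
afterwards, anonymity censoring of counts below 50, optional data-loss
weeks, and a stable summer block.

All randomness flows through one :class:`numpy.random.Generator` (PCG64)
seeded from ``SimConfig.seed``, so identical configurations reproduce
byte-identical panels on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .gravity import gravity_rate
from .io_prep import (
    AGE_GROUPS,
    CovariateSet,
    SUBSCRIBER_COLUMNS,
    TripPanel,
    ValidationError,
    ZipTable,
    canonical_pair,
    haversine_km,
    relative_case_rates,
    weighted_quartile_bounds,
)

_DECLINE_BETA = {
    "dist_q1": 0.0,
    "dist_q3": 0.0,
    "dist_q4": 0.5,
    "prop_higher_income": 0.4,
    "relative_case_rate": 0.1,
    "median_income_std": 0.0,
}
_SUMMER_BETA = {
    "dist_q1": 0.3,
    "dist_q3": 0.0,
    "dist_q4": 0.3,
    "prop_higher_income": 0.4,
    "median_income_std": 0.0,
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic city.

    Defaults encode the reference simulation: 20 zips, 9 weekly frames of
    which the first 4 are baseline, three age groups, gravity baseline
    rates with lognormal route noise, covariate effects dominated by
    long-distance routes and higher-income zips, censoring at 50, and a
    13-week summer block at modestly reduced mobility.
    """

    n_zips: int = 20
    n_weeks: int = 9
    baseline_weeks: int = 4
    seed: int = 0
    # gravity baseline: r = theta * p_ia^alpha * pop_j^delta * d^gamma
    theta: float = 5e-3
    alpha: float = 0.5
    delta: float = 0.5
    gamma: float = -1.2
    baseline_noise_sd: float = 0.5
    # decline truth
    c: tuple[float, ...] = (0.12, 0.12, 0.10, 0.08, 0.06)
    beta: dict[str, float] = field(default_factory=lambda: dict(_DECLINE_BETA))
    beta_a: tuple[float, float, float] = (0.0, -0.05, -0.1)
    # summer truth
    summer_beta0: float = 0.2
    summer_beta: dict[str, float] = field(default_factory=lambda: dict(_SUMMER_BETA))
    summer_beta_a: tuple[float, float, float] = (0.0, -0.05, -0.1)
    summer_n_weeks: int = 13
    # observation process
    censor_threshold: int = 50
    data_loss_weeks: frozenset[int] = field(default_factory=frozenset)
    subscriber_scale: float = 0.3
    age_shares: tuple[float, float, float] = (0.25, 0.35, 0.40)
    # city geography / demography
    box_km: float = 40.0
    pop_median: float = 6000.0
    pop_sigma: float = 0.5
    income_median: float = 60000.0
    income_sigma: float = 0.3
    prop_income_beta: tuple[float, float] = (6.0, 4.0)
    n_counties: int | None = None
    # county epidemic curves (per 100k per week)
    case_base: float = 20.0
    case_growth: float = 0.25
    case_noise_sd: float = 0.3
    city_id: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_zips < 4:
            raise ValidationError("need at least 4 zips")
        if self.theta <= 0:
            raise ValidationError("theta must be positive")
        if any(ck < 0 for ck in self.c):
            raise ValidationError("weekly decrements c must be non-negative")
        if len(self.c) != self.n_weeks - self.baseline_weeks:
            raise ValidationError(
                "length of c must equal the number of post-baseline weeks"
            )

    @property
    def counties(self) -> int:
        return self.n_counties if self.n_counties is not None else max(3, self.n_zips // 6)


def generate_city(config: SimConfig) -> ZipTable:
    """Draw a synthetic city's zip-attribute table.

    Zips are placed uniformly in a ``box_km`` square; census populations
    are lognormal with median ``pop_median``; subscriber counts are a
    fixed fraction of population with an age skew toward older groups;
    the proportion of higher-income subscribers is Beta-distributed,
    independent of the zip's median household income.  Counties are
    longitudinal bands of the box.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_zips
    x = rng.uniform(0, config.box_km, n)
    y = rng.uniform(0, config.box_km, n)
    lat0, lon0 = 40.0, -95.0
    lat = lat0 + y / 110.574
    lon = lon0 + x / (111.320 * np.cos(np.radians(lat0)))
    pop = np.round(np.exp(rng.normal(np.log(config.pop_median), config.pop_sigma, n)))
    income = np.exp(rng.normal(np.log(config.income_median), config.income_sigma, n))
    prop = rng.beta(*config.prop_income_beta, n)
    edges = np.quantile(x, np.linspace(0, 1, config.counties + 1)[1:-1])
    county = np.digitize(x, edges)
    shares = np.asarray(config.age_shares)
    subs = np.maximum(1, np.round(config.subscriber_scale * pop[:, None] * shares[None, :]))
    df = pd.DataFrame(
        {
            "lat": lat,
            "lon": lon,
            "pop_total": pop,
            "median_income": income,
            "county_id": [f"{config.city_id}-C{k + 1}" for k in county],
            "subs_18_34": subs[:, 0],
            "subs_35_54": subs[:, 1],
            "subs_55p": subs[:, 2],
            "prop_higher_income": prop,
        },
        index=pd.Index([f"Z{k + 1:03d}" for k in range(n)], name="zip_id"),
    )
    return ZipTable(df)


def generate_case_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Weekly county case rates: an exponential epidemic curve with noise."""
    counties = [f"{config.city_id}-C{k + 1}" for k in range(config.counties)]
    rows = []
    for w in range(1, config.n_weeks + 1):
        base = config.case_base * np.exp(config.case_growth * (w - 1))
        noise = np.exp(rng.normal(0.0, config.case_noise_sd, len(counties)))
        for cid, z in zip(counties, noise):
            rows.append({"county_id": cid, "week": w, "cases_per_100k": base * z})
    return pd.DataFrame(rows)


def _directed_arrays(ziptable: ZipTable, config: SimConfig, rng: np.random.Generator):
    """Directed baseline log-rates and the indexing scaffold shared by panels."""
    zips = ziptable.zip_ids
    pairs = [(zips[i], zips[j]) for i in range(len(zips)) for j in range(i + 1, len(zips))]
    pairs = sorted(canonical_pair(*p) for p in pairs)
    lat = ziptable.df["lat"]
    lon = ziptable.df["lon"]
    dist = np.array(
        [haversine_km(lat[i], lon[i], lat[j], lon[j]) for i, j in pairs]
    )
    subs = ziptable.df[[SUBSCRIBER_COLUMNS[a] for a in AGE_GROUPS]].to_numpy(float)
    pop = ziptable.df["pop_total"].to_numpy(float)
    zpos = {z: k for k, z in enumerate(zips)}
    i_pos = np.array([zpos[p[0]] for p in pairs])
    j_pos = np.array([zpos[p[1]] for p in pairs])

    # directed rates: (n_pairs, 2 directions, n_ages)
    n_pairs, n_ages = len(pairs), len(AGE_GROUPS)
    r = np.empty((n_pairs, 2, n_ages))
    for ka in range(n_ages):
        r[:, 0, ka] = gravity_rate(
            config.theta, config.alpha, config.delta, config.gamma,
            subs[i_pos, ka], pop[j_pos], dist,
        )
        r[:, 1, ka] = gravity_rate(
            config.theta, config.alpha, config.delta, config.gamma,
            subs[j_pos, ka], pop[i_pos], dist,
        )
    r *= np.exp(rng.normal(0.0, config.baseline_noise_sd, r.shape))
    return pairs, dist, subs, i_pos, j_pos, r


def _truth_covariates(
    ziptable: ZipTable,
    config: SimConfig,
    pairs: list[tuple[str, str]],
    dist: np.ndarray,
    subs: np.ndarray,
    i_pos: np.ndarray,
    j_pos: np.ndarray,
    r: np.ndarray,
    cases: pd.DataFrame | None,
) -> CovariateSet:
    """The covariate set under which the synthetic panel is generated.

    Distance quartiles are weighted by expected baseline trips (the
    quantity the observed February weighting estimates).
    """
    weight = (subs[i_pos][:, :] * r[:, 0, :] + subs[j_pos][:, :] * r[:, 1, :]).sum(axis=1)
    bounds = weighted_quartile_bounds(dist, weight)
    q = 1 + np.searchsorted(np.asarray(bounds), dist, side="left")
    mi = ziptable.df["median_income"].to_numpy(float)
    std = (mi - mi.mean()) / mi.std()
    zip_static = pd.DataFrame(
        {
            "prop_higher_income": ziptable.df["prop_higher_income"].to_numpy(float),
            "median_income_std": std,
        },
        index=ziptable.df.index,
    )
    rel = relative_case_rates(ziptable, cases) if cases is not None else None
    return CovariateSet(
        quartile_of_pair={p: int(k) for p, k in zip(pairs, q)},
        quartile_bounds=bounds,
        zip_static=zip_static,
        rel_case=rel,
        reference_quartile=2,
    )


def _log_r_series(pairs, r) -> pd.Series:
    tuples, vals = [], []
    for kp, (zi, zj) in enumerate(pairs):
        for d, (o, dd) in enumerate(((zi, zj), (zj, zi))):
            for ka, a in enumerate(AGE_GROUPS):
                tuples.append((o, dd, a))
                vals.append(np.log(r[kp, d, ka]))
    return pd.Series(
        vals, index=pd.MultiIndex.from_tuples(tuples, names=["origin", "dest", "age_group"])
    )


def simulate_decline_panel(
    ziptable: ZipTable,
    config: SimConfig,
    mode: Literal["poisson", "mean"] = "poisson",
) -> tuple[TripPanel, dict]:
    """Simulate a weekly decline-window panel and return the ground truth.

    Counts are drawn per (unordered pair, age, week) from
    ``Poisson(p_ia r_ija q_ijat + p_ja r_jia q_jiat)`` (or set to the mean
    exactly in ``mean`` mode); q is 1 during the baseline weeks and decays
    by the covariate-modulated cumulative decrements afterwards.  Cells
    below ``censor_threshold`` are flagged censored; declared data-loss
    weeks are dropped after simulation.

    The truth dict carries the directed baseline log-rates, the decline
    parameters, the covariate set and the county case table, so recovery
    tests can compare estimates against the generative values.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    pairs, dist, subs, i_pos, j_pos, r = _directed_arrays(ziptable, config, rng)
    cases = generate_case_table(config, rng)
    covs = _truth_covariates(ziptable, config, pairs, dist, subs, i_pos, j_pos, r, cases)
    names = covs.names
    beta = np.array([config.beta.get(n, 0.0) for n in names])
    beta_a = np.asarray(config.beta_a)
    c = np.asarray(config.c, float)
    cumc = np.concatenate([[0.0], np.cumsum(c)])

    n_pairs, n_ages = len(pairs), len(AGE_GROUPS)
    weeks = np.arange(1, config.n_weeks + 1)
    # cell grid: pair-major, then age, then week
    pair_rep = np.repeat(np.arange(n_pairs), n_ages * len(weeks))
    age_rep = np.tile(np.repeat(np.arange(n_ages), len(weeks)), n_pairs)
    week_rep = np.tile(weeks, n_pairs * n_ages)

    origins_i = np.array([pairs[k][0] for k in pair_rep])
    origins_j = np.array([pairs[k][1] for k in pair_rep])
    cell_pairs = [pairs[k] for k in pair_rep]
    X1 = covs.design_matrix(origins_i, cell_pairs, week_rep)
    X2 = covs.design_matrix(origins_j, cell_pairs, week_rep)
    eta1 = X1 @ beta + beta_a[age_rep]
    eta2 = X2 @ beta + beta_a[age_rep]
    C = cumc[np.maximum(week_rep - config.baseline_weeks, 0)]
    q1 = np.exp(-np.exp(eta1) * C)
    q2 = np.exp(-np.exp(eta2) * C)
    p1 = subs[i_pos[pair_rep], age_rep]
    p2 = subs[j_pos[pair_rep], age_rep]
    r1 = r[pair_rep, 0, age_rep]
    r2 = r[pair_rep, 1, age_rep]
    mu = p1 * r1 * q1 + p2 * r2 * q2
    if not np.isfinite(mu).all() or mu.max() > 1e12:
        raise ValidationError(
            "expected trip counts overflow; reduce subscriber_scale or theta"
        )
    counts = rng.poisson(mu).astype(float) if mode == "poisson" else mu.copy()
    censored = (
        counts < config.censor_threshold
        if config.censor_threshold > 0
        else np.zeros(len(counts), bool)
    )
    df = pd.DataFrame(
        {
            "origin": origins_i,
            "dest": origins_j,
            "age_group": [AGE_GROUPS[k] for k in age_rep],
            "week": week_rep,
            "count": np.where(censored, np.nan, counts),
            "censored": censored,
        }
    )
    df = df[~df["week"].isin(config.data_loss_weeks)].reset_index(drop=True)
    panel = TripPanel(
        df=df,
        resolution="weekly",
        censor_threshold=config.censor_threshold,
        data_loss_weeks=frozenset(config.data_loss_weeks),
    )
    truth = {
        "log_r": _log_r_series(pairs, r),
        "c": c,
        "beta": pd.Series(beta, index=names),
        "beta_a": pd.Series(beta_a[1:], index=list(AGE_GROUPS[1:])),
        "covariates": covs,
        "cases": cases,
        "config": config,
        "expected": mu,
    }
    return panel, truth


def simulate_summer_panel(
    ziptable: ZipTable,
    baseline_log_r: pd.Series,
    config: SimConfig,
    covariates: CovariateSet | None = None,
    mode: Literal["poisson", "mean"] = "poisson",
) -> tuple[TripPanel, dict]:
    """Simulate the summer block: one aggregated count per route and age.

    The mean over the ``summer_n_weeks`` window is
    ``n_weeks * (p_ia r_ija e^{-eta_ij} + p_ja r_jia e^{-eta_ji})`` with
    ``eta = beta0 + beta' X + beta_a``.  ``baseline_log_r`` supplies the
    directed baseline rates (generative truth or a decline-fit estimate).
    The summer covariate set has no case-rate term.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    pairs, dist, subs, i_pos, j_pos, r_unused = _directed_arrays(ziptable, config, rng)
    if covariates is None:
        covs = _truth_covariates(ziptable, config, pairs, dist, subs, i_pos, j_pos, r_unused, None)
    else:
        covs = replace(covariates, rel_case=None)
    names = covs.names
    beta = np.array([config.summer_beta.get(n, 0.0) for n in names])
    beta_a = np.asarray(config.summer_beta_a)

    n_pairs, n_ages = len(pairs), len(AGE_GROUPS)
    pair_rep = np.repeat(np.arange(n_pairs), n_ages)
    age_rep = np.tile(np.arange(n_ages), n_pairs)
    origins_i = np.array([pairs[k][0] for k in pair_rep])
    origins_j = np.array([pairs[k][1] for k in pair_rep])
    cell_pairs = [pairs[k] for k in pair_rep]
    X1 = covs.design_matrix(origins_i, cell_pairs, None)
    X2 = covs.design_matrix(origins_j, cell_pairs, None)
    eta1 = config.summer_beta0 + X1 @ beta + beta_a[age_rep]
    eta2 = config.summer_beta0 + X2 @ beta + beta_a[age_rep]
    ages = [AGE_GROUPS[k] for k in age_rep]
    r1 = np.exp(
        baseline_log_r.loc[list(zip(origins_i, origins_j, ages))].to_numpy(float)
    )
    r2 = np.exp(
        baseline_log_r.loc[list(zip(origins_j, origins_i, ages))].to_numpy(float)
    )
    p1 = subs[i_pos[pair_rep], age_rep]
    p2 = subs[j_pos[pair_rep], age_rep]
    mu = config.summer_n_weeks * (p1 * r1 * np.exp(-eta1) + p2 * r2 * np.exp(-eta2))
    if not np.isfinite(mu).all() or mu.max() > 1e12:
        raise ValidationError(
            "expected trip counts overflow; reduce subscriber_scale or theta"
        )
    counts = rng.poisson(mu).astype(float) if mode == "poisson" else mu.copy()
    censored = (
        counts < config.censor_threshold
        if config.censor_threshold > 0
        else np.zeros(len(counts), bool)
    )
    df = pd.DataFrame(
        {
            "origin": origins_i,
            "dest": origins_j,
            "age_group": ages,
            "count": np.where(censored, np.nan, counts),
            "censored": censored,
        }
    )
    panel = TripPanel(
        df=df,
        resolution="aggregate",
        censor_threshold=config.censor_threshold,
        n_weeks=config.summer_n_weeks,
    )
    truth = {
        "beta0": config.summer_beta0,
        "beta": pd.Series(beta, index=names),
        "beta_a": pd.Series(beta_a[1:], index=list(AGE_GROUPS[1:])),
        "covariates": covs,
        "log_r": baseline_log_r,
        "config": config,
        "expected": mu,
    }
    return panel, truth
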