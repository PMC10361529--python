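"""Baseline-relative descriptive mobility metrics.

All series here express weekly travel as a ratio to the pre-pandemic
baseline: the weekly total number of trips in a stratum divided by the
mean weekly total over the baseline month (the first four data weeks).
Strata can be the whole city, an age group, a route distance quartile, or
the zip codes above/below the city median proportion of higher-income
subscribers.  Censored cells enter the totals at the midpoint of their
feasible range (threshold / 2) by default; a drop policy is available as
a sensitivity toggle.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_prep import (
    CovariateSet,
    TripPanel,
    ValidationError,
    ZipTable,
    canonical_pair,
)


def _weekly_totals(df: pd.DataFrame, censor_threshold: int, censored_policy: str) -> pd.Series:
    if censored_policy == "midpoint":
        counts = df["count"].fillna(censor_threshold / 2.0)
    elif censored_policy == "drop":
        df = df[~df["censored"]]
        counts = df["count"]
    else:
        raise ValidationError(f"unknown censored_policy {censored_policy!r}")
    return counts.groupby(df["week"]).sum()


def relative_mobility(
    panel: TripPanel,
    baseline_weeks: set[int] | None = None,
    subset: pd.Series | None = None,
    censored_policy: str = "midpoint",
) -> pd.Series:
    """Weekly trips relative to the mean weekly baseline total.

    ``subset`` is an optional boolean mask over panel rows selecting a
    stratum.  Weeks lost to data collection are simply absent.  Raises on
    a zero baseline total.
    """
    if panel.resolution != "weekly":
        raise ValidationError("relative_mobility expects a weekly panel")
    if baseline_weeks is None:
        baseline_weeks = {1, 2, 3, 4}
    df = panel.df if subset is None else panel.df[subset]
    totals = _weekly_totals(df, panel.censor_threshold, censored_policy)
    base = totals[totals.index.isin(baseline_weeks)]
    if len(base) == 0 or base.mean() == 0:
        raise ValidationError("zero or missing baseline total")
    out = totals / base.mean()
    out.name = "relative_mobility"
    return out


def stratified_series(
    panel: TripPanel,
    by: str,
    baseline_weeks: set[int] | None = None,
    covariates: CovariateSet | None = None,
    censored_policy: str = "midpoint",
) -> dict[str, pd.Series]:
    """Relative-mobility series per stratum, each against its own baseline.

    ``by`` is ``"age"`` or ``"distance"`` (the latter needs a covariate
    set for the route -> quartile map).  Strata with no baseline trips are
    skipped with a warning.
    """
    if by == "age":
        labels = sorted(panel.df["age_group"].unique())
        masks = {a: panel.df["age_group"] == a for a in labels}
    elif by == "distance":
        if covariates is None:
            raise ValidationError("distance strata require a covariate set")
        pairs = [canonical_pair(o, d) for o, d in zip(panel.df["origin"], panel.df["dest"])]
        q = pd.Series([covariates.quartile_of_pair[p] for p in pairs], index=panel.df.index)
        masks = {f"Q{k}": q == k for k in (1, 2, 3, 4)}
    else:
        raise ValidationError(f"unknown stratification {by!r}")
    out: dict[str, pd.Series] = {}
    for label, mask in masks.items():
        if not mask.any():
            warnings.warn(f"stratum {label} is empty; skipped")
            continue
        try:
            out[label] = relative_mobility(panel, baseline_weeks, mask, censored_policy)
        except ValidationError:
            warnings.warn(f"stratum {label} has no baseline trips; skipped")
    return out


def income_ratio_series(
    panel: TripPanel,
    ziptable: ZipTable,
    baseline_weeks: set[int] | None = None,
    groups: tuple[set[str], set[str]] | None = None,
    censored_policy: str = "midpoint",
) -> pd.Series:
    """Ratio of relative outward trips: higher-income zips over the rest.

    Zips are split at the city median of the proportion of higher-income
    subscribers (above vs at-or-below); outward trips are attributed to
    the recorded origin zip.  Each group's weekly outward total is made
    relative to its own baseline and the ratio above/below is returned: a
    value below one means travel fell more, relative to baseline, in zip
    codes with more higher-income subscribers.  ``groups`` overrides the
    median split with explicit (above, below) zip sets.
    """
    if groups is None:
        prop = ziptable.df["prop_higher_income"]
        med = float(prop.median())
        above = set(prop.index[prop > med])
        below = set(prop.index[prop <= med])
    else:
        above, below = (set(groups[0]), set(groups[1]))
    series = []
    for grp in (above, below):
        mask = panel.df["origin"].isin(grp)
        if not mask.any():
            raise ValidationError("income group with no outward trips")
        series.append(relative_mobility(panel, baseline_weeks, mask, censored_policy))
    ratio = series[0] / series[1]
    ratio.name = "income_ratio"
    return ratio


def city_covariate_correlation(
    mobility: pd.Series, covariate: pd.Series
) -> float:
    """Pearson correlation across cities of window-mean mobility vs a covariate.

    Both inputs are indexed by city.  Requires at least 3 cities; returns
    NaN with a warning when either vector has zero variance.
    """
    joined = pd.concat([mobility, covariate], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValidationError("need at least 3 cities for a correlation")
    x = joined.iloc[:, 0].to_numpy(float)
    y = joined.iloc[:, 1].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def descriptive_table(
    panel: TripPanel,
    ziptable: ZipTable,
    covariates: CovariateSet | None = None,
    baseline_weeks: set[int] | None = None,
    city_id: str = "city",
) -> pd.DataFrame:
    """Tidy long table of every descriptive series for one city."""
    rows = []

    def emit(series: pd.Series, stratum: str):
        for wk, val in series.items():
            rows.append(
                {"city": city_id, "stratum": stratum, "week": int(wk), "value": float(val)}
            )

    emit(relative_mobility(panel, baseline_weeks), "all")
    for label, s in stratified_series(panel, "age", baseline_weeks).items():
        emit(s, f"age:{label}")
    if covariates is not None:
        for label, s in stratified_series(
            panel, "distance", baseline_weeks, covariates
        ).items():
            emit(s, f"distance:{label}")
    emit(income_ratio_series(panel, ziptable, baseline_weeks), "income_ratio")
    return pd.DataFrame(rows)


def plot_relative_series(series: dict[str, pd.Series], path: str) -> None:
    """Line plot of relative-mobility series (one line per stratum)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for label, s in series.items():
        ax.plot(s.index, s.to_numpy(), marker="o", ms=3, label=label)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("week")
    ax.set_ylabel("trips relative to baseline")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
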