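"""Containers and preparation steps for zip-level origin-destination trip data.

The observable unit throughout the package is a *trip cell*: the number of
trips recorded between a pair of zip codes, for one subscriber age group, in
one time frame (day or week).  Counts below the operator's anonymity
threshold (50 by default) are withheld at source; such cells are carried as
*censored* records with an unknown count known only to lie below the
threshold.

Three light containers are defined here:

``ZipTable``
    Per-zip attributes: centroid coordinates, census population, median
    household income, subscriber counts by age group and the proportion of
    subscribers in the higher income band (> $50,000/yr).
``TripPanel``
    Long-format trip cells at daily, weekly or aggregate resolution, with
    censoring flags and declared data-loss weeks.
``CovariateSet``
    Route- and zip-level explanatory variables used by the regression
    models: trip-weighted route distance quartile, proportion of
    higher-income subscribers, weekly county case rate relative to the
    city mean, and standardized median household income.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

AGE_GROUPS: tuple[str, ...] = ("18-34", "35-54", "55+")
SUBSCRIBER_COLUMNS: dict[str, str] = {
    "18-34": "subs_18_34",
    "35-54": "subs_35_54",
    "55+": "subs_55p",
}
EARTH_RADIUS_KM = 6371.0
DEFAULT_CENSOR_THRESHOLD = 50


class FormatError(ValueError):
    """A file does not match the expected tabular layout."""


class ValidationError(ValueError):
    """A container violates one of its invariants."""


# ---------------------------------------------------------------------------
# ZipTable
# ---------------------------------------------------------------------------

_ZIP_COLUMNS = [
    "lat",
    "lon",
    "pop_total",
    "median_income",
    "county_id",
    "subs_18_34",
    "subs_35_54",
    "subs_55p",
    "prop_higher_income",
]


@dataclass
class ZipTable:
    """Per-zip attribute table, indexed by zip identifier.

    The frame must carry the columns ``lat``, ``lon``, ``pop_total``,
    ``median_income``, ``county_id``, one subscriber-count column per age
    group and ``prop_higher_income`` (fraction of subscribers earning more
    than $50,000/yr).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _ZIP_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"zip table missing columns: {missing}")
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate zip identifiers")
        if (self.df["lat"].abs() > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
        if (self.df["lon"].abs() > 180).any():
            raise ValidationError("longitude outside [-180, 180]")
        p = self.df["prop_higher_income"]
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("prop_higher_income outside [0, 1]")
        subs = self.df[list(SUBSCRIBER_COLUMNS.values())]
        if (subs.to_numpy() < 0).any():
            raise ValidationError("negative subscriber counts")
        self.df = self.df.copy()
        self.df.index = self.df.index.astype(str)

    @property
    def zip_ids(self) -> list[str]:
        return list(self.df.index)

    def subscribers(self, age_group: str) -> pd.Series:
        """Subscriber counts p_ia for one age group, indexed by zip."""
        return self.df[SUBSCRIBER_COLUMNS[age_group]]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ZipTable":
        df = pd.read_csv(path, dtype={"zip_id": str, "county_id": str})
        if "zip_id" not in df.columns:
            raise FormatError("zip table must have a zip_id column")
        return cls(df.set_index("zip_id"))

    def to_csv(self, path: str | Path) -> None:
        self.df.rename_axis("zip_id").reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TripPanel
# ---------------------------------------------------------------------------


@dataclass
class TripPanel:
    """Long-format origin-destination trip counts with censoring flags.

    ``df`` columns: ``origin``, ``dest``, ``age_group``, a time column
    (``date`` at daily resolution, ``week`` at weekly; absent for aggregate
    panels), ``count`` (float; NaN when censored) and ``censored`` (bool).
    An optional ``censor_bound`` column carries the largest value a censored
    aggregate cell can take when it differs from ``censor_threshold - 1``.
    """

    df: pd.DataFrame
    resolution: str  # "daily" | "weekly" | "aggregate"
    censor_threshold: int = DEFAULT_CENSOR_THRESHOLD
    data_loss_weeks: frozenset[int] = field(default_factory=frozenset)
    start_date: pd.Timestamp | None = None
    n_weeks: int | None = None  # only meaningful for aggregate panels

    def __post_init__(self) -> None:
        if self.resolution not in ("daily", "weekly", "aggregate"):
            raise ValidationError(f"unknown resolution {self.resolution!r}")
        required = {"origin", "dest", "age_group", "count", "censored"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"trip panel missing columns: {sorted(missing)}")
        if self.resolution == "daily" and "date" not in self.df.columns:
            raise FormatError("daily panel requires a date column")
        if self.resolution == "weekly" and "week" not in self.df.columns:
            raise FormatError("weekly panel requires a week column")

    @property
    def weeks(self) -> list[int]:
        if self.resolution != "weekly":
            raise ValidationError("weeks defined only for weekly panels")
        return sorted(self.df["week"].unique())

    def total_trips(self, censored_value: float | None = None) -> float:
        """Total count, valuing censored cells at ``censored_value`` (0 if None)."""
        counts = self.df["count"].fillna(0.0).to_numpy(float)
        if censored_value is not None:
            counts = np.where(self.df["censored"].to_numpy(bool), censored_value, counts)
        return float(counts.sum())


def validate_trip_panel(panel: TripPanel, strict: bool = False) -> list[str]:
    """Check panel invariants; return a list of warnings (empty when clean).

    Hard violations (negative counts, origin == destination, censor-flag
    inconsistencies) raise :class:`ValidationError`.  Observed counts below
    the censor threshold are a warning only: real operator data never shows
    them, but synthetic panels generated without censoring legitimately do.
    In ``strict`` mode they raise instead.
    """
    df = panel.df
    if (df["origin"] == df["dest"]).any():
        raise ValidationError("within-zip records (origin == dest) are not allowed")
    observed = ~df["censored"].to_numpy(bool)
    counts = df["count"].to_numpy(float)
    if np.isnan(counts[observed]).any():
        raise ValidationError("observed records must carry a count")
    if (counts[observed] < 0).any():
        raise ValidationError("negative trip counts")
    if not np.isnan(counts[~observed]).all():
        raise ValidationError("censored records must not carry a count")
    issues: list[str] = []
    thr = panel.censor_threshold
    if thr > 0:
        low = observed & (counts >= 1) & (counts < thr)
        if low.any():
            msg = f"{int(low.sum())} observed counts below censor threshold {thr}"
            if strict:
                raise ValidationError(msg)
            issues.append(msg)
    if panel.resolution == "weekly":
        weeks = sorted(df["week"].unique())
        if weeks:
            expected = set(range(min(weeks), max(weeks) + 1)) - set(panel.data_loss_weeks)
            gaps = expected - set(weeks)
            if gaps:
                issues.append(f"undeclared missing weeks: {sorted(gaps)}")
    return issues


def load_trip_panel(
    path: str | Path,
    censor_threshold: int = DEFAULT_CENSOR_THRESHOLD,
    data_loss_weeks: frozenset[int] | set[int] = frozenset(),
) -> TripPanel:
    """Read a long-format trips CSV (origin, dest, age_group, date|week, count[, censored]).

    Censored cells are marked either by a true value in the ``censored``
    column or by an empty/missing count.  Malformed rows raise
    :class:`FormatError` / :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype={"origin": str, "dest": str, "age_group": str})
    base = {"origin", "dest", "age_group", "count"}
    missing = base - set(df.columns)
    if missing:
        raise FormatError(f"trips file missing columns: {sorted(missing)}")
    if "date" in df.columns:
        resolution = "daily"
        df["date"] = pd.to_datetime(df["date"])
    elif "week" in df.columns:
        resolution = "weekly"
        df["week"] = df["week"].astype(int)
    else:
        resolution = "aggregate"  # one cell per route/age over a declared window
    df["count"] = pd.to_numeric(df["count"], errors="coerce")
    if "censored" in df.columns:
        df["censored"] = df["censored"].astype(bool)
    else:
        df["censored"] = df["count"].isna()
    df.loc[df["censored"], "count"] = np.nan
    start = df["date"].min() if resolution == "daily" else None
    panel = TripPanel(
        df=df,
        resolution=resolution,
        censor_threshold=censor_threshold,
        data_loss_weeks=frozenset(data_loss_weeks),
        start_date=start,
    )
    validate_trip_panel(panel)
    return panel


def write_trip_panel(panel: TripPanel, path: str | Path) -> None:
    cols = ["origin", "dest", "age_group"]
    if panel.resolution == "daily":
        cols.append("date")
    elif panel.resolution == "weekly":
        cols.append("week")
    cols += ["count", "censored"]
    if "censor_bound" in panel.df.columns:
        cols.append("censor_bound")
    panel.df[cols].to_csv(path, index=False)


def aggregate_weekly(panel: TripPanel) -> TripPanel:
    """Sum daily cells into weekly cells anchored at the first panel date.

    A weekly cell containing any censored daily contribution is itself
    censored: its partial sum is a lower bound of unknown tightness, so it
    is discarded rather than imputed.  Declared data-loss weeks are dropped.
    Already-weekly input is returned unchanged with a warning.
    """
    if panel.resolution == "weekly":
        warnings.warn("panel is already weekly; aggregate_weekly is a no-op")
        return panel
    if panel.resolution != "daily":
        raise ValidationError("aggregate_weekly expects a daily panel")
    df = panel.df.copy()
    start = panel.start_date if panel.start_date is not None else df["date"].min()
    df["week"] = ((df["date"] - start).dt.days // 7 + 1).astype(int)
    grouped = (
        df.groupby(["origin", "dest", "age_group", "week"], sort=True)
        .agg(count=("count", "sum"), censored=("censored", "any"))
        .reset_index()
    )
    grouped.loc[grouped["censored"], "count"] = np.nan
    grouped = grouped[~grouped["week"].isin(panel.data_loss_weeks)].reset_index(drop=True)
    return TripPanel(
        df=grouped,
        resolution="weekly",
        censor_threshold=panel.censor_threshold,
        data_loss_weeks=panel.data_loss_weeks,
        start_date=start,
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between points given in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if (np.abs(lat) > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def centroid_distance(ziptable: ZipTable, zip_a: str, zip_b: str) -> float:
    """Haversine distance between the centroids of two zips (km)."""
    a = ziptable.df.loc[zip_a]
    b = ziptable.df.loc[zip_b]
    return float(haversine_km(a["lat"], a["lon"], b["lat"], b["lon"]))


def canonical_pair(origin: str, dest: str) -> tuple[str, str]:
    """Order a route's endpoints canonically (lexicographic)."""
    return (origin, dest) if origin <= dest else (dest, origin)


def pair_distances(ziptable: ZipTable, pairs: list[tuple[str, str]]) -> pd.Series:
    """Centroid distances (km) for a list of canonical pairs."""
    i = [p[0] for p in pairs]
    j = [p[1] for p in pairs]
    d = haversine_km(
        ziptable.df.loc[i, "lat"].to_numpy(),
        ziptable.df.loc[i, "lon"].to_numpy(),
        ziptable.df.loc[j, "lat"].to_numpy(),
        ziptable.df.loc[j, "lon"].to_numpy(),
    )
    return pd.Series(np.atleast_1d(d), index=pd.MultiIndex.from_tuples(pairs))


# ---------------------------------------------------------------------------
# Distance quartiles
# ---------------------------------------------------------------------------


def weighted_quartile_bounds(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """25/50/75th percentiles of ``values`` weighted by ``weights``.

    The k-th bound is the smallest value at which the cumulative weight
    share reaches k/4, so that equal weights on n distinct values split
    them into four equal groups.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    n_distinct = len(np.unique(values))
    if n_distinct < 2:
        raise ValidationError("fewer than 2 distinct distances; quartile binning is degenerate")
    if n_distinct < 4:
        warnings.warn("fewer than 4 distinct distances; some quartiles will be empty")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    total = cw[-1]
    if total <= 0:
        raise ValidationError("non-positive total weight for quartile binning")
    idx = np.searchsorted(cw, [0.25 * total, 0.5 * total, 0.75 * total], side="left")
    b = v[np.minimum(idx, len(v) - 1)]
    return float(b[0]), float(b[1]), float(b[2])


def assign_distance_quartiles(
    panel: TripPanel,
    ziptable: ZipTable,
    period_weeks: set[int] | None = None,
) -> tuple[dict[tuple[str, str], int], tuple[float, float, float]]:
    """Assign each route (unordered zip pair) to a trip-weighted distance quartile.

    Quartile boundaries are percentiles of route centroid distance weighted
    by the total number of trips on each route over ``period_weeks`` (the
    whole panel when None).  Censored cells contribute weight
    ``censor_threshold / 2`` — the midpoint of the feasible [0, threshold)
    range.  Returns the route -> quartile map (1..4) and the boundaries.
    """
    df = panel.df
    if period_weeks is not None and "week" in df.columns:
        df = df[df["week"].isin(period_weeks)]
    pairs = [canonical_pair(o, d) for o, d in zip(df["origin"], df["dest"])]
    w = df["count"].fillna(panel.censor_threshold / 2.0).to_numpy(float)
    weight = pd.Series(w).groupby(pd.Series(pairs)).sum()
    all_pairs = sorted(
        {canonical_pair(o, d) for o, d in zip(panel.df["origin"], panel.df["dest"])}
    )
    dist = pair_distances(ziptable, all_pairs)
    weights = np.array([weight.get(p, 0.0) for p in all_pairs])
    bounds = weighted_quartile_bounds(dist.to_numpy(), weights)
    q = 1 + np.searchsorted(np.asarray(bounds), dist.to_numpy(), side="left")
    return {p: int(k) for p, k in zip(all_pairs, q)}, bounds


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


@dataclass
class CovariateSet:
    """Design values X for the regression models.

    Distance quartiles are encoded as three indicator covariates with a
    configurable reference quartile (Q2 by default, so effects read as
    contrasts against medium-distance travel).  ``rel_case`` is the weekly
    county case rate of each zip divided by the population-weighted city
    mean; it is absent (None) when the model carries no case covariate.
    """

    quartile_of_pair: dict[tuple[str, str], int]
    quartile_bounds: tuple[float, float, float]
    zip_static: pd.DataFrame  # index zip_id: prop_higher_income, median_income_std
    rel_case: pd.DataFrame | None = None  # index zip_id, columns week
    reference_quartile: int = 2

    @property
    def quartile_levels(self) -> list[int]:
        return [k for k in (1, 2, 3, 4) if k != self.reference_quartile]

    @property
    def names(self) -> list[str]:
        out = [f"dist_q{k}" for k in self.quartile_levels]
        out.append("prop_higher_income")
        if self.rel_case is not None:
            out.append("relative_case_rate")
        out.append("median_income_std")
        return out

    def design_matrix(
        self,
        origins: np.ndarray,
        pairs: list[tuple[str, str]],
        weeks: np.ndarray | None = None,
    ) -> np.ndarray:
        """Design rows for cells with given origin zip, route and week.

        The origin zip supplies the zip-level covariates (income proportion,
        case rate, median income); the route supplies the distance quartile.
        """
        n = len(origins)
        cols: list[np.ndarray] = []
        qvals = np.array([self.quartile_of_pair[p] for p in pairs])
        for k in self.quartile_levels:
            cols.append((qvals == k).astype(float))
        zs = self.zip_static
        zidx = zs.index.get_indexer(origins)
        if (zidx < 0).any():
            raise ValidationError("origin zip missing from covariate table")
        cols.append(zs["prop_higher_income"].to_numpy()[zidx])
        if self.rel_case is not None:
            if weeks is None:
                raise ValidationError("weeks required when a case covariate is present")
            rc = self.rel_case
            widx = rc.columns.get_indexer(weeks)
            if (widx < 0).any():
                missing = sorted(set(np.asarray(weeks)[widx < 0]))
                raise ValidationError(f"weeks missing from case-rate table: {missing}")
            rzidx = rc.index.get_indexer(origins)
            if (rzidx < 0).any():
                raise ValidationError("origin zip missing from case-rate table")
            cols.append(rc.to_numpy()[rzidx, widx])
        cols.append(zs["median_income_std"].to_numpy()[zidx])
        X = np.column_stack(cols)
        assert X.shape == (n, len(self.names))
        return X


def weekly_case_rates(cases: pd.DataFrame, start_date: pd.Timestamp | None = None) -> pd.DataFrame:
    """County-week case rates (per 100k/week) from a daily or weekly table.

    Daily values (columns county_id, date, cases_per_100k) are averaged
    within weeks anchored at ``start_date`` (default: first date present).
    A table already carrying a ``week`` column passes through.
    """
    if "week" in cases.columns:
        return cases[["county_id", "week", "cases_per_100k"]].copy()
    df = cases.copy()
    df["date"] = pd.to_datetime(df["date"])
    start = start_date if start_date is not None else df["date"].min()
    df["week"] = ((df["date"] - start).dt.days // 7 + 1).astype(int)
    return (
        df.groupby(["county_id", "week"], sort=True)["cases_per_100k"].mean().reset_index()
    )


def relative_case_rates(
    ziptable: ZipTable, county_week_rates: pd.DataFrame
) -> pd.DataFrame:
    """Zip-week case rates divided by the population-weighted city mean.

    Returns a frame indexed by zip with one column per week.  A week with a
    city-wide rate of zero yields zeros for every zip (with a warning).
    Population weighting uses census ``pop_total``, so within a city-week
    the population-weighted mean of the relative rates is 1.
    """
    counties = ziptable.df["county_id"]
    known = set(county_week_rates["county_id"].unique())
    unknown = sorted(set(counties) - known)
    if unknown:
        raise ValidationError(f"zips with county absent from case table: counties {unknown}")
    wide = county_week_rates.pivot(index="county_id", columns="week", values="cases_per_100k")
    ziprates = wide.loc[counties.to_numpy()]
    ziprates.index = ziptable.df.index
    pop = ziptable.df["pop_total"].to_numpy(float)
    means = (ziprates.to_numpy(float) * pop[:, None]).sum(axis=0) / pop.sum()
    out = np.zeros_like(ziprates.to_numpy(float))
    nz = means > 0
    out[:, nz] = ziprates.to_numpy(float)[:, nz] / means[nz]
    if (~nz).any():
        warnings.warn("city-wide case rate is zero in some weeks; relative rates set to 0")
    return pd.DataFrame(out, index=ziprates.index, columns=ziprates.columns)


def build_covariates(
    panel: TripPanel,
    ziptable: ZipTable,
    cases: pd.DataFrame | None = None,
    reference_quartile: int = 2,
    quartile_period: set[int] | None = None,
) -> CovariateSet:
    """Assemble the covariate set for a weekly panel.

    ``cases`` is a county-level case-rate table (daily or weekly); when
    None the relative case-rate covariate is omitted.  ``quartile_period``
    restricts the trip weighting of the distance quartiles to given weeks
    (e.g. the baseline month); default is the whole panel period.
    """
    qmap, bounds = assign_distance_quartiles(panel, ziptable, period_weeks=quartile_period)
    mi = ziptable.df["median_income"].to_numpy(float)
    sd = mi.std()
    std = (mi - mi.mean()) / sd if sd > 0 else np.zeros_like(mi)
    zip_static = pd.DataFrame(
        {
            "prop_higher_income": ziptable.df["prop_higher_income"].to_numpy(float),
            "median_income_std": std,
        },
        index=ziptable.df.index,
    )
    rel = None
    if cases is not None:
        weekly = weekly_case_rates(cases, start_date=panel.start_date)
        rel = relative_case_rates(ziptable, weekly)
    return CovariateSet(
        quartile_of_pair=qmap,
        quartile_bounds=bounds,
        zip_static=zip_static,
        rel_case=rel,
        reference_quartile=reference_quartile,
    )
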