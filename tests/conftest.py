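"""Shared fixtures: hand-built micro-cities and seeded synthetic panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from odmobility import SimConfig, TripPanel, ZipTable, generate_city, simulate_decline_panel


@pytest.fixture
def tiny_ziptable() -> ZipTable:
    """Four zips on a line at the equator with distinct pairwise spacings."""
    df = pd.DataFrame(
        {
            "lat": [0.0, 0.0, 0.0, 0.0],
            "lon": [0.0, 1.0, 2.5, 4.75],
            "pop_total": [1000.0, 2000.0, 1500.0, 1200.0],
            "median_income": [40000.0, 60000.0, 50000.0, 70000.0],
            "county_id": ["CA", "CA", "CB", "CB"],
            "subs_18_34": [100.0, 120.0, 90.0, 110.0],
            "subs_35_54": [110.0, 130.0, 95.0, 115.0],
            "subs_55p": [120.0, 140.0, 100.0, 125.0],
            "prop_higher_income": [0.3, 0.45, 0.6, 0.75],
        },
        index=pd.Index(["A", "B", "C", "D"], name="zip_id"),
    )
    return ZipTable(df)


def make_weekly_panel(records, censor_threshold=50, data_loss_weeks=()):
    """records: iterable of (origin, dest, age, week, count_or_None)."""
    rows = []
    for o, d, a, w, c in records:
        rows.append(
            {
                "origin": o,
                "dest": d,
                "age_group": a,
                "week": w,
                "count": np.nan if c is None else float(c),
                "censored": c is None,
            }
        )
    return TripPanel(
        df=pd.DataFrame(rows),
        resolution="weekly",
        censor_threshold=censor_threshold,
        data_loss_weeks=frozenset(data_loss_weeks),
    )


@pytest.fixture(scope="session")
def city8():
    """A seeded 8-zip city with its decline panel and generative truth."""
    cfg = SimConfig(n_zips=8, seed=42)
    zt = generate_city(cfg)
    panel, truth = simulate_decline_panel(zt, cfg)
    return zt, panel, truth


@pytest.fixture(scope="session")
def city8_mean():
    """Noiseless (mean-mode, uncensored) 8-zip city for exact identities."""
    cfg = SimConfig(n_zips=8, seed=42, censor_threshold=0)
    zt = generate_city(cfg)
    panel, truth = simulate_decline_panel(zt, cfg, mode="mean")
    return zt, panel, truth
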