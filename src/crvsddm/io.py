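"""CSV dialects for census counts, death counts, surveys and registry series.

All inputs are tidy delimited tables:

* census:   ``sex,age_start,open,count,date`` (two distinct dates)
* deaths:   ``sex,age_start,open,deaths,period_start,period_end``
* sibling:  ``respondent_id,weight,sib_sex,alive,current_age,age_at_death,
  years_since_death,birth_date,death_date,interview_date``
* household: ``household_id,weight,sex,age,died,death_date,survey_date``
* registry: ``year,sex,count`` per source
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .ddm import CensusPair, DeathSeries
from .grids import AgeGrid

__all__ = [
    "read_census",
    "read_deaths",
    "census_pair_from_frame",
    "death_series_from_frame",
    "census_pair_to_frame",
    "death_series_to_frame",
    "peru_registry_counts",
]


def _grid_from_rows(rows: pd.DataFrame) -> AgeGrid:
    rows = rows.sort_values("age_start")
    open_rows = rows[rows["open"].astype(bool)]
    if len(open_rows) != 1:
        raise ValueError("exactly one open age group is required per series")
    open_age = int(open_rows["age_start"].iloc[0])
    closed = tuple(int(a) for a in rows.loc[~rows["open"].astype(bool),
                                            "age_start"])
    return AgeGrid(closed, open_age)


def read_census(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_deaths(path) -> pd.DataFrame:
    return pd.read_csv(path)


def census_pair_from_frame(df: pd.DataFrame, sex: str) -> CensusPair:
    sub = df[df["sex"] == sex]
    dates = np.sort(sub["date"].unique())
    if len(dates) != 2:
        raise ValueError(f"need exactly two census dates for {sex}, "
                         f"found {len(dates)}")
    d1, d2 = float(dates[0]), float(dates[1])
    c1 = sub[sub["date"] == dates[0]].sort_values("age_start")
    c2 = sub[sub["date"] == dates[1]].sort_values("age_start")
    grid = _grid_from_rows(c1)
    if _grid_from_rows(c2) != grid:
        raise ValueError("the two censuses use different age grids")
    return CensusPair(grid=grid, sex=sex, date1=d1, date2=d2,
                      N1=c1["count"].to_numpy(dtype=float),
                      N2=c2["count"].to_numpy(dtype=float))


def death_series_from_frame(df: pd.DataFrame, sex: str,
                            grid: AgeGrid | None = None) -> DeathSeries:
    sub = df[df["sex"] == sex].sort_values("age_start")
    g = _grid_from_rows(sub)
    if grid is not None and g != grid:
        raise ValueError("death series grid does not match the census grid")
    return DeathSeries(grid=g, sex=sex,
                       period_start=float(sub["period_start"].iloc[0]),
                       period_end=float(sub["period_end"].iloc[0]),
                       D_star=sub["deaths"].to_numpy(dtype=float))


def census_pair_to_frame(cp: CensusPair) -> pd.DataFrame:
    rows = []
    opens = [False] * (cp.grid.n_groups - 1) + [True]
    for date, counts in ((cp.date1, cp.N1), (cp.date2, cp.N2)):
        for age, op, cnt in zip(cp.grid.starts, opens, counts):
            rows.append((cp.sex, int(age), op, float(cnt), date))
    return pd.DataFrame(rows, columns=["sex", "age_start", "open", "count",
                                       "date"])


def death_series_to_frame(ds: DeathSeries) -> pd.DataFrame:
    opens = [False] * (ds.grid.n_groups - 1) + [True]
    return pd.DataFrame(
        {
            "sex": ds.sex,
            "age_start": ds.grid.starts,
            "open": opens,
            "deaths": ds.D_star,
            "period_start": ds.period_start,
            "period_end": ds.period_end,
        }
    )


def peru_registry_counts() -> pd.DataFrame:
    """Published annual death totals from Peru's health ministry (MINSA)
    and civil registry (RENIEC), 2005-2019, by sex.

    Returns a tidy frame with columns ``year,sex,minsa,reniec``.
    """
    ref = importlib.resources.files("crvsddm.data") / "peru_registry_deaths.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)
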