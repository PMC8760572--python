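"""Direct adult-mortality estimation from DHS-style survey modules.

Two survey instruments are supported:

* **Sibling histories** — female respondents list their brothers and
  sisters with survival status, current age (if alive) or age at death
  and years since death (if dead). Person-years of exposure and deaths
  are accumulated by five-year age group over a reference period, giving
  age-specific death rates and the adult mortality probability 35q15.
  Exact birth/death dates are frequently blank in these files and are
  imputed from the integer age/recall variables with a midpoint (+0.5)
  convention.

* **Household deaths** — household rosters recording deaths in a fixed
  window (default five years) before the survey date, giving death rates
  by sex and age from a single source.

Uncertainty for the sibling estimate comes from a respondent-level
bootstrap: whole respondents (with all their siblings) are resampled
with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import AgeGrid, FEMALE, MALE
from .lifetable import build_life_table, rate_to_prob, sexgap_e15
from .grids import RateSchedule

__all__ = [
    "ExposureTable",
    "impute_sibling_dates",
    "sibling_exposure",
    "direct_35q15",
    "household_rates",
    "screen_survey_weights",
    "adult_grid",
    "SiblingSurveyModel",
    "SiblingResults",
    "HouseholdSurveyModel",
    "HouseholdResults",
    "WeightScreenVerdict",
]

SIBLING_COLUMNS = [
    "respondent_id", "weight", "sib_sex", "alive", "current_age",
    "age_at_death", "years_since_death", "birth_date", "death_date",
    "interview_date",
]

HOUSEHOLD_COLUMNS = [
    "household_id", "weight", "sex", "age", "died", "death_date",
    "survey_date",
]


def adult_grid() -> AgeGrid:
    """The seven five-year groups 15-19 ... 45-49 (open 50+, unused)."""
    return AgeGrid(tuple(range(15, 50, 5)), 50)


# ---------------------------------------------------------------------------
# date imputation


def impute_sibling_dates(records: pd.DataFrame):
    """Fill missing sibling birth/death dates from age and recall variables.

    For dead siblings lacking explicit dates:
    ``death_date = interview_date - (years_since_death + 0.5)`` and
    ``birth_date = death_date - (age_at_death + 0.5)``; for living
    siblings ``birth_date = interview_date - (current_age + 0.5)``. The
    +0.5 midpoint reflects that the integer fields are completed years.
    Explicit dates are never overwritten.

    Returns ``(imputed_frame, n_unusable)`` where unusable dead records
    (no dates and no age/recall pair) are dropped.
    """
    df = records.copy()
    if df["interview_date"].isna().any():
        raise ValueError("interview_date must be present on every record")
    dead = ~df["alive"].astype(bool)

    need_dd = dead & df["death_date"].isna()
    can_dd = need_dd & df["years_since_death"].notna()
    df.loc[can_dd, "death_date"] = (
        df.loc[can_dd, "interview_date"]
        - (df.loc[can_dd, "years_since_death"] + 0.5)
    )

    need_bd = dead & df["birth_date"].isna()
    can_bd = need_bd & df["death_date"].notna() & df["age_at_death"].notna()
    df.loc[can_bd, "birth_date"] = (
        df.loc[can_bd, "death_date"] - (df.loc[can_bd, "age_at_death"] + 0.5)
    )

    living_bd = ~dead & df["birth_date"].isna() & df["current_age"].notna()
    df.loc[living_bd, "birth_date"] = (
        df.loc[living_bd, "interview_date"]
        - (df.loc[living_bd, "current_age"] + 0.5)
    )

    usable = df["birth_date"].notna() & (~dead | df["death_date"].notna())
    n_unusable = int((~usable).sum())
    return df[usable].reset_index(drop=True), n_unusable


# ---------------------------------------------------------------------------
# exposure tabulation


@dataclass
class ExposureTable:
    """Weighted person-years and deaths by five-year age cell, one sex.

    ``py_by_respondent`` / ``deaths_by_respondent`` keep the per-respondent
    decomposition (n_respondents x n_cells) used by the bootstrap.
    """

    grid: AgeGrid
    sex: str
    period: tuple
    person_years: np.ndarray
    deaths: np.ndarray
    respondent_ids: np.ndarray = field(default=None, repr=False)
    py_by_respondent: np.ndarray = field(default=None, repr=False)
    deaths_by_respondent: np.ndarray = field(default=None, repr=False)
    weights_by_respondent: np.ndarray = field(default=None, repr=False)


def sibling_exposure(records: pd.DataFrame, period, sex: str,
                     grid: AgeGrid | None = None) -> ExposureTable:
    """Tabulate weighted sibling person-years and deaths over ``period``.

    Each sibling of the given sex contributes time from
    max(birth, period start) to min(death-or-interview, period end),
    split exactly across the five-year age cells crossed as age advances;
    a death landing inside the period and age range adds the respondent
    weight to its cell. Records must be date-complete (run
    :func:`impute_sibling_dates` first). Periods are half-open
    ``[start, end)``.
    """
    p0, p1 = float(period[0]), float(period[1])
    if p1 <= p0:
        raise ValueError("period end must follow period start")
    grid = grid or adult_grid()
    cells = grid.start_ages
    n_cells = len(cells)

    df = records[records["sib_sex"] == sex]
    resp_ids, resp_idx = np.unique(df["respondent_id"].to_numpy(),
                                   return_inverse=True)
    n_resp = len(resp_ids)
    py_mat = np.zeros((n_resp, n_cells))
    d_mat = np.zeros((n_resp, n_cells))
    w = df["weight"].to_numpy(dtype=float)
    resp_w = np.zeros(n_resp)
    np.maximum.at(resp_w, resp_idx, np.nan_to_num(w, nan=0.0))

    if len(df):
        birth = df["birth_date"].to_numpy(dtype=float)
        interview = df["interview_date"].to_numpy(dtype=float)
        dead = ~df["alive"].to_numpy(dtype=bool)
        death = df["death_date"].to_numpy(dtype=float)
        end_obs = np.where(dead, death, interview)
        if np.isnan(birth).any() or np.isnan(end_obs).any():
            raise ValueError("records are not date-complete; impute dates first")

        for j, a in enumerate(cells):
            lo = np.maximum.reduce([birth + a, np.full_like(birth, p0)])
            hi = np.minimum.reduce([birth + a + 5.0, end_obs,
                                    np.full_like(birth, p1)])
            contrib = w * np.clip(hi - lo, 0.0, None)
            np.add.at(py_mat, (resp_idx, j), contrib)

        age_at_death = death - birth
        in_win = dead & (death >= p0) & (death < p1)
        in_age = (age_at_death >= cells[0]) & (age_at_death < cells[-1] + 5.0)
        sel = in_win & in_age
        if sel.any():
            cell_ix = ((age_at_death[sel] - cells[0]) // 5).astype(int)
            np.add.at(d_mat, (resp_idx[sel], cell_ix), w[sel])

    return ExposureTable(
        grid=grid, sex=sex, period=(p0, p1),
        person_years=py_mat.sum(axis=0), deaths=d_mat.sum(axis=0),
        respondent_ids=resp_ids, py_by_respondent=py_mat,
        deaths_by_respondent=d_mat, weights_by_respondent=resp_w,
    )


# ---------------------------------------------------------------------------
# direct 35q15 with bootstrap


@dataclass
class Direct35q15:
    """Point estimate, rates, and bootstrap interval for 35q15."""

    sex: str
    period: tuple
    q3515: float
    M: np.ndarray
    q: np.ndarray
    conf_int: tuple
    boot: np.ndarray = field(repr=False)
    n_boot: int = 0
    seed: int | None = None


def _q3515_from_cells(py: np.ndarray, deaths: np.ndarray) -> float:
    M = deaths / py
    q = rate_to_prob(M, 5.0, 2.5)
    return float(1.0 - np.prod(1.0 - q))


def direct_35q15(exposure: ExposureTable, n_boot: int = 200,
                 seed: int | None = 0, alpha: float = 0.05) -> Direct35q15:
    """35q15 from an exposure table, with a respondent-level bootstrap CI.

    Rates per cell are deaths/person-years, converted to five-year
    probabilities with a = 2.5; 35q15 = 1 - prod(1 - q). The percentile
    bootstrap resamples whole respondents with replacement.
    """
    py, deaths = exposure.person_years, exposure.deaths
    zero = py <= 0
    if zero.any():
        bad = [exposure.grid.labels()[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero exposure in cells {bad}; widen the period")
    M = deaths / py
    q = rate_to_prob(M, 5.0, 2.5)
    point = float(1.0 - np.prod(1.0 - q))

    boots = np.empty(0)
    ci = (float("nan"), float("nan"))
    if n_boot and exposure.py_by_respondent is not None:
        rng = np.random.default_rng(seed)
        n_resp = exposure.py_by_respondent.shape[0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            counts = rng.multinomial(n_resp, np.full(n_resp, 1.0 / n_resp))
            py_b = counts @ exposure.py_by_respondent
            d_b = counts @ exposure.deaths_by_respondent
            if np.any(py_b <= 0):
                boots[b] = np.nan
                continue
            boots[b] = _q3515_from_cells(py_b, d_b)
        ok = boots[np.isfinite(boots)]
        if len(ok):
            ci = (float(np.percentile(ok, 100 * alpha / 2)),
                  float(np.percentile(ok, 100 * (1 - alpha / 2))))

    return Direct35q15(sex=exposure.sex, period=exposure.period, q3515=point,
                       M=M, q=q, conf_int=ci, boot=boots, n_boot=n_boot,
                       seed=seed)


# ---------------------------------------------------------------------------
# weight screening


@dataclass
class WeightScreenVerdict:
    """Usable/dropped verdict for one survey's weight column."""

    usable: bool
    missing_fraction: float
    n_records: int
    threshold: float

    def __str__(self):
        verdict = "usable" if self.usable else "dropped"
        return (f"{verdict}: {self.missing_fraction:.1%} of {self.n_records} "
                f"weights missing (threshold {self.threshold:.0%})")


def screen_survey_weights(survey_table: pd.DataFrame, weight_col: str = "weight",
                          threshold: float = 0.5) -> WeightScreenVerdict:
    """Drop a survey year whose sampling weights are mostly missing.

    The survey is dropped when the missing fraction strictly exceeds
    ``threshold`` (a table exactly at the threshold is retained).
    """
    col = survey_table[weight_col]
    n = len(col)
    frac = float(col.isna().mean()) if n else 0.0
    return WeightScreenVerdict(usable=frac <= threshold, missing_fraction=frac,
                               n_records=n, threshold=threshold)


# ---------------------------------------------------------------------------
# household deaths


@dataclass
class HouseholdResults:
    """Death rates and life-table summaries from a household-death module."""

    grid: AgeGrid
    window: tuple
    mid_period: float
    person_years: dict
    deaths: dict

    def rate_schedule(self, sex: str) -> RateSchedule:
        py = self.person_years[sex]
        if np.any(py <= 0):
            bad = [self.grid.labels()[i] for i in np.flatnonzero(py <= 0)]
            raise ValueError(f"zero exposure for {sex} in cells {bad}")
        return RateSchedule(grid=self.grid, sex=sex,
                            M=self.deaths[sex] / py)

    def life_table(self, sex: str, radix: float = 100_000.0):
        return build_life_table(self.rate_schedule(sex), radix=radix)

    def q3515(self, sex: str) -> float:
        lo = self.grid.index_of(15)
        hi = self.grid.index_of(45)
        py = self.person_years[sex][lo:hi + 1]
        d = self.deaths[sex][lo:hi + 1]
        if np.any(py <= 0):
            raise ValueError(f"zero adult exposure for {sex}")
        return _q3515_from_cells(py, d)

    def e15(self, sex: str) -> float:
        return self.life_table(sex).e_at(15)

    def sexgap_e15(self) -> float:
        return sexgap_e15(self.life_table(FEMALE), self.life_table(MALE))

    def summary(self) -> str:
        lines = [
            "Household-death module results",
            "=" * 46,
            f"window:     [{self.window[0]:.1f}, {self.window[1]:.1f})  "
            f"mid-period {self.mid_period:.1f}",
        ]
        for sex in (FEMALE, MALE):
            if sex in self.deaths:
                try:
                    q = self.q3515(sex)
                    lines.append(f"{sex:8s} 35q15 = {q:.4f}  "
                                 f"(deaths {self.deaths[sex].sum():.0f})")
                except ValueError:
                    lines.append(f"{sex:8s} adult exposure incomplete")
        return "\n".join(lines)


def household_rates(records: pd.DataFrame, survey_date: float,
                    window_years: float = 5.0,
                    grid: AgeGrid | None = None) -> HouseholdResults:
    """Death rates by sex and age from household deaths in a lookback window.

    Deaths and person-years are tabulated over
    ``[survey_date - window, survey_date)``. Member birth dates are
    reconstructed with the midpoint convention: alive members from the
    age at survey, dead members from the age at death and death date.
    The mid-period label is ``survey_date - window/2``.
    """
    if window_years <= 0:
        raise ValueError("window must be positive")
    grid = grid or AgeGrid.standard(0, 80)
    p0, p1 = survey_date - window_years, survey_date
    cells = grid.starts
    n_cells = grid.n_groups

    py = {}
    deaths = {}
    for sex, df in records.groupby("sex"):
        age = df["age"].to_numpy(dtype=float)
        died = df["died"].to_numpy(dtype=bool)
        ddate = df["death_date"].to_numpy(dtype=float)
        w = df["weight"].to_numpy(dtype=float)
        birth = np.where(died, ddate - (age + 0.5), survey_date - (age + 0.5))
        end_obs = np.where(died, ddate, p1)

        py_s = np.zeros(n_cells)
        d_s = np.zeros(n_cells)
        for j, a in enumerate(cells):
            upper = np.inf if j == n_cells - 1 else birth + a + 5.0
            lo = np.maximum(birth + a, p0)
            hi = np.minimum(upper, np.minimum(end_obs, p1))
            py_s[j] = np.sum(w * np.clip(hi - lo, 0.0, None))
        dead_in = died & (ddate >= p0) & (ddate < p1)
        age_d = age[dead_in] + 0.5
        cell_ix = np.clip(np.searchsorted(cells, age_d, side="right") - 1,
                          0, n_cells - 1)
        np.add.at(d_s, cell_ix, w[dead_in])
        py[sex] = py_s
        deaths[sex] = d_s

    return HouseholdResults(grid=grid, window=(p0, p1),
                            mid_period=survey_date - window_years / 2.0,
                            person_years=py, deaths=deaths)


# ---------------------------------------------------------------------------
# model front-ends


class SiblingSurveyModel:
    """Sibling-history survey model.

    Wraps date imputation, weight screening, exposure tabulation and the
    bootstrapped direct 35q15 estimate.

    Parameters
    ----------
    records : DataFrame
        One row per reported sibling (columns of ``SIBLING_COLUMNS``).
    weight_threshold : float
        Surveys whose weight column exceeds this missing fraction raise
        at fit time (mirroring exclusion of unusable survey years).
    """

    def __init__(self, records: pd.DataFrame, weight_threshold: float = 0.5):
        self.screen = screen_survey_weights(records, threshold=weight_threshold)
        self.records, self.n_unusable = impute_sibling_dates(records)

    def fit(self, period, n_boot: int = 200, seed: int | None = 0,
            sexes=(FEMALE, MALE)) -> "SiblingResults":
        if not self.screen.usable:
            raise ValueError(f"survey weights unusable ({self.screen})")
        by_sex = {}
        for sex in sexes:
            exp = sibling_exposure(self.records, period, sex)
            by_sex[sex] = direct_35q15(exp, n_boot=n_boot, seed=seed)
        return SiblingResults(self, tuple(period), by_sex)


class SiblingResults:
    """Per-sex direct 35q15 estimates from one sibling survey."""

    def __init__(self, model: SiblingSurveyModel, period, by_sex: dict):
        self.model = model
        self.period = period
        self.by_sex = by_sex

    def q3515(self, sex: str) -> float:
        return self.by_sex[sex].q3515

    def conf_int(self, sex: str) -> tuple:
        return self.by_sex[sex].conf_int

    def summary(self) -> str:
        lines = [
            "Sibling-history direct estimates",
            "=" * 46,
            f"period:            [{self.period[0]:.1f}, {self.period[1]:.1f})",
            f"unusable records:  {self.model.n_unusable}",
        ]
        for sex, r in self.by_sex.items():
            lo, hi = r.conf_int
            lines.append(
                f"{sex:8s} 35q15 = {r.q3515:.4f}  "
                f"(95% bootstrap CI {lo:.4f}-{hi:.4f}, {r.n_boot} reps)"
            )
        return "\n".join(lines)


class HouseholdSurveyModel:
    """Household-death module model: tabulation plus life-table summaries."""

    def __init__(self, records: pd.DataFrame):
        self.records = records

    def fit(self, survey_date: float | None = None, window_years: float = 5.0,
            grid: AgeGrid | None = None) -> HouseholdResults:
        if survey_date is None:
            survey_date = float(self.records["survey_date"].iloc[0])
        return household_rates(self.records, survey_date,
                               window_years=window_years, grid=grid)
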