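"""Synthetic populations and surveys with known ground truth.

Three generators mirror the three estimation stages:

* :func:`make_ddm_scenario` — a stable population closed to migration,
  observed through two coverage-degraded censuses and a
  completeness-degraded death register. The stable age distribution is
  ``N(a) da = B exp(-r a) l(a) da`` with a Gompertz survival function
  ``l(a) = exp(-(alpha/beta)(exp(beta a) - 1))``. True intercensal deaths
  are defined from the same discrete growth-balance identity the
  estimators use (birthday flow minus growth of the open segment), so
  that in the deterministic, closed, age-constant case the GGB plotting
  coordinates are exactly collinear and completeness recovery error is
  attributable to the estimators alone. A Poisson switch adds count
  noise; a migration schedule and an age-varying-completeness switch
  deliberately break the method assumptions for negative-control tests.

* :func:`make_sibling_survey` — DHS-like sibling rosters drawn from a
  known life table, rendered with the missing-date pathology of real
  files: integer age at death and years since death, blank date columns.

* :func:`make_household_survey` — household rosters with exact
  continuous-time deaths over a pre-survey window under a
  piecewise-constant hazard, reported with integer ages.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import CensusPair, DeathSeries
from .grids import AgeGrid, FEMALE, MALE, RateSchedule
from .lifetable import LifeTable

__all__ = [
    "ScenarioTruth",
    "ScenarioData",
    "make_ddm_scenario",
    "make_sibling_survey",
    "make_household_survey",
    "default_sibship_dist",
]

_AGE_CAP = 130.0   # integration horizon for the open interval
_H = 1.0 / 64.0    # quadrature step (years) for stable-population integrals


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground-truth parameters of a two-census DDM scenario.

    Adult hazard is Gompertz, ``mu(x) = alpha * exp(beta * x)``;
    ``c`` is death-registration completeness, ``k1``/``k2`` census
    enumeration coverages, ``r`` the stable growth rate, ``t`` the
    intercensal length in years.
    """

    r: float = 0.01
    alpha: float = 3e-4
    beta: float = 0.068
    c: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    t: float = 10.0
    sex: str = FEMALE
    births: float = 100_000.0
    date1: float = 2000.0
    grid: AgeGrid = field(default_factory=AgeGrid.standard)
    poisson_noise: bool = False
    completeness_age_slope: float = 0.0   # per year of age, relative
    migration: tuple | None = None        # net rate per group, per year

    def __post_init__(self):
        if self.alpha <= 0 or self.beta < 0:
            raise ValueError("Gompertz parameters need alpha > 0, beta >= 0")
        if not 0 < self.c <= 1:
            raise ValueError("completeness c must lie in (0, 1]")
        for k in (self.k1, self.k2):
            if not 0 < k <= 1:
                raise ValueError("census coverages must lie in (0, 1]")
        if not 1 < self.t < 30:
            raise ValueError("intercensal length must lie in (1, 30)")

    def survival(self, a):
        """Gompertz survival l(a) from birth."""
        a = np.asarray(a, dtype=float)
        if self.beta == 0:
            return np.exp(-self.alpha * a)
        return np.exp(-(self.alpha / self.beta) * (np.exp(self.beta * a) - 1.0))

    def hazard(self, a):
        return self.alpha * np.exp(self.beta * np.asarray(a, dtype=float))


@dataclass
class ScenarioData:
    """Observed census pair and death series plus retained ground truth."""

    census_pair: CensusPair
    death_series: DeathSeries
    truth: ScenarioTruth
    true_deaths: np.ndarray         # per group, full intercensal period
    true_pop_mid: np.ndarray        # per group, mid-period
    seed: int | None = None

    def true_rates(self) -> RateSchedule:
        """True death rates per group: true deaths over true person-years."""
        PY = self.truth.t * self.true_pop_mid
        return RateSchedule(grid=self.truth.grid, sex=self.truth.sex,
                            M=self.true_deaths / PY)


def _stable_group_counts(truth: ScenarioTruth) -> np.ndarray:
    """Integral of B exp(-r a) l(a) over each grid group (census-1 time)."""
    grid = truth.grid
    edges = np.r_[grid.starts.astype(float), _AGE_CAP]
    a = np.arange(0.0, _AGE_CAP + _H, _H)
    dens = truth.births * np.exp(-truth.r * a) * truth.survival(a)
    # trapezoid masses per fine step, then bucket by group
    seg = 0.5 * (dens[1:] + dens[:-1]) * _H
    mids = 0.5 * (a[1:] + a[:-1])
    ix = np.clip(np.searchsorted(edges, mids, side="right") - 1, 0,
                 grid.n_groups - 1)
    G = np.zeros(grid.n_groups)
    np.add.at(G, ix, seg)
    return G


def make_ddm_scenario(truth: ScenarioTruth, seed: int | None = None) -> ScenarioData:
    """Build a two-census DDM scenario with known completeness.

    Census 1 counts are ``k1 * N``, census 2 ``k2 * N * exp(r t)`` (the
    stable population grown over the intercensal length); registered
    deaths are ``c`` times the true deaths in every age group, exactly,
    unless Poisson noise or age-varying completeness is switched on.
    """
    grid = truth.grid
    P1 = _stable_group_counts(truth)                # true census-1 population
    P_mid = P1 * np.exp(truth.r * truth.t / 2.0)    # true mid-period population
    P2 = P1 * np.exp(truth.r * truth.t)

    # True annual deaths above each cumulation age from the discrete
    # growth-balance identity: deaths(x+) = birthday flow at x - r * N(x+).
    b_mid = (P_mid[:-1] + P_mid[1:]) / 10.0         # flow at starts[1:]
    # the group-mean flow estimate is invalid at the open age (the open
    # group is not five years wide); use the exact stable flow there
    A = float(grid.open_age)
    b_mid[-1] = (truth.births * np.exp(-truth.r * A) * truth.survival(A)
                 * np.exp(truth.r * truth.t / 2.0))
    N_plus_mid = np.cumsum(P_mid[::-1])[::-1]
    D_yr_plus = b_mid - truth.r * N_plus_mid[1:]
    if np.any(D_yr_plus <= 0):
        raise ValueError("growth rate too high for this mortality schedule "
                         "(negative implied deaths)")
    d_yr = np.empty(grid.n_groups)
    d_yr[1:-1] = D_yr_plus[:-1] - D_yr_plus[1:]
    d_yr[-1] = D_yr_plus[-1]
    # group 0-4 plays no role in adult DDM; use the hazard integral
    a0 = np.arange(0.0, 5.0 + _H, _H)
    f0 = truth.births * np.exp(-truth.r * a0) * truth.survival(a0) * truth.hazard(a0)
    d_yr[0] = np.trapezoid(f0, a0) * np.exp(truth.r * truth.t / 2.0)
    if np.any(d_yr < 0):
        raise ValueError("negative per-group deaths; schedule/growth inconsistent")
    true_deaths = d_yr * truth.t

    c_by_group = np.full(grid.n_groups, truth.c)
    if truth.completeness_age_slope:
        mids = np.r_[grid.starts[:-1] + 2.5, grid.open_age + 5.0]
        c_by_group = np.clip(
            truth.c * (1.0 + truth.completeness_age_slope * (mids - 40.0)),
            0.01, 1.5,
        )
    registered = c_by_group * true_deaths

    N1 = truth.k1 * P1
    N2 = truth.k2 * P2
    if truth.migration is not None:
        m = np.asarray(truth.migration, dtype=float)
        if m.shape != (grid.n_groups,):
            raise ValueError("migration schedule must have one rate per group")
        N2 = N2 * np.exp(m * truth.t)

    if truth.poisson_noise:
        rng = np.random.default_rng(seed)
        registered = rng.poisson(registered).astype(float)
        N1 = rng.poisson(N1).astype(float)
        N2 = rng.poisson(N2).astype(float)

    cp = CensusPair(grid=grid, sex=truth.sex, date1=truth.date1,
                    date2=truth.date1 + truth.t, N1=N1, N2=N2)
    ds = DeathSeries(grid=grid, sex=truth.sex, period_start=truth.date1,
                     period_end=truth.date1 + truth.t, D_star=registered)
    return ScenarioData(census_pair=cp, death_series=ds, truth=truth,
                        true_deaths=true_deaths, true_pop_mid=P_mid, seed=seed)


# ---------------------------------------------------------------------------
# sibling histories


def default_sibship_dist() -> np.ndarray:
    """Default sibship-size distribution over {1..10}: shifted Poisson(3)."""
    from scipy.stats import poisson

    p = poisson.pmf(np.arange(10), 3.0)
    return p / p.sum()


def _sample_death_ages(lt: LifeTable, n: int, rng) -> np.ndarray:
    """Exact ages at death drawn from a life table.

    Deaths are uniform within closed intervals (consistent with a = n/2)
    and exponential with the open-interval rate beyond the open age.
    """
    l = lt.l / lt.radix
    u = rng.uniform(0.0, 1.0, size=n)
    starts = lt.grid.starts.astype(float)
    # group in which death occurs: largest j with l[j] >= u
    j = np.searchsorted(-l, -u, side="right") - 1
    j = np.clip(j, 0, len(l) - 1)
    ages = np.empty(n)
    closed = j < len(l) - 1
    jc = j[closed]
    frac = (l[jc] - u[closed]) / (l[jc] - l[jc + 1])
    ages[closed] = starts[jc] + 5.0 * frac
    n_open = int((~closed).sum())
    if n_open:
        ages[~closed] = starts[-1] + rng.exponential(1.0 / lt.M[-1], size=n_open)
    return ages


def make_sibling_survey(
    n_respondents: int,
    sibship_size_dist,
    lifetable: LifeTable,
    interview_date: float,
    seed: int | None = 0,
    weight_missing_frac: float = 0.0,
    respondent_age_range: tuple = (15.0, 50.0),
    sibling_age_spread: float = 10.0,
) -> pd.DataFrame:
    """Simulate a DHS-like sibling-history file from a known life table.

    Respondent ages are uniform over ``respondent_age_range`` at
    interview; sibling births scatter uniformly within
    ``+/- sibling_age_spread`` years of the respondent's. Each sibling's
    age at death is drawn from ``lifetable``; siblings whose death falls
    after the interview are recorded alive. Dead siblings carry integer
    ``age_at_death`` and ``years_since_death`` with the date columns
    blank, reproducing the missing-date pathology of real files.
    """
    if sibship_size_dist is None:
        sibship_size_dist = default_sibship_dist()
    p = np.asarray(sibship_size_dist, dtype=float)
    if len(p) != 10 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("sibship_size_dist must be 10 probabilities summing to 1")
    rng = np.random.default_rng(seed)

    resp_age = rng.uniform(*respondent_age_range, size=n_respondents)
    resp_birth = interview_date - resp_age
    sizes = rng.choice(np.arange(1, 11), size=n_respondents, p=p)
    resp_idx = np.repeat(np.arange(n_respondents), sizes)
    n_sib = len(resp_idx)

    sib_birth = resp_birth[resp_idx] + rng.uniform(
        -sibling_age_spread, sibling_age_spread, size=n_sib
    )
    death_age = _sample_death_ages(lifetable, n_sib, rng)
    death_date = sib_birth + death_age
    dead = death_date < interview_date

    weight = np.ones(n_respondents)
    if weight_missing_frac > 0:
        n_miss = int(round(weight_missing_frac * n_respondents))
        miss = rng.choice(n_respondents, size=n_miss, replace=False)
        weight[miss] = np.nan

    df = pd.DataFrame(
        {
            "respondent_id": resp_idx,
            "weight": weight[resp_idx],
            "sib_sex": rng.choice([FEMALE, MALE], size=n_sib),
            "alive": ~dead,
            "current_age": np.where(
                dead, np.nan, np.floor(interview_date - sib_birth)
            ),
            "age_at_death": np.where(dead, np.floor(death_age), np.nan),
            "years_since_death": np.where(
                dead, np.floor(interview_date - death_date), np.nan
            ),
            "birth_date": np.nan,
            "death_date": np.nan,
            "interview_date": interview_date,
        }
    )
    return df


# ---------------------------------------------------------------------------
# household deaths


def make_household_survey(
    n_households: int,
    schedule,
    survey_date: float,
    window: float = 5.0,
    seed: int | None = 0,
    mean_household_size: float = 4.0,
    age_range: tuple = (0.0, 85.0),
) -> pd.DataFrame:
    """Simulate a household-death module under a piecewise-constant hazard.

    ``schedule`` is a :class:`RateSchedule` applied to both sexes or a
    ``{sex: RateSchedule}`` mapping. Member ages at the window start are
    uniform over ``age_range``; deaths over the window are exact
    continuous-time draws from the age-advancing piecewise-constant
    hazard. Ages are reported as completed years.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not isinstance(schedule, dict):
        schedule = {FEMALE: schedule, MALE: schedule}
    rng = np.random.default_rng(seed)
    w0 = survey_date - window

    sizes = np.maximum(rng.poisson(mean_household_size, size=n_households), 1)
    hh_idx = np.repeat(np.arange(n_households), sizes)
    n = len(hh_idx)
    age0 = rng.uniform(*age_range, size=n)
    sex = rng.choice(sorted(schedule), size=n)

    death_time = np.full(n, np.inf)     # years after window start
    E = rng.exponential(1.0, size=n)
    for s, sched in schedule.items():
        sel = sex == s
        death_time[sel] = _piecewise_death_time(
            age0[sel], E[sel], sched, window
        )

    died = death_time < window
    death_date = np.where(died, w0 + death_time, np.nan)
    age_out = np.where(died, np.floor(age0 + death_time),
                       np.floor(age0 + window))

    return pd.DataFrame(
        {
            "household_id": hh_idx,
            "weight": 1.0,
            "sex": sex,
            "age": age_out,
            "died": died,
            "death_date": death_date,
            "survey_date": survey_date,
        }
    )


def _piecewise_death_time(age0, E, sched: RateSchedule, horizon: float):
    """Time to death under an age-advancing piecewise-constant hazard.

    Inverts cumulative hazard against exponential draws ``E``; returns
    ``inf`` where the cumulative hazard over ``horizon`` never reaches E.
    """
    starts = sched.grid.starts.astype(float)
    M = sched.M
    n = len(age0)
    t_done = np.zeros(n)
    cum = np.zeros(n)
    out = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    while np.any(alive) and np.any(t_done < horizon):
        a_now = age0 + t_done
        j = np.clip(np.searchsorted(starts, a_now, side="right") - 1, 0,
                    len(starts) - 1)
        nxt = starts[np.minimum(j + 1, len(starts) - 1)]
        seg_end = np.where(j == len(starts) - 1, np.inf, nxt)
        dt = np.minimum(seg_end - a_now, horizon - t_done)
        lam = M[j]
        need = np.where(lam > 0, (E - cum) / np.where(lam > 0, lam, 1.0), np.inf)
        dies = alive & (need <= dt) & (t_done < horizon)
        out[dies] = t_done[dies] + need[dies]
        alive &= ~dies
        cum = cum + lam * dt
        t_done = t_done + dt
        if np.all(t_done >= horizon):
            break
    return out
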