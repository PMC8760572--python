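"""Death distribution methods: GGB, SEG, and the combined GGB-SEG.

Death distribution methods compare the age distribution of registered
intercensal deaths with two census age distributions to estimate the
completeness ``C`` of death registration relative to census coverage.

* **GGB** (generalized growth balance): in a population closed to
  migration, the entry rate into the open age segment ``x+`` equals the
  growth rate plus the death rate of that segment. With deaths
  under-registered by a factor ``C`` and censuses enumerated with
  coverages ``k1, k2``, the points

      entry_rate(x) - r(x+)   versus   registered_death_rate(x+)

  lie on a straight line with slope ``sqrt(k1*k2)/C`` and intercept
  ``ln(k1/k2)/t``. Fitting the line yields completeness (1/slope) and the
  relative census coverage ``k1/k2 = exp(intercept*t)``.

* **SEG** (synthetic extinct generations, Bennett-Horiuchi): the number
  of persons reaching exact age ``x`` per year equals future deaths to
  the cohort, discounted by age-specific growth; accumulating registered
  deaths up the age axis reconstructs a synthetic population whose ratio
  to the census population estimates ``C`` directly.

* **GGB-SEG**: the second census is first rescaled by the relative
  coverage ``k1/k2`` estimated by GGB, removing the differential-coverage
  bias that plain SEG cannot absorb, and SEG is then run on the adjusted
  inputs.

Discretization follows the classical five-year-group scheme: the flow of
persons turning exact age x per year is estimated as
``(5N(x-5) + 5N(x)) / 10`` on geometric-mean census counts, person-years
above x as ``t * sqrt(N1(x+) * N2(x+))``, and segment growth rates as
``ln(N2/N1)/t``. All completeness values are reported as estimated, never
clipped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import AgeGrid, RateSchedule

__all__ = [
    "CensusPair",
    "DeathSeries",
    "IntercensalInputs",
    "GGBFit",
    "SEGResult",
    "CompletenessEstimate",
    "intercensal_inputs",
    "ggb_fit",
    "ggbseg_estimate",
    "seg_estimate",
    "trim_sweep",
    "adjust_rates",
    "enumerate_windows",
    "DDMModel",
    "DDMResults",
]


# ---------------------------------------------------------------------------
# input containers


@dataclass
class CensusPair:
    """Two dated census count vectors for one sex on a shared grid."""

    grid: AgeGrid
    sex: str
    date1: float
    date2: float
    N1: np.ndarray
    N2: np.ndarray

    def __post_init__(self):
        self.N1 = np.asarray(self.N1, dtype=float)
        self.N2 = np.asarray(self.N2, dtype=float)
        for name, v in (("N1", self.N1), ("N2", self.N2)):
            if v.shape != (self.grid.n_groups,):
                raise ValueError(f"{name} must have one count per age group")
            if np.any(v < 0):
                raise ValueError(f"{name} contains negative counts")
        t = self.date2 - self.date1
        if not 1.0 < t < 30.0:
            raise ValueError(f"intercensal length t={t:.2f} outside (1, 30) years")

    @property
    def t(self) -> float:
        """Intercensal length in years."""
        return self.date2 - self.date1


@dataclass
class DeathSeries:
    """Registered deaths by age group over a full intercensal period."""

    grid: AgeGrid
    sex: str
    period_start: float
    period_end: float
    D_star: np.ndarray

    def __post_init__(self):
        self.D_star = np.asarray(self.D_star, dtype=float)
        if self.D_star.shape != (self.grid.n_groups,):
            raise ValueError("D_star must have one count per age group")
        if np.any(self.D_star < 0):
            raise ValueError("registered deaths must be non-negative")
        if self.period_end <= self.period_start:
            raise ValueError("period end must follow period start")

    def matches(self, cp: CensusPair, tol: float = 0.51) -> bool:
        return (
            abs(self.period_start - cp.date1) <= tol
            and abs(self.period_end - cp.date2) <= tol
        )


@dataclass
class IntercensalInputs:
    """Derived quantities feeding both GGB and SEG.

    All age-indexed arrays other than the per-group ones are defined on
    ``ages`` = group starts from the second group up to and including the
    open age (the cumulation ages at which the birthday flow is
    estimable).
    """

    grid: AgeGrid
    t: float
    ages: np.ndarray          # cumulation ages x
    r_plus: np.ndarray        # growth rate of N(x+), per year
    PY_plus: np.ndarray       # person-years lived above x over the period
    entry_rate: np.ndarray    # estimated birthday flow at x / mid-period N(x+)
    death_rate: np.ndarray    # D*(x+) / PY(x+)
    birthdays: np.ndarray     # geometric-mean flow of persons turning x, per yr
    r_group: np.ndarray       # per-group growth rates (one per grid group)
    N_geo: np.ndarray         # geometric-mean census count per group
    D_plus: np.ndarray        # cumulated registered deaths above x


def intercensal_inputs(cp: CensusPair, ds: DeathSeries) -> IntercensalInputs:
    """Growth rates, person-years and GGB regression coordinates.

    Raises if any cumulated census segment above the first cumulation age
    is empty (the log growth rate would be undefined there).
    """
    if ds.grid != cp.grid:
        raise ValueError("census pair and death series use different grids")
    grid = cp.grid
    t = cp.t
    starts = grid.starts

    N1_plus = np.cumsum(cp.N1[::-1])[::-1]
    N2_plus = np.cumsum(cp.N2[::-1])[::-1]
    D_plus_full = np.cumsum(ds.D_star[::-1])[::-1]

    for i, age in enumerate(starts):
        if (N1_plus[i] <= 0 or N2_plus[i] <= 0) and age >= starts[1]:
            raise ValueError(f"empty cumulated census population above age {age}")

    # cumulation ages: second group start .. open age
    sl = slice(1, None)
    ages = starts[sl]
    r_plus = np.log(N2_plus[sl] / N1_plus[sl]) / t
    PY_plus = t * np.sqrt(N1_plus[sl] * N2_plus[sl])

    N_geo = np.sqrt(cp.N1 * cp.N2)
    # persons turning exact age x per year ~ (5N(x-5) + 5N(x)) / 10
    birthdays = (N_geo[:-1] + N_geo[1:]) / 10.0
    entry_rate = t * birthdays / PY_plus
    death_rate = D_plus_full[sl] / PY_plus

    with np.errstate(divide="ignore", invalid="ignore"):
        r_group = np.log(cp.N2 / cp.N1) / t

    return IntercensalInputs(
        grid=grid, t=t, ages=ages, r_plus=r_plus, PY_plus=PY_plus,
        entry_rate=entry_rate, death_rate=death_rate, birthdays=birthdays,
        r_group=r_group, N_geo=N_geo, D_plus=D_plus_full,
    )


# ---------------------------------------------------------------------------
# GGB


@dataclass
class GGBFit:
    """A fitted growth-balance line over one age window.

    ``C = 1/slope`` is death-registration completeness relative to the
    geometric-mean census coverage; ``rel_coverage = exp(intercept * t)``
    estimates the relative census coverage k1/k2. A non-positive slope or
    an under-determined fit is flagged ``degenerate`` and leaves ``C``
    as NaN rather than clipping.
    """

    window: tuple
    slope: float
    intercept: float
    t: float
    n_points: int
    residuals: np.ndarray
    degenerate: bool = False

    @property
    def C(self) -> float:
        if self.degenerate:
            return float("nan")
        return 1.0 / self.slope

    @property
    def rel_coverage(self) -> float:
        if self.degenerate:
            return float("nan")
        return float(np.exp(self.intercept * self.t))


def _window_mask(ages: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return (ages >= lo) & (ages <= hi - 5)


def _fit_line(x: np.ndarray, y: np.ndarray, method: str):
    if method == "ols":
        slope, intercept = np.polyfit(x, y, 1)
    elif method == "orthogonal":
        # total least squares: smallest right singular vector of centered data
        xm, ym = x.mean(), y.mean()
        u = np.c_[x - xm, y - ym]
        _, _, vt = np.linalg.svd(u, full_matrices=False)
        nx, ny = vt[-1]
        if ny == 0:
            return float("inf"), float("nan")
        slope = -nx / ny
        intercept = ym - slope * xm
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return float(slope), float(intercept)


def ggb_fit(ii: IntercensalInputs, window, fit: str = "ols") -> GGBFit:
    """Fit the growth-balance line over cumulation ages in ``window``.

    Points are ``(registered death rate above x, entry rate - r(x+))`` for
    window start <= x <= window end - 5. Requires at least 3 points.
    """
    mask = _window_mask(ii.ages, window)
    x = ii.death_rate[mask]
    y = ii.entry_rate[mask] - ii.r_plus[mask]
    n = int(mask.sum())
    if n < 3:
        return GGBFit(tuple(window), float("nan"), float("nan"), ii.t, n,
                      np.array([]), degenerate=True)
    slope, intercept = _fit_line(x, y, fit)
    resid = y - (slope * x + intercept)
    degenerate = not np.isfinite(slope) or slope <= 0
    return GGBFit(tuple(window), slope, intercept, ii.t, n, resid,
                  degenerate=degenerate)


# ---------------------------------------------------------------------------
# SEG


@dataclass
class SEGResult:
    """Synthetic-extinct-generations result over one age window.

    ``N_hat`` holds the reconstructed flow of persons turning each exact
    age per year (indexed by ``ages``); ``ratios`` compares it with the
    census-based flow at the same exact ages; ``C`` aggregates the ratios
    over the window.
    """

    window: tuple
    ages: np.ndarray
    N_hat: np.ndarray
    ratios: np.ndarray
    C: float
    open_closure_e: float


def _seg_nhat(ii: IntercensalInputs, ds: DeathSeries, open_e: float) -> np.ndarray:
    """Bennett-Horiuchi recursion for the synthetic birthday flow.

    Returns N_hat at every cumulation age of ``ii.ages`` (second group
    start .. open age). The open interval is seeded with
    ``D(open)/t * [exp(r*e) - (r*e)^2 / 6]``.
    """
    grid = ii.grid
    d_yr = ds.D_star / ii.t          # annual deaths per group
    r_grp = ii.r_group
    n = grid.n_groups

    N_hat = np.zeros(n)              # indexed like grid groups; entry i = flow at starts[i]
    r_open = ii.r_plus[-1]
    z = r_open * open_e
    N_hat[-1] = d_yr[-1] * (np.exp(z) - z * z / 6.0)
    for i in range(n - 2, 0, -1):
        N_hat[i] = N_hat[i + 1] * np.exp(5.0 * r_grp[i]) + d_yr[i] * np.exp(
            2.5 * r_grp[i]
        )
    return N_hat[1:]


def _iterate_open_e(ii: IntercensalInputs, ds: DeathSeries, window,
                    C0: float, max_iter: int = 25, tol: float = 1e-8):
    """Fixed-point iteration for the open-interval life expectancy.

    The open-age expectancy under a constant-hazard tail is
    ``e = C / M_unadj(open)`` where ``M_unadj`` is the unadjusted open-group
    death rate; C is re-estimated from the resulting SEG ratios until the
    pair (e, C) is self-consistent.
    """
    M_open_unadj = ds.D_star[-1] / (ii.t * ii.N_geo[-1])
    if M_open_unadj <= 0:
        raise ValueError("zero deaths in the open interval; cannot close SEG")
    C = C0
    ratios_mask = _window_mask(ii.ages, window)
    if not ratios_mask.any():
        raise ValueError(f"window {window} selects no exact ages on this grid")
    e = C / M_open_unadj
    for _ in range(max_iter):
        N_hat = _seg_nhat(ii, ds, e)
        ratios = N_hat / ii.birthdays
        C_new = float(np.mean(ratios[ratios_mask]))
        e_new = C_new / M_open_unadj
        if abs(e_new - e) < tol:
            e = e_new
            break
        e = e_new
    return e


def seg_estimate(
    ii: IntercensalInputs,
    cp: CensusPair,
    ds: DeathSeries,
    window,
    open_closure_e: float | None = None,
    aggregate: str = "mean",
) -> SEGResult:
    """SEG completeness over one age window.

    The synthetic flow of persons turning exact age x is accumulated from
    registered deaths above x, each group discounted by its own growth
    rate; ratios to the census birthday flow are averaged over exact ages
    in the window (arithmetic mean by default, ``aggregate="median"``
    optional).

    ``open_closure_e`` fixes the open-interval life expectancy used by the
    Bennett-Horiuchi closure; when omitted it is obtained from the data by
    completeness fixed-point iteration.
    """
    if open_closure_e is None:
        open_e = _iterate_open_e(ii, ds, window, C0=1.0)
    else:
        open_e = float(open_closure_e)
        if ds.D_star[-1] <= 0:
            raise ValueError("zero deaths in the open interval; cannot close SEG")
    N_hat = _seg_nhat(ii, ds, open_e)
    ratios = N_hat / ii.birthdays
    mask = _window_mask(ii.ages, window)
    if not mask.any():
        raise ValueError(f"window {window} selects no exact ages on this grid")
    agg = np.median if aggregate == "median" else np.mean
    C = float(agg(ratios[mask]))
    return SEGResult(tuple(window), ii.ages.copy(), N_hat, ratios, C, open_e)


def ggbseg_estimate(
    ii: IntercensalInputs,
    cp: CensusPair,
    ds: DeathSeries,
    window,
    fit: str = "ols",
    open_closure_e: float | None = None,
    aggregate: str = "mean",
    adjust_census: int = 2,
) -> SEGResult:
    """Combined GGB-SEG: SEG on coverage-adjusted census counts.

    The GGB intercept over the same window estimates relative census
    coverage k1/k2; the second census is multiplied by it (equivalently
    the first census may be divided, ``adjust_census=1``), the intercensal
    inputs are recomputed, and SEG is run on the adjusted data with its
    closure iteration seeded at the GGB completeness.
    """
    g = ggb_fit(ii, window, fit=fit)
    if g.degenerate:
        raise ValueError(
            f"degenerate GGB fit on window {tuple(window)} "
            f"(slope={g.slope!r}, n={g.n_points}); cannot adjust census"
        )
    rel = g.rel_coverage
    if adjust_census == 2:
        cp_adj = CensusPair(cp.grid, cp.sex, cp.date1, cp.date2, cp.N1, cp.N2 * rel)
    elif adjust_census == 1:
        cp_adj = CensusPair(cp.grid, cp.sex, cp.date1, cp.date2, cp.N1 / rel, cp.N2)
    else:
        raise ValueError("adjust_census must be 1 or 2")
    ii_adj = intercensal_inputs(cp_adj, ds)
    if open_closure_e is None:
        open_e = _iterate_open_e(ii_adj, ds, window, C0=g.C)
    else:
        open_e = float(open_closure_e)
    return seg_estimate(ii_adj, cp_adj, ds, window,
                        open_closure_e=open_e, aggregate=aggregate)


# ---------------------------------------------------------------------------
# trim sweep


def enumerate_windows(grid: AgeGrid, min_groups: int = 8, low: int = 15,
                      high_end: int = 80) -> list:
    """All contiguous windows of >= min_groups five-year groups in [low, high_end)."""
    starts = [a for a in grid.start_ages if low <= a and a + 5 <= high_end]
    if not starts:
        raise ValueError("grid does not cover the requested trim range")
    n = len(starts)
    out = []
    for L in range(min_groups, n + 1):
        for i in range(n - L + 1):
            out.append((starts[i], starts[i] + 5 * L))
    if not out:
        raise ValueError(
            f"no window of {min_groups}+ groups fits in [{low}, {high_end})"
        )
    return out


@dataclass
class CompletenessEstimate:
    """Per-method completeness summarized over trim windows."""

    method: str
    sex: str
    mean: float
    min: float
    max: float
    per_window: list = field(repr=False)
    n_degenerate: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.method, self.sex, w[0], w[1], c) for w, c in self.per_window],
            columns=["method", "sex", "window_low", "window_high", "C"],
        )


def trim_sweep(
    method: str,
    ii: IntercensalInputs,
    cp: CensusPair,
    ds: DeathSeries,
    min_groups: int = 8,
    low: int = 15,
    high_end: int = 80,
    fit: str = "ols",
    exclude: list | None = None,
    **kwargs,
) -> CompletenessEstimate:
    """Age-trim sensitivity sweep for one method.

    Enumerates every contiguous window of at least ``min_groups`` adjacent
    five-year groups between ``low`` and ``high_end``, estimates
    completeness on each, and reports the mean together with the min-max
    sensitivity interval. ``exclude`` removes specific ``(low, high)``
    windows from the enumeration.
    """
    windows = enumerate_windows(ii.grid, min_groups, low, high_end)
    if exclude:
        excl = {tuple(w) for w in exclude}
        windows = [w for w in windows if w not in excl]
    per_window = []
    n_deg = 0
    for w in windows:
        if method == "ggb":
            g = ggb_fit(ii, w, fit=fit)
            c = g.C
            if g.degenerate:
                n_deg += 1
        elif method == "seg":
            c = seg_estimate(ii, cp, ds, w, **kwargs).C
        elif method == "ggbseg":
            c = ggbseg_estimate(ii, cp, ds, w, fit=fit, **kwargs).C
        else:
            raise ValueError(f"unknown method {method!r}")
        per_window.append((w, c))
    vals = np.array([c for _, c in per_window], dtype=float)
    ok = vals[np.isfinite(vals)]
    if len(ok) == 0:
        raise ValueError(f"all {len(windows)} windows degenerate for {method}")
    return CompletenessEstimate(
        method=method, sex=cp.sex, mean=float(ok.mean()), min=float(ok.min()),
        max=float(ok.max()), per_window=per_window, n_degenerate=n_deg,
    )


# ---------------------------------------------------------------------------
# completeness-adjusted rates


def adjust_rates(ds: DeathSeries, cp: CensusPair, C: float) -> RateSchedule:
    """Death rates adjusted for registration completeness.

    M(x) = D*(x) / (C * PY(x)) with per-group person-years
    PY(x) = t * sqrt(N1(x) * N2(x)).
    """
    if not np.isfinite(C) or C <= 0:
        raise ValueError(f"completeness must be positive, got {C!r}")
    PY = cp.t * np.sqrt(cp.N1 * cp.N2)
    if np.any(PY <= 0):
        bad = cp.grid.starts[PY <= 0]
        raise ValueError(f"zero census population in groups starting {bad.tolist()}")
    M = ds.D_star / (C * PY)
    return RateSchedule(grid=cp.grid, sex=ds.sex, M=M)


# ---------------------------------------------------------------------------
# model / results front-end


class DDMModel:
    """Death-distribution-method model for one sex.

    Parameters
    ----------
    census_pair : CensusPair
        Two dated census count vectors on a shared five-year grid.
    death_series : DeathSeries
        Registered deaths by age over the intercensal period.

    Examples
    --------
    >>> model = DDMModel(cp, ds)           # doctest: +SKIP
    >>> res = model.fit(method="ggbseg")   # doctest: +SKIP
    >>> res.completeness.mean              # doctest: +SKIP
    """

    def __init__(self, census_pair: CensusPair, death_series: DeathSeries):
        if not death_series.matches(census_pair):
            raise ValueError("death series period does not match the census dates")
        self.census_pair = census_pair
        self.death_series = death_series
        self.inputs = intercensal_inputs(census_pair, death_series)

    @classmethod
    def from_dataframes(cls, census: pd.DataFrame, deaths: pd.DataFrame,
                        sex: str) -> "DDMModel":
        """Build from tidy census / deaths tables (see :mod:`crvsddm.io`)."""
        from .io import census_pair_from_frame, death_series_from_frame

        cp = census_pair_from_frame(census, sex)
        ds = death_series_from_frame(deaths, sex, grid=cp.grid)
        return cls(cp, ds)

    def fit(self, method: str = "ggbseg", min_groups: int = 8, low: int = 15,
            high_end: int = 80, fit: str = "ols", **kwargs) -> "DDMResults":
        """Run the trim sweep for one method and package the results."""
        est = trim_sweep(method, self.inputs, self.census_pair,
                         self.death_series, min_groups=min_groups, low=low,
                         high_end=high_end, fit=fit, **kwargs)
        full_window = (low, high_end)
        return DDMResults(self, method, est, full_window, fit)


class DDMResults:
    """Completeness estimates with the trim-sensitivity interval.

    ``completeness`` carries the mean/min/max over windows;
    ``adjusted_rates`` and ``life_table`` divide the registered rates by
    the chosen completeness value and push them through the abridged life
    table.
    """

    def __init__(self, model: DDMModel, method: str,
                 completeness: CompletenessEstimate, full_window, fit: str):
        self.model = model
        self.method = method
        self.completeness = completeness
        self.full_window = tuple(full_window)
        self.fit_method = fit

    def which_C(self, which: str = "mean") -> float:
        try:
            return float(getattr(self.completeness, which))
        except AttributeError:
            raise ValueError("which must be one of 'mean', 'min', 'max'") from None

    def adjusted_rates(self, which: str = "mean") -> RateSchedule:
        return adjust_rates(self.model.death_series, self.model.census_pair,
                            self.which_C(which))

    def unadjusted_rates(self) -> RateSchedule:
        return adjust_rates(self.model.death_series, self.model.census_pair, 1.0)

    def life_table(self, which: str = "mean", radix: float = 100_000.0):
        from .lifetable import build_life_table

        return build_life_table(self.adjusted_rates(which), radix=radix)

    def summary(self) -> str:
        from .pipeline import format_estimate

        c = self.completeness
        lines = [
            "Death distribution method results",
            "=" * 46,
            f"method:            {self.method.upper()}",
            f"sex:               {c.sex}",
            f"fit:               {self.fit_method}",
            f"windows swept:     {len(c.per_window)}"
            + (f" ({c.n_degenerate} degenerate)" if c.n_degenerate else ""),
            f"completeness:      {format_estimate(c.mean, c.min, c.max)}",
        ]
        return "\n".join(lines)
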