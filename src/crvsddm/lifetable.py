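"""Abridged period life tables and the adult summary measures 35q15 / e15.

The recursion is the standard abridged one: interval death probabilities
nqx are obtained from rates via ``q = n*M / (1 + (n - a)*M)``, survivors
``l`` cascade down, person-years ``nLx = n*l(x+n) + a*d``, and the open
interval is closed with ``L = l/M`` (equivalently ``e(open) = 1/M(open)``,
a constant-hazard tail). The two adult measures the package reports are
the probability of dying between exact ages 15 and 50 (35q15) and the
remaining life expectancy at exact age 15 (e15), plus the female-minus-male
gap in e15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import AgeGrid, RateSchedule

__all__ = [
    "LifeTable",
    "rate_to_prob",
    "build_life_table",
    "prob_15_50",
    "sexgap_e15",
]

DEFAULT_RADIX = 100_000.0


def rate_to_prob(M, n, a):
    """Convert a central death rate to an interval death probability.

    q = n*M / (1 + (n - a)*M), clipped to [0, 1].

    Parameters
    ----------
    M : float or array
        Central death rate per person-year, >= 0.
    n : float
        Interval width in years.
    a : float or array
        Mean years lived in the interval by those dying in it, in (0, n].
    """
    M = np.asarray(M, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(M < 0) or not np.all(np.isfinite(M)):
        raise ValueError("M must be finite and non-negative")
    if np.any(a <= 0) or np.any(a > n):
        raise ValueError(f"a must lie in (0, {n}]")
    q = n * M / (1.0 + (n - a) * M)
    return np.clip(q, 0.0, 1.0)


@dataclass
class LifeTable:
    """Abridged life table columns on an :class:`AgeGrid`.

    Exact-age columns (l, T, e) are indexed by the interval start age;
    intervals are half-open ``[x, x+5)``.
    """

    grid: AgeGrid
    sex: str
    M: np.ndarray
    a: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    radix: float = DEFAULT_RADIX

    def to_frame(self) -> pd.DataFrame:
        n = np.r_[np.full(len(self.grid.start_ages), 5.0), np.nan]
        return pd.DataFrame(
            {
                "age": self.grid.starts,
                "n": n,
                "M": self.M,
                "a": self.a,
                "q": self.q,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def l_at(self, age: int) -> float:
        """Survivors at exact ``age`` (a group start)."""
        return float(self.l[self.grid.index_of(age)])

    def e_at(self, age: int) -> float:
        """Remaining life expectancy at exact ``age`` (a group start)."""
        return float(self.e[self.grid.index_of(age)])


def build_life_table(rates: RateSchedule, radix: float = DEFAULT_RADIX) -> LifeTable:
    """Build an abridged life table from an age-specific rate schedule.

    The open interval is closed assuming a constant hazard equal to the
    open-interval rate: L(open) = l(open)/M(open), hence
    e(open) = 1/M(open). M(open) must therefore be positive.
    """
    if radix <= 0:
        raise ValueError("radix must be positive")
    grid = rates.grid
    M, a = rates.M, rates.a
    if M[-1] <= 0:
        raise ValueError("open-interval rate must be positive to close the table")

    k = grid.n_groups
    q = np.empty(k)
    q[:-1] = rate_to_prob(M[:-1], 5.0, a[:-1])
    q[-1] = 1.0

    l = np.empty(k)
    l[0] = radix
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = np.empty(k)
    d[:-1] = l[:-1] - l[1:]
    d[-1] = l[-1]

    L = np.empty(k)
    L[:-1] = 5.0 * l[1:] + a[:-1] * d[:-1]
    L[-1] = l[-1] / M[-1]

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return LifeTable(grid=grid, sex=rates.sex, M=M.copy(), a=a.copy(), q=q,
                     l=l, d=d, L=L, T=T, e=e, radix=float(radix))


def prob_15_50(lt: LifeTable) -> float:
    """Probability of dying between exact ages 15 and 50: 1 - l(50)/l(15)."""
    l15 = lt.l_at(15)
    l50 = lt.l_at(50)
    if l15 <= 0:
        raise ValueError("no survivors at age 15; 35q15 undefined")
    return 1.0 - l50 / l15


def sexgap_e15(female: LifeTable, male: LifeTable) -> float:
    """Female-minus-male gap in life expectancy at exact age 15 (years).

    Positive values mean a female advantage.
    """
    if female.grid != male.grid:
        raise ValueError("life tables are on different age grids")
    return female.e_at(15) - male.e_at(15)
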