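"""Five-year age grids and age-specific rate schedules.

An :class:`AgeGrid` is an ordered sequence of closed five-year age groups
``[x, x+5)`` followed by exactly one open-ended terminal group ``open_age+``.
All estimators in this package (death distribution methods, life tables,
survey tabulations) share this representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AgeGrid", "RateSchedule", "FEMALE", "MALE"]

FEMALE = "female"
MALE = "male"

_STEP = 5


@dataclass(frozen=True)
class AgeGrid:
    """Ordered 5-year age groups with one open terminal interval.

    Parameters
    ----------
    start_ages : tuple of int
        Start ages of the closed groups, strictly increasing in steps of 5.
    open_age : int
        Start of the open-ended terminal group; must equal the end of the
        last closed group.
    """

    start_ages: tuple
    open_age: int

    def __post_init__(self):
        starts = tuple(int(a) for a in self.start_ages)
        object.__setattr__(self, "start_ages", starts)
        if len(starts) == 0:
            raise ValueError("grid needs at least one closed age group")
        diffs = np.diff(starts)
        if len(diffs) and not np.all(diffs == _STEP):
            raise ValueError("closed start ages must increase in steps of 5")
        if self.open_age != starts[-1] + _STEP:
            raise ValueError(
                f"open_age must be {starts[-1] + _STEP}, got {self.open_age}"
            )

    @classmethod
    def standard(cls, first: int = 0, open_age: int = 80) -> "AgeGrid":
        """Grid ``first, first+5, ... , open_age+`` (default 0-4 ... 75-79, 80+)."""
        return cls(tuple(range(first, open_age, _STEP)), open_age)

    @property
    def starts(self) -> np.ndarray:
        """Start ages of all groups, the open group last."""
        return np.asarray(self.start_ages + (self.open_age,))

    @property
    def n_groups(self) -> int:
        return len(self.start_ages) + 1

    @property
    def widths(self) -> np.ndarray:
        """Interval widths; the open interval is reported as ``inf``."""
        return np.r_[np.full(len(self.start_ages), float(_STEP)), np.inf]

    def index_of(self, age: int) -> int:
        """Index of the group starting at exact ``age``."""
        starts = self.starts
        hits = np.flatnonzero(starts == age)
        if len(hits) == 0:
            raise KeyError(f"age {age} is not a group start of this grid")
        return int(hits[0])

    def labels(self) -> list:
        out = [f"{a}-{a + _STEP - 1}" for a in self.start_ages]
        out.append(f"{self.open_age}+")
        return out

    def restrict(self, low: int, high: int) -> "AgeGrid":
        """Closed-group subgrid covering ``[low, high)`` with open group ``high+``."""
        keep = tuple(a for a in self.start_ages if low <= a < high)
        if not keep:
            raise ValueError("restriction leaves no closed groups")
        return AgeGrid(keep, keep[-1] + _STEP)


@dataclass
class RateSchedule:
    """Age-specific death rates M(x) (per person-year) on an :class:`AgeGrid`.

    ``a`` is the mean years lived in the interval by those dying in it
    (nax); defaults to half the interval width for closed groups. The open
    group's ``a`` is unused by the life-table recursion (the open interval
    is closed with L = l/M).
    """

    grid: AgeGrid
    sex: str
    M: np.ndarray
    a: np.ndarray = field(default=None)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (self.grid.n_groups,):
            raise ValueError("M must have one value per age group")
        if np.any(self.M < 0) or not np.all(np.isfinite(self.M)):
            raise ValueError("death rates must be finite and non-negative")
        if self.a is None:
            self.a = np.full(self.grid.n_groups, _STEP / 2.0)
        self.a = np.asarray(self.a, dtype=float)
        closed = self.a[:-1]
        if np.any(closed <= 0) or np.any(closed > _STEP):
            raise ValueError("a must lie in (0, interval width] for closed groups")
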