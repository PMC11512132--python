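"""Monthly and weekday profiles of decomposed series, and the CV.

The seasonal trend is summarized from the slow component: for each calendar
month, the mean and SD of the slow daily values pooled across years.  The
weekly trend is summarized from the fast component: for each ISO weekday
(Monday first), the mean and SD of the fast daily values re-centered by the
grand mean of the normalized series, so that the profile sits on the same
~1 scale as the monthly one (the fast component itself is zero-mean).
Weekday profiles can be restricted to a month subset, e.g. the South Korean
school-vacation months {January, February, August} versus the school
months.

The coefficient of variation (CV = sigma/mu) contrasts the relative size of
seasonal or weekly variation across groups.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .decompose import DecomposedSeries

__all__ = [
    "MONTH_LABELS",
    "WEEKDAY_LABELS",
    "VACATION_MONTHS",
    "ProfileError",
    "ProfileAggregate",
    "monthly_profile",
    "weekday_profile",
    "coefficient_of_variation",
]

logger = logging.getLogger(__name__)

MONTH_LABELS = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)
#: ISO order, Monday first.
WEEKDAY_LABELS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
#: South Korean school vacation months: January, February, August.
VACATION_MONTHS = frozenset({1, 2, 8})


class ProfileError(ValueError):
    """Invalid input to a profile aggregation."""


@dataclasses.dataclass(frozen=True)
class ProfileAggregate:
    """Per-level (month or weekday) mean/SD/count summary for one group."""

    group_label: str
    level_kind: str  # "month" | "weekday"
    levels: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    month_subset: frozenset[int] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd, "n": self.n},
            index=pd.Index(self.levels, name=self.level_kind),
        )

    def __getitem__(self, level: str) -> tuple[float, float, int]:
        i = self.levels.index(level)
        return float(self.mean[i]), float(self.sd[i]), int(self.n[i])


def _aggregate(
    values: np.ndarray,
    level_index: np.ndarray,
    labels: Sequence[str],
    ddof: int,
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray, np.ndarray]:
    levels, means, sds, counts = [], [], [], []
    for i, label in enumerate(labels):
        sel = values[level_index == i]
        if sel.size == 0:
            logger.warning("level %s has no days in range; omitted", label)
            continue
        levels.append(label)
        means.append(float(sel.mean()))
        sds.append(float(sel.std(ddof=ddof)) if sel.size > ddof else 0.0)
        counts.append(int(sel.size))
    return tuple(levels), np.array(means), np.array(sds), np.array(counts, dtype=int)


def monthly_profile(decomposed: DecomposedSeries, ddof: int = 1) -> ProfileAggregate:
    """Per-calendar-month mean/SD of the slow component, pooled across years.

    The slow component retains the DC term, so means are interpretable on
    the ~1 scale of a median-normalized series.  Requires at least one full
    year of coverage so every month is represented.
    """
    if decomposed.n_days < 365:
        raise ProfileError("monthly profile requires at least one full year of data")
    month_idx = decomposed.dates.month.to_numpy() - 1
    levels, mean, sd, n = _aggregate(decomposed.slow, month_idx, MONTH_LABELS, ddof)
    return ProfileAggregate(
        group_label=decomposed.group_label,
        level_kind="month",
        levels=levels,
        mean=mean,
        sd=sd,
        n=n,
    )


def weekday_profile(
    decomposed: DecomposedSeries,
    month_subset: Iterable[int] | None = None,
    offset: bool = True,
    ddof: int = 1,
) -> ProfileAggregate:
    """Per-ISO-weekday mean/SD of the fast component.

    Parameters
    ----------
    decomposed
        Band-split series.
    month_subset
        Optional set of month numbers (1-12) to restrict to, e.g.
        :data:`VACATION_MONTHS` or its complement.
    offset
        If True (default) the zero-mean fast component is re-centered by the
        grand mean of the normalized series (slow + fast), putting the
        profile on the ~1 scale; if False the raw zero-mean values are used.
    ddof
        SD denominator convention; 1 (sample SD) by default.
    """
    if month_subset is not None:
        month_subset = frozenset(int(m) for m in month_subset)
        if not month_subset:
            raise ProfileError("month_subset must be nonempty when given")
        if not month_subset <= set(range(1, 13)):
            raise ProfileError(f"month_subset outside 1..12: {sorted(month_subset)}")
    values = decomposed.fast
    if offset:
        values = values + float((decomposed.slow + decomposed.fast).mean())
    dates = decomposed.dates
    keep = np.ones(decomposed.n_days, dtype=bool)
    if month_subset is not None:
        keep = np.isin(dates.month.to_numpy(), sorted(month_subset))
        if not keep.any():
            raise ProfileError(
                f"no days fall in months {sorted(month_subset)} within the series range"
            )
    weekday_idx = dates.weekday.to_numpy()[keep]  # Monday=0 .. Sunday=6
    levels, mean, sd, n = _aggregate(values[keep], weekday_idx, WEEKDAY_LABELS, ddof)
    return ProfileAggregate(
        group_label=decomposed.group_label,
        level_kind="weekday",
        levels=levels,
        mean=mean,
        sd=sd,
        n=n,
        month_subset=month_subset,
    )


def coefficient_of_variation(values: Sequence[float], ddof: int = 1) -> float:
    """SD divided by mean (sigma/mu) of a sequence of daily values.

    Raises
    ------
    ProfileError
        If the sequence is empty or its mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ProfileError("coefficient of variation of an empty sequence")
    mu = float(v.mean())
    if mu == 0.0:
        raise ProfileError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=ddof)) / mu
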