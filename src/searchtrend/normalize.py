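"""Per-calendar-year median normalization of daily search-volume series.

Relative search-volume exports scale each group so that its single peak day
equals 100, which makes levels incomparable across groups.  Dividing each
day by its calendar year's median (computed within the group) yields a
unitless series in which a value above 1 means "above that year's typical
day".  Years are then concatenated into one contiguous normalized series.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging

import numpy as np
import pandas as pd

from .io_panel import RawDailySeries

__all__ = ["DegenerateYearError", "NormalizedSeries", "annual_median_normalize"]

logger = logging.getLogger(__name__)


class DegenerateYearError(ValueError):
    """A calendar year's median (or mean) is zero; normalization undefined."""


@dataclasses.dataclass(frozen=True)
class NormalizedSeries:
    """Daily unitless ratios against the per-year group median.

    Invariant: for every calendar year fully contained in the range, the
    median of that year's values is 1 (to numerical precision).
    """

    group_label: str
    start_date: dt.date
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a nonempty 1-d sequence")
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("normalized values must be finite and >= 0")

    @property
    def n_days(self) -> int:
        return int(self.values.size)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


def _days_in_year(year: int) -> int:
    return (dt.date(year + 1, 1, 1) - dt.date(year, 1, 1)).days


def annual_median_normalize(
    series: RawDailySeries, method: str = "median"
) -> NormalizedSeries:
    """Divide each day's value by its calendar year's center within the group.

    Parameters
    ----------
    series
        Raw export-scale daily series.
    method
        ``"median"`` (default) divides by each year's median; ``"mean"`` is a
        sensitivity variant dividing by each year's mean.

    Returns
    -------
    NormalizedSeries
        One contiguous series; years are normalized independently and merged.

    Raises
    ------
    DegenerateYearError
        If a year's median (or mean) is zero.

    Notes
    -----
    Even-length year subsets use the midpoint-of-two-central-values median.
    A year only partially covered by the input is normalized by the median of
    its available days, with a logged warning.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"method must be 'median' or 'mean', got {method!r}")
    years = series.dates.year
    values = series.values
    out = np.empty_like(values)
    for year in np.unique(years):
        mask = years == year
        n = int(mask.sum())
        if n < _days_in_year(int(year)):
            logger.warning(
                "group %s: year %d has only %d day(s); normalizing by the "
                "median of the available days",
                series.group_label,
                year,
                n,
            )
        center = float(np.median(values[mask]) if method == "median" else np.mean(values[mask]))
        if center <= 0.0:
            raise DegenerateYearError(
                f"group {series.group_label!r}: {method} of year {year} is {center:g}"
            )
        out[mask] = values[mask] / center
    return NormalizedSeries(
        group_label=series.group_label, start_date=series.start_date, values=out
    )
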