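"""Fourier band-splitting of a normalized daily series at 1 cycle per week.

The discrete Fourier transform of the full multi-year series is split at a
cutoff frequency (default 1/7 cycles per day): bins strictly below the
cutoff, including the DC term, form the *slow* (seasonal) component; bins at
or above the cutoff form the *fast* (weekly) component.  The boundary bin is
assigned to fast, so an exact 7-day cycle is entirely weekly structure.

No windowing, tapering, zero-padding or truncation is applied: the plain
transform of the series as given, at its native length (1461 days for four
calendar years including a leap year), is used.  Spectral leakage from
components that are not commensurate with the series length is accepted.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .normalize import NormalizedSeries

__all__ = [
    "DEFAULT_CUTOFF",
    "DecompositionError",
    "DecomposedSeries",
    "bandsplit_values",
    "fft_bandsplit",
    "reconstruct",
]

#: 1 cycle per week, in cycles per day.
DEFAULT_CUTOFF = 1.0 / 7.0
#: Shortest series for which a weekly/seasonal split is meaningful.
MIN_LENGTH = 14


class DecompositionError(ValueError):
    """Invalid input to the band-split (length, cutoff, or inconsistency)."""


@dataclasses.dataclass(frozen=True)
class DecomposedSeries:
    """Paired slow/fast daily components summing to the normalized input.

    ``slow`` carries all frequencies below ``cutoff`` including the mean
    (DC) term; ``fast`` carries frequencies at or above ``cutoff`` and has
    zero mean over the full series.
    """

    group_label: str
    start_date: dt.date
    slow: np.ndarray
    fast: np.ndarray
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        slow = np.asarray(self.slow, dtype=float)
        fast = np.asarray(self.fast, dtype=float)
        object.__setattr__(self, "slow", slow)
        object.__setattr__(self, "fast", fast)
        if slow.shape != fast.shape or slow.ndim != 1:
            raise DecompositionError("slow and fast must be 1-d arrays of equal length")

    @property
    def n_days(self) -> int:
        return int(self.slow.size)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


def bandsplit_values(
    values: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> tuple[np.ndarray, np.ndarray]:
    """Split a real daily sequence into (slow, fast) at ``cutoff`` cycles/day.

    Frequency bin k of an n-point transform has frequency k/n cycles/day;
    bins with k/n < cutoff (including k=0) are slow, the rest fast.  The
    fast component is obtained as the residual ``values - slow``, which
    makes additivity exact in floating point.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < MIN_LENGTH:
        raise DecompositionError(
            f"series must be 1-d with at least {MIN_LENGTH} days, got shape {v.shape}"
        )
    if not (0.0 < cutoff <= 0.5):
        raise DecompositionError(f"cutoff must be in (0, 0.5] cycles/day, got {cutoff!r}")
    n = v.size
    spectrum = np.fft.rfft(v)
    k = np.arange(spectrum.size)
    # boundary bin (k/n == cutoff) belongs to fast; 1e-9 absorbs fp error in k/n
    fast_bins = k >= cutoff * n - 1e-9
    slow = np.fft.irfft(np.where(fast_bins, 0.0, spectrum), n)
    fast = v - slow
    return slow, fast


def fft_bandsplit(
    series: NormalizedSeries, cutoff: float = DEFAULT_CUTOFF
) -> DecomposedSeries:
    """Band-split a normalized series into seasonal and weekly components.

    Raises
    ------
    DecompositionError
        If the series is shorter than 14 days or the cutoff is outside
        (0, 0.5] cycles/day.
    """
    slow, fast = bandsplit_values(series.values, cutoff)
    return DecomposedSeries(
        group_label=series.group_label,
        start_date=series.start_date,
        slow=slow,
        fast=fast,
        cutoff=cutoff,
    )


def reconstruct(decomposed: DecomposedSeries) -> NormalizedSeries:
    """Invert the split: element-wise slow + fast with the original metadata."""
    if decomposed.n_days == 0:
        raise DecompositionError("cannot reconstruct a zero-length decomposition")
    return NormalizedSeries(
        group_label=decomposed.group_label,
        start_date=decomposed.start_date,
        values=decomposed.slow + decomposed.fast,
    )
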