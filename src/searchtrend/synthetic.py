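"""Synthetic daily search-volume panels with known structure.

Emulates an age-stratified daily relative-search-volume export: each
group's latent daily volume is a positive baseline modulated
multiplicatively by a per-month seasonal factor, a per-ISO-weekday factor,
and log-normal noise; the series is then rescaled so its maximum over the
period equals 100 (the export convention) and rounded to 2 decimals.

Because both the max-to-100 rescale and the downstream per-year median
normalization are scale-free, the baseline never affects pipeline outputs;
the month and weekday multipliers are the recoverable ground truth used in
parameter-recovery tests.

Default shapes mirror the published seasonal and weekly profiles of South
Korean insomnia searches over 2016-2019: an adolescent-like group with a
strong vacation-month (Jan/Feb/Aug) surge and a Monday peak, and an
adult-like group with mild seasonality; log-scale noise SD 0.1.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .io_panel import Panel, RawDailySeries

__all__ = [
    "SyntheticConfigError",
    "GroupSpec",
    "SyntheticConfig",
    "adolescent_group",
    "adult_group",
    "flat_group",
    "default_config",
    "generate_panel",
    "recovery_report",
]

DEFAULT_START = dt.date(2016, 1, 1)
DEFAULT_END = dt.date(2019, 12, 31)

# Month (Jan..Dec) and weekday (Mon..Sun) multiplier shapes emulating the
# published adolescent and adult profiles.
ADOLESCENT_MONTH_SHAPE = (2.52, 1.84, 0.92, 0.71, 0.83, 1.03, 1.16, 1.64, 0.93, 1.05, 0.96, 1.11)
ADOLESCENT_WEEKDAY_SHAPE = (1.33, 1.06, 1.01, 0.97, 0.85, 0.78, 1.01)
ADULT_MONTH_SHAPE = (1.16, 1.09, 1.00, 0.97, 1.01, 1.05, 0.99, 0.95, 0.97, 0.98, 0.89, 0.94)
ADULT_WEEKDAY_SHAPE = (1.14, 1.16, 1.13, 1.08, 0.97, 0.75, 0.78)

DEFAULT_NOISE_SIGMA = 0.1


class SyntheticConfigError(ValueError):
    """Invalid synthetic-panel configuration."""


@dataclasses.dataclass(frozen=True)
class GroupSpec:
    """Latent structure for one synthetic group.

    ``month_multipliers`` are indexed Jan..Dec, ``weekday_multipliers``
    Mon..Sun (ISO); all must be positive.  ``noise_sigma`` is the SD of the
    log-normal day-to-day noise (log scale).  ``trend_per_year`` adds an
    optional linear secular trend (relative change per year; 0 = off).
    """

    label: str
    baseline: float = 1.0
    month_multipliers: tuple[float, ...] = (1.0,) * 12
    weekday_multipliers: tuple[float, ...] = (1.0,) * 7
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    trend_per_year: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise SyntheticConfigError(f"{self.label!r}: baseline must be > 0")
        if len(self.month_multipliers) != 12 or min(self.month_multipliers) <= 0:
            raise SyntheticConfigError(f"{self.label!r}: need 12 positive month multipliers")
        if len(self.weekday_multipliers) != 7 or min(self.weekday_multipliers) <= 0:
            raise SyntheticConfigError(f"{self.label!r}: need 7 positive weekday multipliers")
        if self.noise_sigma < 0:
            raise SyntheticConfigError(f"{self.label!r}: noise_sigma must be >= 0")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Full panel configuration: period, groups, seed and export scaling."""

    groups: tuple[GroupSpec, ...]
    start: dt.date = DEFAULT_START
    end: dt.date = DEFAULT_END
    seed: int = 0
    rescale_max: float = 100.0
    decimals: int = 2

    def __post_init__(self) -> None:
        if not self.groups:
            raise SyntheticConfigError("at least one group is required")
        if len({g.label for g in self.groups}) != len(self.groups):
            raise SyntheticConfigError("group labels must be unique")
        if self.end < self.start:
            raise SyntheticConfigError("end date before start date")
        if self.rescale_max <= 0:
            raise SyntheticConfigError("rescale_max must be > 0")


def adolescent_group(
    label: str = "13-18", noise_sigma: float = DEFAULT_NOISE_SIGMA
) -> GroupSpec:
    """Group with the adolescent-like vacation surge and Monday peak."""
    return GroupSpec(
        label=label,
        month_multipliers=ADOLESCENT_MONTH_SHAPE,
        weekday_multipliers=ADOLESCENT_WEEKDAY_SHAPE,
        noise_sigma=noise_sigma,
    )


def adult_group(label: str = "19-59", noise_sigma: float = DEFAULT_NOISE_SIGMA) -> GroupSpec:
    """Group with the adult-like mild seasonality and weekend dip."""
    return GroupSpec(
        label=label,
        month_multipliers=ADULT_MONTH_SHAPE,
        weekday_multipliers=ADULT_WEEKDAY_SHAPE,
        noise_sigma=noise_sigma,
    )


def flat_group(label: str, noise_sigma: float = DEFAULT_NOISE_SIGMA) -> GroupSpec:
    """Group with no seasonal or weekly structure (null model)."""
    return GroupSpec(label=label, noise_sigma=noise_sigma)


def default_config(seed: int = 0) -> SyntheticConfig:
    """Adolescent-like vs adult-like two-group panel, 2016-2019."""
    return SyntheticConfig(groups=(adolescent_group(), adult_group()), seed=seed)


def generate_panel(config: SyntheticConfig) -> Panel:
    """Generate a deterministic export-style panel from a config.

    For group g on day d the latent volume is
    ``baseline * month_mult[month(d)] * weekday_mult[weekday(d)]
    * (1 + trend_per_year * years_since_start) * exp(noise_sigma * z_d)``
    with z_d standard normal from one seeded generator (groups drawn in
    listed order).  Each group is rescaled to max = ``rescale_max`` and
    rounded to ``decimals`` places.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start, config.end, freq="D")
    n = len(dates)
    month_idx = dates.month.to_numpy() - 1
    weekday_idx = dates.weekday.to_numpy()
    years_elapsed = np.arange(n) / 365.25
    series = {}
    for g in config.groups:
        latent = (
            g.baseline
            * np.asarray(g.month_multipliers)[month_idx]
            * np.asarray(g.weekday_multipliers)[weekday_idx]
            * (1.0 + g.trend_per_year * years_elapsed)
        )
        if np.any(latent <= 0):
            raise SyntheticConfigError(f"{g.label!r}: trend drives the latent volume <= 0")
        if g.noise_sigma > 0:
            latent = latent * np.exp(g.noise_sigma * rng.standard_normal(n))
        else:
            rng.standard_normal(n)  # keep the stream aligned across configs
        scaled = latent / latent.max() * config.rescale_max
        values = np.round(scaled, config.decimals)
        series[g.label] = RawDailySeries(
            group_label=g.label, start_date=config.start, values=values
        )
    return Panel(series_by_group=series)


def recovery_report(config: SyntheticConfig, profile) -> dict[str, float]:
    """Absolute error of a recovered profile against the injected multipliers.

    Both the estimated level means and the injected multipliers are reduced
    to ratios against their respective level medians (profiles are only
    identified up to a common scale), and the per-level absolute difference
    of those ratios is returned.
    """
    spec = next((g for g in config.groups if g.label == profile.group_label), None)
    if spec is None:
        raise SyntheticConfigError(
            f"profile group {profile.group_label!r} not present in the config"
        )
    if profile.level_kind == "month":
        injected = np.asarray(spec.month_multipliers)
        all_levels = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
                      "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
    elif profile.level_kind == "weekday":
        injected = np.asarray(spec.weekday_multipliers)
        all_levels = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
    else:
        raise SyntheticConfigError(f"unknown level kind {profile.level_kind!r}")
    present = [all_levels.index(l) for l in profile.levels]
    inj = injected[present]
    est_ratio = profile.mean / np.median(profile.mean)
    inj_ratio = inj / np.median(inj)
    return {
        level: float(abs(e - i))
        for level, e, i in zip(profile.levels, est_ratio, inj_ratio)
    }
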