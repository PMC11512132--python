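"""Group x time interaction tests and per-level pairwise contrasts.

The analysis treats daily component values as exchangeable replicates
within each (group, month) or (group, weekday) cell — no autocorrelation
modelling — mirroring the surveillance-analysis convention this pipeline
reproduces.  An omnibus two-way fixed-effects ANOVA screens for a
group x time interaction; per-level group contrasts then use the Wilcoxon
rank-sum test (default) or Welch's t, with Bonferroni correction over the
whole table of contrasts as one family.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "StatsError",
    "DesignError",
    "ComparisonResult",
    "InteractionResult",
    "two_way_anova_interaction",
    "wilcoxon_rank_sum",
    "welch_t",
    "bonferroni",
    "tukey_hsd",
]

#: Largest combined sample size for which the rank-sum test enumerates
#: all label assignments exactly instead of using the normal approximation.
EXACT_THRESHOLD = 12


class StatsError(ValueError):
    """Invalid input to a statistical test."""


class DesignError(StatsError):
    """The factorial design is degenerate (empty cell, too few levels)."""


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """One pairwise contrast: statistic, raw and multiplicity-corrected p."""

    pair: tuple[str, str]
    statistic_name: str  # "wilcoxon_rank_sum" | "welch_t" | "tukey_hsd"
    statistic: float
    p_raw: float
    p_corrected: float
    n_a: int
    n_b: int
    level: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= self.p_corrected <= 1.0 + 1e-12):
            raise StatsError(
                f"invalid p-values: raw={self.p_raw}, corrected={self.p_corrected}"
            )

    def with_correction(self, family_size: int) -> "ComparisonResult":
        """Bonferroni-adjust: corrected p = min(1, family_size * raw p)."""
        if family_size < 1:
            raise StatsError(f"family_size must be >= 1, got {family_size}")
        return dataclasses.replace(
            self, p_corrected=min(1.0, family_size * self.p_raw)
        )


@dataclasses.dataclass(frozen=True)
class InteractionResult:
    """Omnibus interaction test outcome for a group x time factorial."""

    factors: tuple[str, str]
    F: float
    df: tuple[int, int]
    p: float


def two_way_anova_interaction(
    values: Sequence[float],
    group_factor: Sequence[str],
    time_factor: Sequence[str],
    cell_means: bool = False,
) -> InteractionResult:
    """Fixed-effects two-way ANOVA, returning the group x time interaction.

    Sums of squares are Type II (identical to Type I for the interaction,
    which always enters last).  With ``cell_means=True`` a variant analysis
    is run instead: observations are first averaged within each
    (group, time) cell and a one-way ANOVA of the group factor on the cell
    means is reported — a coarser screen whose denominator df is
    (cells - groups) rather than the daily-replicate residual df.

    Raises
    ------
    DesignError
        For fewer than 2 groups or 2 time levels, or an empty / singleton
        cell (named in the message).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_factor, dtype=object)
    t = np.asarray(time_factor, dtype=object)
    if not (y.shape == g.shape == t.shape) or y.ndim != 1:
        raise StatsError("values, group_factor and time_factor must be equal-length 1-d")
    groups, times = np.unique(g), np.unique(t)
    if len(groups) < 2 or len(times) < 2:
        raise DesignError(
            f"need >= 2 groups and >= 2 time levels, got {len(groups)} x {len(times)}"
        )
    for gi, ti in itertools.product(groups, times):
        n_cell = int(np.sum((g == gi) & (t == ti)))
        if n_cell < 2:
            raise DesignError(f"cell ({gi}, {ti}) has {n_cell} observation(s); need >= 2")
    if cell_means:
        means_by_group = [
            [float(y[(g == gi) & (t == ti)].mean()) for ti in times] for gi in groups
        ]
        F, p = scipy.stats.f_oneway(*means_by_group)
        df_num = len(groups) - 1
        df_den = len(groups) * len(times) - len(groups)
        return InteractionResult(
            factors=("group", "time"), F=float(F), df=(df_num, df_den), p=float(p)
        )
    frame = pd.DataFrame({"y": y, "g": g.astype(str), "t": t.astype(str)})
    fit = ols("y ~ C(g) * C(t)", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(g):C(t)"]
    return InteractionResult(
        factors=("group", "time"),
        F=float(row["F"]),
        df=(int(row["df"]), int(table.loc["Residual", "df"])),
        p=float(row["PR(>F)"]),
    )


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of label assignments.

    Works with midranks, so it remains valid under ties (the permutation
    null conditions on the observed pooled values).
    """
    n = ranks.size
    mu = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mu)
    offset = n_a * (n_a + 1) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    level: str | None = None,
    pair: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    For combined sample sizes up to 12 the permutation null is enumerated
    exactly (valid under ties); above that, the normal approximation with
    tie-corrected variance and continuity correction is used.  The reported
    statistic is the Mann-Whitney U of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(combined)
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    if a.size + b.size <= EXACT_THRESHOLD:
        p = _exact_rank_sum_p(ranks, a.size, u_a)
    elif np.ptp(combined) == 0.0:
        p = 1.0  # every observation tied: the null variance is zero
    else:
        res = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    return ComparisonResult(
        pair=pair,
        statistic_name="wilcoxon_rank_sum",
        statistic=u_a,
        p_raw=p,
        p_corrected=p,
        n_a=int(a.size),
        n_b=int(b.size),
        level=level,
    )


def welch_t(
    a: Sequence[float],
    b: Sequence[float],
    level: str | None = None,
    pair: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Welch's unequal-variance t test (Satterthwaite df), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs >= 2 values for Welch's t")
    if a.var(ddof=1) + b.var(ddof=1) == 0.0:
        raise StatsError("both samples have zero variance; t statistic undefined")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        pair=pair,
        statistic_name="welch_t",
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_corrected=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        level=level,
    )


def bonferroni(p_values: Sequence[float], family_size: int) -> np.ndarray:
    """Bonferroni correction: each p becomes min(1, family_size * p)."""
    p = np.asarray(p_values, dtype=float)
    if family_size < p.size:
        raise StatsError(
            f"family_size {family_size} smaller than number of p-values {p.size}"
        )
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return np.minimum(1.0, family_size * p)


def tukey_hsd(
    values: Sequence[float], level_factor: Sequence[str]
) -> list[ComparisonResult]:
    """All pairwise level contrasts with Tukey HSD adjusted p-values.

    One-way layout (e.g. months within a single group).  The reported
    statistic is the difference of level means; ``p_corrected`` is the
    studentized-range adjusted p and ``p_raw`` the unadjusted pooled-
    variance t p-value for the same contrast.
    """
    y = np.asarray(values, dtype=float)
    lv = np.asarray(level_factor, dtype=object)
    if y.shape != lv.shape or y.ndim != 1:
        raise StatsError("values and level_factor must be equal-length 1-d")
    levels = list(dict.fromkeys(lv))  # stable order of appearance
    if len(levels) < 3:
        raise DesignError(f"Tukey HSD needs >= 3 levels, got {len(levels)}")
    samples = [y[lv == l] for l in levels]
    for l, s in zip(levels, samples):
        if s.size < 2:
            raise DesignError(f"level {l!r} has {s.size} observation(s); need >= 2")
    res = scipy.stats.tukey_hsd(*samples)
    df_err = sum(s.size for s in samples) - len(levels)
    mse = sum(float(((s - s.mean()) ** 2).sum()) for s in samples) / df_err
    out = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        diff = float(samples[i].mean() - samples[j].mean())
        se = math.sqrt(mse * (1.0 / samples[i].size + 1.0 / samples[j].size))
        p_unadj = 2.0 * float(scipy.stats.t.sf(abs(diff) / se, df_err)) if se > 0 else 1.0
        p_adj = float(res.pvalue[i, j])
        out.append(
            ComparisonResult(
                pair=(str(levels[i]), str(levels[j])),
                statistic_name="tukey_hsd",
                statistic=diff,
                p_raw=min(p_unadj, p_adj),
                p_corrected=p_adj,
                n_a=int(samples[i].size),
                n_b=int(samples[j].size),
            )
        )
    return out
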