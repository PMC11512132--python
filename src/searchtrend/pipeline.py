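"""End-to-end pipeline: load/simulate -> normalize -> decompose -> profile -> compare.

Every convention the analysis leaves open (median vs mean normalization, SD
denominator, CV granularity, the weekday-profile re-centering, Bonferroni
family size) surfaces as a :class:`PipelineConfig` field with its default,
and every run logs the flags in effect and writes a JSON manifest with a
hash of the configuration, so any table can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import itertools
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import aggregate, decompose, groupstats, io_panel, normalize, synthetic

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

KNOWN_TESTS = ("anova", "wilcoxon", "ttest", "tukey")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``input_path`` (a panel CSV) or ``synthetic`` (a
    generator config) must be given.  ``family_size`` is either ``"auto"``
    (the whole contrast table is one family: levels x group pairs) or an
    explicit integer.
    """

    input_path: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    normalization: str = "median"  # "median" | "mean"
    cutoff_days: float = 7.0
    vacation_months: frozenset[int] = aggregate.VACATION_MONTHS
    tests: tuple[str, ...] = ("anova", "wilcoxon")
    family_size: int | str = "auto"
    sd_ddof: int = 1
    cv_granularity: str = "daily"  # "daily" | "level_means"
    weekday_offset: bool = True
    output_dir: str = "searchtrend_out"
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path or synthetic must be set")
        if self.cutoff_days < 2:
            raise ValueError(f"cutoff_days must be >= 2, got {self.cutoff_days}")
        months = frozenset(int(m) for m in self.vacation_months)
        object.__setattr__(self, "vacation_months", months)
        if not months <= set(range(1, 13)):
            raise ValueError(f"vacation_months outside 1..12: {sorted(months)}")
        unknown = set(self.tests) - set(KNOWN_TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}; choose from {KNOWN_TESTS}")
        if self.normalization not in ("median", "mean"):
            raise ValueError("normalization must be 'median' or 'mean'")
        if self.cv_granularity not in ("daily", "level_means"):
            raise ValueError("cv_granularity must be 'daily' or 'level_means'")
        if isinstance(self.family_size, str) and self.family_size != "auto":
            raise ValueError("family_size must be 'auto' or an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Build a config from a YAML mapping mirroring the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            if syn.get("default"):
                syn_cfg = synthetic.default_config(seed=int(syn.get("seed", 0)))
            else:
                groups = tuple(
                    synthetic.GroupSpec(
                        label=str(g["label"]),
                        baseline=float(g.get("baseline", 1.0)),
                        month_multipliers=tuple(g.get("month_multipliers", [1.0] * 12)),
                        weekday_multipliers=tuple(g.get("weekday_multipliers", [1.0] * 7)),
                        noise_sigma=float(g.get("noise_sigma", synthetic.DEFAULT_NOISE_SIGMA)),
                        trend_per_year=float(g.get("trend_per_year", 0.0)),
                    )
                    for g in syn["groups"]
                )
                syn_cfg = synthetic.SyntheticConfig(
                    groups=groups,
                    start=_as_date(syn.get("start", synthetic.DEFAULT_START)),
                    end=_as_date(syn.get("end", synthetic.DEFAULT_END)),
                    seed=int(syn.get("seed", 0)),
                    rescale_max=float(syn.get("rescale_max", 100.0)),
                    decimals=int(syn.get("decimals", 2)),
                )
            raw["synthetic"] = syn_cfg
        for key in ("vacation_months", "tests"):
            if key in raw:
                raw[key] = tuple(raw[key]) if key == "tests" else frozenset(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["vacation_months"] = sorted(self.vacation_months)
        d["tests"] = list(self.tests)
        if self.synthetic is not None:
            s = dataclasses.asdict(self.synthetic)
            s["start"] = self.synthetic.start.isoformat()
            s["end"] = self.synthetic.end.isoformat()
            s["groups"] = [dataclasses.asdict(g) for g in self.synthetic.groups]
            d["synthetic"] = s
        return d


def _as_date(value: Any) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclasses.dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    config: PipelineConfig
    panel: io_panel.Panel
    normalized: dict[str, normalize.NormalizedSeries]
    decomposed: dict[str, decompose.DecomposedSeries]
    monthly_profiles: dict[str, aggregate.ProfileAggregate]
    weekday_profiles: dict[str, dict[str, aggregate.ProfileAggregate]]  # stratum -> group
    interactions: dict[str, groupstats.InteractionResult]
    contrasts: list[groupstats.ComparisonResult]
    cv: pd.DataFrame
    output_paths: dict[str, Path]


def _profile_table(profiles: dict[str, aggregate.ProfileAggregate]) -> pd.DataFrame:
    """Wide table: one row per level, per-group mean/sd/n columns."""
    frames = {}
    for label, prof in profiles.items():
        f = prof.to_frame()
        f.columns = [f"{label}_{c}" for c in f.columns]
        frames[label] = f
    return pd.concat(frames.values(), axis=1)


def _component_samples(
    dec: decompose.DecomposedSeries,
    kind: str,
    offset: bool,
) -> pd.Series:
    """Daily analysis values with a month or weekday level index."""
    if kind == "month":
        values = dec.slow
        idx = [aggregate.MONTH_LABELS[m - 1] for m in dec.dates.month]
    else:
        values = dec.fast
        if offset:
            values = values + float((dec.slow + dec.fast).mean())
        idx = [aggregate.WEEKDAY_LABELS[w] for w in dec.dates.weekday]
    return pd.Series(values, index=idx)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all output tables.

    Writes into ``config.output_dir``: ``normalized.csv``, ``slow.csv``,
    ``fast.csv``, ``monthly_profile.csv``, ``weekday_profile.csv`` (overall
    plus vacation/school strata), ``stats.csv``, ``cv.csv`` and
    ``manifest.json``.  Stage failures propagate with the stage name
    prefixed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline flags: normalization=%s cutoff_days=%g vacation_months=%s "
        "tests=%s family_size=%s sd_ddof=%d cv_granularity=%s weekday_offset=%s",
        config.normalization, config.cutoff_days, sorted(config.vacation_months),
        config.tests, config.family_size, config.sd_ddof, config.cv_granularity,
        config.weekday_offset,
    )

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise type(exc)(f"[{name}] {exc}") from exc
        return deco

    # --- load / simulate -------------------------------------------------
    if config.input_path is not None:
        panel = stage("load")(lambda: io_panel.read_panel_csv(config.input_path))
    else:
        syn = config.synthetic
        if config.seed is not None:
            syn = dataclasses.replace(syn, seed=config.seed)
        panel = stage("simulate")(lambda: synthetic.generate_panel(syn))

    # --- normalize --------------------------------------------------------
    normalized = stage("normalize")(lambda: {
        label: normalize.annual_median_normalize(s, method=config.normalization)
        for label, s in panel.series_by_group.items()
    })

    # --- decompose --------------------------------------------------------
    cutoff = 1.0 / config.cutoff_days
    decomposed = stage("decompose")(lambda: {
        label: decompose.fft_bandsplit(ns, cutoff=cutoff)
        for label, ns in normalized.items()
    })

    # --- profiles ---------------------------------------------------------
    school_months = frozenset(range(1, 13)) - config.vacation_months
    monthly = stage("profile")(lambda: {
        label: aggregate.monthly_profile(d, ddof=config.sd_ddof)
        for label, d in decomposed.items()
    })
    weekday = stage("profile")(lambda: {
        "overall": {
            label: aggregate.weekday_profile(
                d, offset=config.weekday_offset, ddof=config.sd_ddof
            )
            for label, d in decomposed.items()
        },
        "vacation": {
            label: aggregate.weekday_profile(
                d, month_subset=config.vacation_months,
                offset=config.weekday_offset, ddof=config.sd_ddof,
            )
            for label, d in decomposed.items()
        },
        "school": {
            label: aggregate.weekday_profile(
                d, month_subset=school_months,
                offset=config.weekday_offset, ddof=config.sd_ddof,
            )
            for label, d in decomposed.items()
        },
    })

    # --- statistics -------------------------------------------------------
    interactions, contrasts = stage("compare")(
        lambda: _run_stats(decomposed, config)
    )

    # --- coefficients of variation ---------------------------------------
    cv = stage("cv")(lambda: _cv_table(decomposed, monthly, weekday["overall"], config))

    # --- outputs ----------------------------------------------------------
    paths = stage("write")(lambda: _write_outputs(
        out_dir, config, panel, normalized, decomposed, monthly, weekday,
        interactions, contrasts, cv,
    ))

    return PipelineResult(
        config=config,
        panel=panel,
        normalized=normalized,
        decomposed=decomposed,
        monthly_profiles=monthly,
        weekday_profiles=weekday,
        interactions=interactions,
        contrasts=contrasts,
        cv=cv,
        output_paths=paths,
    )


def _run_stats(decomposed, config):
    labels = list(decomposed)
    pairs = list(itertools.combinations(labels, 2))
    interactions: dict[str, groupstats.InteractionResult] = {}
    contrasts: list[groupstats.ComparisonResult] = []
    for kind, time_name in (("month", "month"), ("weekday", "day")):
        samples = {
            label: _component_samples(decomposed[label], kind, config.weekday_offset)
            for label in labels
        }
        levels = aggregate.MONTH_LABELS if kind == "month" else aggregate.WEEKDAY_LABELS
        if "anova" in config.tests and len(labels) >= 2:
            y, gf, tf = [], [], []
            for label, s in samples.items():
                y.extend(s.to_numpy())
                gf.extend([label] * len(s))
                tf.extend(s.index)
            interactions[f"group_x_{time_name}"] = groupstats.two_way_anova_interaction(
                y, gf, tf
            )
        family = (
            len(levels) * len(pairs)
            if config.family_size == "auto"
            else int(config.family_size)
        )
        for test_name in config.tests:
            if test_name not in ("wilcoxon", "ttest"):
                continue
            fn = groupstats.wilcoxon_rank_sum if test_name == "wilcoxon" else groupstats.welch_t
            for level in levels:
                for a_label, b_label in pairs:
                    a = samples[a_label][samples[a_label].index == level].to_numpy()
                    b = samples[b_label][samples[b_label].index == level].to_numpy()
                    res = fn(a, b, level=level, pair=(a_label, b_label))
                    contrasts.append(res.with_correction(family))
        if "tukey" in config.tests:
            for label, s in samples.items():
                for res in groupstats.tukey_hsd(s.to_numpy(), s.index.to_numpy()):
                    contrasts.append(
                        dataclasses.replace(res, level=f"{time_name}:{label}")
                    )
    return interactions, contrasts


def _cv_table(decomposed, monthly, weekday_overall, config):
    rows = []
    for label, dec in decomposed.items():
        if config.cv_granularity == "daily":
            seasonal_values = dec.slow
            # fast is zero-mean; CV needs the re-centered (~1 scale) values
            grand = float((dec.slow + dec.fast).mean())
            weekly_values = dec.fast + grand
        else:
            seasonal_values = monthly[label].mean
            weekly_values = weekday_overall[label].mean
        rows.append(
            {
                "group": label,
                "seasonal_cv": aggregate.coefficient_of_variation(
                    seasonal_values, ddof=config.sd_ddof
                ),
                "weekly_cv": aggregate.coefficient_of_variation(
                    weekly_values, ddof=config.sd_ddof
                ),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _write_outputs(
    out_dir, config, panel, normalized, decomposed, monthly, weekday,
    interactions, contrasts, cv,
):
    paths: dict[str, Path] = {}
    dates = next(iter(normalized.values())).dates

    def table(columns: dict[str, Any]) -> pd.DataFrame:
        return pd.DataFrame(columns, index=dates)

    paths["normalized"] = out_dir / "normalized.csv"
    io_panel.write_table_csv(
        table({g: ns.values for g, ns in normalized.items()}), paths["normalized"]
    )
    paths["slow"] = out_dir / "slow.csv"
    io_panel.write_table_csv(
        table({g: d.slow for g, d in decomposed.items()}), paths["slow"]
    )
    paths["fast"] = out_dir / "fast.csv"
    io_panel.write_table_csv(
        table({g: d.fast for g, d in decomposed.items()}), paths["fast"]
    )

    paths["monthly_profile"] = out_dir / "monthly_profile.csv"
    _profile_table(monthly).to_csv(paths["monthly_profile"], float_format="%.6g")

    frames = []
    for stratum, profs in weekday.items():
        f = _profile_table(profs)
        f.insert(0, "stratum", stratum)
        frames.append(f)
    paths["weekday_profile"] = out_dir / "weekday_profile.csv"
    pd.concat(frames).to_csv(paths["weekday_profile"], float_format="%.6g")

    stat_rows = [
        {
            "test": "two_way_anova",
            "scope": name,
            "level": "",
            "pair": "x".join(res.factors),
            "statistic": res.F,
            "df": f"{res.df[0]},{res.df[1]}",
            "p_raw": res.p,
            "p_corrected": res.p,
            "n_a": "",
            "n_b": "",
        }
        for name, res in interactions.items()
    ] + [
        {
            "test": c.statistic_name,
            "scope": "",
            "level": c.level or "",
            "pair": f"{c.pair[0]} vs {c.pair[1]}",
            "statistic": c.statistic,
            "df": "",
            "p_raw": c.p_raw,
            "p_corrected": c.p_corrected,
            "n_a": c.n_a,
            "n_b": c.n_b,
        }
        for c in contrasts
    ]
    paths["stats"] = out_dir / "stats.csv"
    pd.DataFrame(stat_rows).to_csv(paths["stats"], index=False, float_format="%.6g")

    paths["cv"] = out_dir / "cv.csv"
    cv.to_csv(paths["cv"], float_format="%.6g")

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    try:
        pkg_version = version("searchtrend")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        pkg_version = "unknown"
    manifest = {
        "package": "searchtrend",
        "version": pkg_version,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {k: str(v) for k, v in paths.items()},
        "groups": list(panel.groups),
        "period": [panel.period[0].isoformat(), panel.period[1].isoformat()],
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
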