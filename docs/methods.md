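# Methods

## Data model

The input is a *panel*: for each group g, a daily series v_g(t) on the
relative 0–100 export scale (the group's maximum over the loaded period is
scaled to 100), on a strictly contiguous daily calendar. The reader treats
a group maximum far from 100 as a warning, not an error, so truncated
subsets of an export remain loadable. Dates are plain calendar dates; the
day boundary is taken exactly as exported, with no time-zone handling.

## Normalization

Because the export scale is anchored to a single peak day and applied per
group, raw levels are not comparable across groups. Each group is
therefore normalized by its own calendar-year median:

x_g(t) = v_g(t) / median{ v_g(s) : year(s) = year(t) },

and years are concatenated. x_g(t) > 1 means "above that year's typical
day" for that group. The median is the robust choice of center for a
heavy-tailed nonnegative count proxy; a per-year **mean** variant is
available (`method="mean"`) as a sensitivity check, since the two
conventions genuinely differ on skewed data (the grand mean of a
median-normalized series is typically 1.1–1.2, not 1). Even-length
year subsets use the midpoint-of-the-two-central-values median. A year
only partially covered by the input is normalized by the median of its
available days, with a logged warning; a year whose center is zero raises
an error naming the year.

## Spectral decomposition

The merged multi-year normalized series (length N; 1461 days for
2016–2019) is split by one discrete Fourier transform — not per year —
at the cutoff f_c = 1/7 cycles/day:

- **slow** (seasonal): bins with k/N < f_c, including the DC bin;
- **fast** (weekly): bins with k/N ≥ f_c. The boundary bin, exactly one
  cycle per week, belongs to fast.

The inverse transform of each half gives real components with
slow + fast = x exactly (fast is computed as the residual x − slow, making
additivity exact in floating point) and mean(fast) = 0 over the full
series. Because the bands are disjoint, the mean-centered energy
partitions (Parseval): Σ(x−x̄)² = Σ(slow−x̄)² + Σ fast².

No window, taper, zero-padding or truncation is applied; the transform
runs at the native (non-power-of-two) length. The cost is spectral
leakage for components not commensurate with N. This matters for the
weekly lines themselves: 1461 days is 208 weeks + 5 days, so a strictly
7-periodic pattern leaks part of its energy below the cutoff. Measured on
a noise-free weekday-only panel, the leaked error in the recovered
weekday profile is ≤ 0.042 (on the ~1 scale); at a whole number of weeks
it drops to ~0.003. Recovery tolerances (0.05 noise-free, 0.1 at noise SD
0.1) cover this leakage.

## Profiles and the coefficient of variation

- **Monthly profile**: mean, sample SD and day count of the slow
  component for each calendar month, pooled across years (February pools
  4×28+1 days over 2016–2019). Slow retains the DC term, so means sit on
  the ~1 normalized scale.
- **Weekday profile**: the same for the fast component by ISO weekday
  (Monday first), optionally restricted to a month subset. The vacation
  stratification uses the South Korean school calendar: {January,
  February, August} vs the remaining nine months. Since fast is
  zero-mean, the profile is re-centered by the grand mean of the
  normalized series (default `offset=True`), which puts weekday means on
  the same ~1 scale as the monthly table; the raw zero-mean variant is a
  flag. Note the grand mean of a median-normalized skewed series exceeds
  1, so with multiplicative weekly structure the offset profile's peak
  (e.g. Monday ≈ 1.5 on the default synthetic panel) sits above the
  injected multiplier; recovery comparisons are therefore made on ratios
  to the level median, which are offset- and scale-free.
- **CV**: σ/μ with sample SD (ddof=1) by default; a population-SD flag
  exists. The seasonal CV is computed over the *daily* slow-component
  values of the full series and the weekly CV over the daily re-centered
  fast values (`cv_granularity="daily"`); computing instead over the 12
  monthly or 7 weekday means is exposed as `"level_means"`. The daily
  convention is the default because, on the published group profiles, it
  is the convention that reproduces the reported seasonal CVs
  (≈0.48 adolescents, ≈0.13 adults) when back-computed from the printed
  monthly means and SDs.

## Group comparison

Daily component values are treated as exchangeable replicates within each
(group, level) cell — the convention of the analysis this package
reproduces; no autocorrelation-aware inference is attempted (see
Limitations).

- **Omnibus**: fixed-effects two-way ANOVA with interaction, fitted by
  OLS; Type II sums of squares (equal to Type I for the interaction term,
  which enters last; the monthly layout is only slightly unbalanced
  through month lengths). Monthly tests use the slow component, weekday
  tests the re-centered fast component (the offset does not change F).
  A `cell_means=True` variant first averages each cell and runs a one-way
  group ANOVA on the cell means, giving the coarser df = (groups−1,
  cells−groups) seen in some published reports (F with df 1,22 for
  2 groups × 12 months); the daily-replicate interaction is the default.
- **Pairwise contrasts**: Wilcoxon rank-sum with midranks; for combined
  n ≤ 12 the permutation null is enumerated exactly (valid under ties),
  otherwise the normal approximation with tie-corrected variance and
  continuity correction is used. Welch's t (Satterthwaite df) and Tukey
  HSD (studentized range, one-way within a group) are also provided.
- **Multiplicity**: Bonferroni, corrected p = min(1, m·p). The default
  family is the whole printed table — levels × group pairs, e.g. m = 36
  for 12 months × 3 pairs of 3 groups, m = 21 for the weekday table — the
  most conservative reading; m is configurable.

## Synthetic panels

The generator emulates the export: for group g on day t the latent volume
is baseline × month_mult[month(t)] × weekday_mult[weekday(t)] ×
(1 + trend·years(t)) × exp(σ·z_t), z_t ~ N(0,1) from one seeded
generator; the series is rescaled to max = 100 and rounded to 2 decimals.
Noise is multiplicative (log-normal) because search counts are nonnegative
and heavy-tailed, which keeps median normalization meaningful. Defaults
are the study conditions the package targets: 2016-01-01..2019-12-31
(1461 days), two groups whose month/weekday multiplier shapes follow the
published adolescent and adult profiles, σ = 0.1 (a day-to-day jitter of
~10%, comparable to the within-month SDs of the published tables), no
secular trend. Baseline and rescaling are provably irrelevant downstream
(both operations are scale-free), which the tests verify.

What the generator does **not** emulate: integer quantization at low
volumes, moving holidays (Lunar New Year, Chuseok), exam-period spikes,
secular growth in platform usage, and day-to-day autocorrelation in the
noise (z_t is white). Passing recovery tests therefore show that the
pipeline inverts its own generative assumptions — multiplicative
calendar structure plus white multiplicative noise — not that real
exports satisfy those assumptions.

## Numerical choices

- Band membership is decided on integer bin indices (k ≥ f_c·N − 1e−9),
  so the boundary bin lands in fast regardless of floating-point
  representation of 1/7.
- CSV round-trips format floats at 12 significant digits (≤ 1e−9
  round-trip error on the 0–100 scale); the calendar check enumerates the
  expected daily range and names the first missing or duplicated date.
- The exact rank-sum path enumerates all C(n, n_a) assignments of the
  pooled midranks (≤ 924 at the n ≤ 12 threshold) and counts
  |U − μ| ≥ |U_obs − μ| with a 1e−12 tolerance; at the threshold the
  asymptotic path agrees with the exact one to better than 0.01.
- Rank-sum with every pooled observation tied returns p = 1 (the null
  variance is zero); Welch's t on two zero-variance samples raises
  instead, since t is undefined there.
- Pipeline runs are deterministic given (config, seed); outputs are
  byte-identical across repeated runs, and a JSON manifest records the
  config and its SHA-256.

## Limitations

- **Null calibration of the monthly contrasts.** Low-pass filtering
  leaves the slow component autocorrelated over ~1 week, so a month of
  ~120 daily values carries roughly 17 effective observations. The rank
  test assumes exchangeable days and is therefore anticonservative on the
  monthly table: on flat-vs-flat synthetic panels (σ = 0.1, 4 years) a
  monthly contrast spuriously survives whole-table Bonferroni at
  α = 0.05 in roughly 26 of 30 seeds, while the weekday table (high-pass
  values, nearly white) is approximately calibrated (2 of 30). The
  package reproduces the source convention deliberately; corrected
  monthly p-values should be read as descriptive of very large effects,
  not as calibrated error rates. Block permutation or a
  cluster-robust/mixed model would be the calibrated alternative and is
  out of scope.
- Edge effects of the finite untapered transform (the weekly-line leakage
  quantified above) bias weekday amplitudes slightly toward zero at
  lengths not divisible by 7.
- The vacation stratification is a fixed month set, not a school-calendar
  model; moving holidays are ignored.
- Exact reproduction of the published tables requires the original raw
  export, which is not redistributable here; the corresponding check in
  the test suite runs only when that file is supplied and otherwise
  reports the missing input.
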