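# Methods

This note documents the statistical procedure, the defaults and their
rationale, the synthetic test surface, and the open design decisions made
where the method left room for interpretation.

## 1. Data model

The unit of analysis is an **ecoregion panel**: a `T × N` matrix of weekly
anomalies for one target variable (burned area, BA) and ten precursors, each
tagged *top-down* (Tmax, VPD, ET0, Wind, AAI) or *bottom-up* (FPAR, GPP,
NDVI, EVI, SWDI). Missing entries stay missing through every stage;
downstream tests use listwise deletion over the union of lagged index sets.

## 2. Preprocessing

Fixed order, recorded in output metadata: **mask → weekly aggregate →
log transform (BA only) → detrend → deseasonalize**.

- **Quality masking** removes pixels with confidence strictly below 70%.
- **Weekly aggregation** uses a fixed 52-week calendar: week *w* covers days
  `7(w−1)+1 … 7w`, and week 52 absorbs the final 1–2 days of the year. BA is
  *summed* within a week (any missing day makes the week missing);
  precursors are *averaged* over available days.
- **BA transform**: `log1p`, applied before detrending so that the anomaly
  scale of the heavy-tailed, zero-inflated BA distribution is comparable to
  the precursor scales.
- **Detrending**: per-series OLS on time (requires ≥ 104 non-missing weeks,
  i.e. two years).
- **Deseasonalization**: subtraction of the multi-year week-of-year mean
  (52 values), with no smoothing window. A week-of-year never observed in the
  record is an error, not a silent gap. The operator is idempotent and
  commutes with scalar multiplication.

A note on composition: the sequential single-pass order (detrend, then
week-of-year means) is *not* a joint projection onto
`span{1, t, week dummies}`. For an exactly periodic-plus-linear input whose
cycle has nonzero sample covariance `b` with time, the fitted slope is biased
and a deterministic residual of magnitude `|b| · 442` (on a 936-week window)
remains; the residual vanishes to machine precision exactly when the cycle
is orthogonal to the within-year ramp. The acceptance tests assert both
facts. The order is fixed for reproducibility; with balanced complete years
the two steps nearly commute.

## 3. Ecoregion stratification

- Classification rasters (climate zone, vegetation type) and data fields are
  block-aggregated to 0.25°: means for continuous fields, sums for BA,
  mode for categorical codes with ties broken toward the lowest code.
- Ecoregions are the cross-product of climate zones and vegetation types
  (29 × 8 = 232 at full scale), enumerated climate-major for determinism.
- Per ecoregion and week, BA is the **sum** over unmasked member pixels
  (missing only if every pixel is missing) and each precursor is the
  **cos(latitude)-weighted mean** of non-missing pixels.
- Classification is read from NetCDF/CSV. GeoTIFF input is out of scope in
  this build (no GDAL-based raster library in the dependency set); NetCDF
  I/O uses xarray's scipy engine (NetCDF3).

## 4. Two-stage causal discovery

Implemented from scratch in `firelink.pcmci`; the conditional-independence
primitive is linear partial correlation.

**CI test.** `ρ(X, Y | Z)` is computed from the inverse of the sample
covariance of `[X, Y, Z]` (Schur complement), algebraically identical to
correlating the residuals of the two OLS regressions on `Z`. Significance is
a two-sided t test with `df = n − |Z| − 2`. Rows with any missing value among
the involved series are dropped (listwise deletion); tests with fewer than
`|Z| + 12` effective samples or a rank-deficient conditioning set are treated
as degenerate (`ρ = 0, p = 1`) and flagged in the audit.

**Stage 1 — condition selection (PC-like).** For each variable `Y`, start
from all candidates `(X, τ)` with `τ ∈ [max(τ_min, 1), τ_max]`. For
`q = 0 … q_max`, test each surviving candidate conditioned on the `q`
currently strongest *other* candidates and remove those with `p > pc_alpha`
after each sweep. A candidate's strength is the minimum |ρ| over all tests it
has passed. Survivors are the parent set `pa(Y)`.

**Stage 2 — MCI.** Every pair `(X(t−τ), Y(t))`, `τ ∈ [τ_min, τ_max]`, is
tested conditioned on `pa(Y) \ {(X, τ)}` plus the lag-shifted `pa(X)`, each
side truncated to the `max_conds` strongest parents, duplicates removed. All
tests for a panel share a fixed analysis window `t ∈ [max involved lag, T)`.

**Link retention.** Keep links with `p ≤ α`. Contemporaneous (lag-0) links
between two non-target variables are discarded as unoriented;
a lag-0 link between a precursor and the target is oriented precursor →
target (fire does not cause same-week weather at weekly resolution).

**Defaults and rationale.**

| parameter   | default | rationale |
|-------------|---------|-----------|
| `alpha`     | 0.05    | conventional level; calibration verified on the global null (acceptance target t1) |
| `tau_max`   | 156     | three years of weekly lags, covering slow fuel accumulation |
| `tau_min`   | 0       | contemporaneous precursor→target effects are admissible |
| `pc_alpha`  | = alpha | one knob unless explicitly overridden |
| `q_max`     | 3       | PC sweeps beyond 3 conditions change little but multiply cost |
| `max_conds` | 5       | caps MCI conditioning dimension, keeping `df` large at T ≈ 900 |

The API follows the statsmodels model/results convention:
`LaggedCausalModel(panel, config).fit()` returns `CausalDiscoveryResults`
with the retained-link table, parent sets, the full ρ/p/n audit cube
(`xr.Dataset`), `summary()`, exporters, and `attribution()`.

## 5. Dominance attribution

Only links *into* BA are attributed. Each precursor is first collapsed to its
strongest link (max |ρ|; ties to the smaller lag), then:

- **Dominant precursor/group**: argmax |ρ| over collapsed links; ties broken
  by smaller lag, then lexicographically. An ecoregion with no retained link
  into BA has dominant group `None` and is excluded from group statistics.
- **Predictability score**: `Σ ρ²` over collapsed links (0 … 10).
- **Sign fractions**: pooled over ecoregions where the group is dominant,
  using that group's own links; `ρ = 0` counts as positive; a group never
  dominant anywhere yields NaN.
- **Lags**: per ecoregion, the |ρ|-weighted mean lag `Σ|ρ|τ / Σ|ρ|` per
  group; across ecoregions, area-weighted means. The weighted mean over all
  retained links is sensitive to the false-positive background: at
  `τ_max = 80` and `α = 0.05` a non-causal precursor retains a spurious best
  lag with probability `1 − 0.95^81 ≈ 0.98`, pulling the all-links mean
  toward mid-range. Benchmarks therefore check the recovered *dominant* lags
  against planted ones; the all-links weighted mean is still computed and
  reported.
- **Profiles**: 200-bin equal-width dominance profiles along any covariate,
  and per-climate-zone / per-vegetation-type dominance fractions with
  undetected pixels excluded from the denominator.

## 6. Synthetic generator

`firelink.synthetic` produces panels and gridded scenes with known ground
truth.

What it emulates:

- stable lagged linear systems (companion-matrix spectral radius < 1
  enforced; lag-0 part acyclic and solved through `(I − B0)⁻¹`);
- additive sinusoidal seasonality and linear trends per variable;
- a BA-like marginal: exponential skew transform with a zero-inflation
  quantile, so the target is non-negative, zero-inflated and right-skewed
  while `log1p` recovers the latent anomaly above the censoring point;
- gridded scenes: per-ecoregion scenarios, shared latent signal with
  per-pixel noise, per-pixel confidence levels for masking, climate and
  vegetation classification rasters;
- deterministic seeding throughout (`SeedSequence` substreams per variable
  and pixel).

What it does **not** emulate: real spatial autocorrelation structure,
non-linear or threshold fire responses, regime shifts, multiplicative noise,
observation calendars with data gaps, or the actual satellite product error
characteristics. Conclusions about the real system require the real
archives; the generator exists to verify the machinery.

Benchmark scenes (`benchmark_scene_spec`) plant one strong dominant link per
ecoregion (top-down: ET0 → BA at lag 1, coefficient 0.8; bottom-up:
SWDI → BA at lag 30) plus a weaker cross-group link (0.35), over 936 weeks
with seasonality, trend, zero inflation, pixel noise and confidence masking.
These problem sizes are the package's own choice of a desk-scale test bed.

## 7. Numerical choices

- Partial correlation via covariance inverse with an `lstsq` fallback on
  singular systems; ρ clipped to [−1, 1]; p-values via `scipy.special.stdtr`.
- OLS via `np.polyfit`/normal equations; week-of-year means via pandas
  groupby — no iterative optimizers anywhere, so runs are bit-reproducible
  on a platform.
- Pipeline outputs are written with fixed column orders and row sorts;
  re-running an identical config and seed reproduces all CSVs byte-for-byte.

## 8. Open design decisions

- **Anomaly formula**: the week-of-year-mean subtraction is a stand-in for an
  exact published formula that was not available; no smoothing window or
  standardization is applied. This is flagged in the output metadata.
- **Lag-0 orientation**: precursor → target orientation of contemporaneous
  links is an assumption, justified by the one-directional plausibility of
  same-week fire/weather influence at weekly resolution.
- **`q_max = 3`, `max_conds = 5`**: pragmatic caps trading exhaustiveness for
  degrees of freedom and runtime; both are configurable.
- **|ρ| lag weights**: the weighted-mean-lag weights are absolute partial
  correlations, so stronger links dominate the timescale estimate.
- **GeoTIFF**: omitted (see §3); NetCDF3 via xarray's scipy engine is the
  gridded interchange format.

## 9. Limitations

The linear partial-correlation test only detects linear lagged dependence;
calibration results hold under the Gaussian linear model and degrade under
heavy tails or strong nonlinearity. Ecoregion aggregation assumes pixels in
an ecoregion share one causal regime. The dominance dichotomy compresses a
mixed system into its strongest link. All quantitative performance claims in
this repository (calibration, recovery rates, lag accuracy) are made on the
synthetic test surface and are verified by the acceptance suite, not claimed
for real observational archives.
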