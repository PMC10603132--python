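"""Turn raw series into the stationary weekly anomaly panels the causal
analysis consumes.

The standard order is: quality masking -> weekly aggregation (sum for
burned area, mean for precursors) -> log1p transform of burned area ->
linear detrending -> seasonal-cycle removal by week-of-year mean
subtraction.  Burned area is log-transformed because its weekly
marginal is right-skewed with exact zeros; log1p is defined at zero and
monotone.  Detrending and anomaly calculation approximately satisfy
the stationarity assumption of the lagged causal discovery.

Anomalies use the multi-year week-of-year mean (no smoothing window,
no standardization); the choice is recorded in output metadata.  Years
are folded to a fixed 52-week grid: week w covers days of year
7(w-1)+1 .. 7w and week 52 additionally absorbs days 365 and 366.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import Panel

__all__ = [
    "WeeklySeries",
    "ClimatologyModel",
    "mask_low_confidence",
    "aggregate_to_weekly",
    "log_transform_ba",
    "detrend_linear",
    "remove_seasonal_cycle",
    "preprocess_panel",
]

WEEKS_PER_YEAR = 52


@dataclass
class WeeklySeries:
    """A weekly series with explicit week-of-year labels.

    ``values`` uses NaN for missing entries (never silently dropped);
    ``week_of_year`` runs 1..52 under the fixed 52-week convention.
    """

    values: np.ndarray
    week_of_year: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.week_of_year = np.asarray(self.week_of_year, dtype=int)
        if self.values.shape != self.week_of_year.shape:
            raise ValueError("values and week_of_year must have equal length")
        if self.values.size and (
            self.week_of_year.min() < 1 or self.week_of_year.max() > WEEKS_PER_YEAR
        ):
            raise ValueError("week_of_year entries must lie in [1, 52]")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class ClimatologyModel:
    """Linear trend plus week-of-year climatology fitted to one series.

    Removing both components from the series the model was fitted on
    leaves residuals with overall mean zero (to numerical precision,
    for complete series).
    """

    intercept: float
    slope: float
    weekly_means: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "slope": self.slope,
            "weekly_means": None
            if self.weekly_means is None
            else list(np.asarray(self.weekly_means, dtype=float)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClimatologyModel":
        with open(path) as fh:
            d = json.load(fh)
        wm = d["weekly_means"]
        return cls(d["intercept"], d["slope"], None if wm is None else np.asarray(wm))


# ----------------------------------------------------------------------
def mask_low_confidence(values, confidence, threshold: float = 70.0):
    """Set entries whose percent confidence is strictly below ``threshold``
    to missing (NaN).

    Entries exactly at the threshold are kept.  Returns the masked array
    and the count of newly masked entries.
    """
    values = np.asarray(values, dtype=float)
    confidence = np.asarray(confidence, dtype=float)
    if values.shape != confidence.shape:
        raise ValueError(
            f"shape mismatch: values {values.shape} vs confidence {confidence.shape}"
        )
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    mask = confidence < threshold
    out = values.copy()
    newly = int(np.count_nonzero(mask & ~np.isnan(values)))
    out[mask] = np.nan
    return out, newly


def _week_of_year_from_doy(doy: np.ndarray) -> np.ndarray:
    """Fixed 52-week fold: week w covers days 7(w-1)+1..7w, week 52
    absorbs days 365/366."""
    return np.minimum((doy - 1) // 7 + 1, WEEKS_PER_YEAR)


def aggregate_to_weekly(daily: pd.Series, method: str) -> WeeklySeries:
    """Aggregate a calendar-dated daily series to fixed 52-week weeks.

    ``method='sum'`` (burned area): observed zeros contribute 0; any
    missing day makes the weekly sum missing (missingness propagates,
    it is never imputed as zero burning).
    ``method='mean'`` (precursors): missing days are excluded; a week
    with no observed day is missing.
    """
    if method not in ("mean", "sum"):
        raise ValueError(f"method must be 'mean' or 'sum', got {method!r}")
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise TypeError("daily series must have a DatetimeIndex")
    daily = daily.sort_index()
    years = daily.index.year.to_numpy()
    doy = daily.index.dayofyear.to_numpy()
    woy = _week_of_year_from_doy(doy)
    key = years * 100 + woy
    vals = daily.to_numpy(dtype=float)

    order = np.argsort(key, kind="stable")
    key_s, vals_s = key[order], vals[order]
    uniq, start = np.unique(key_s, return_index=True)
    out = np.empty(uniq.size)
    bounds = np.append(start, key_s.size)
    for i in range(uniq.size):
        chunk = vals_s[bounds[i] : bounds[i + 1]]
        nan = np.isnan(chunk)
        if method == "sum":
            out[i] = np.nan if nan.any() else chunk.sum()
        else:
            out[i] = np.nan if nan.all() else np.nanmean(chunk)
    return WeeklySeries(
        out,
        uniq % 100,
        meta={
            "method": method,
            "first_key": int(uniq[0]),
            "last_key": int(uniq[-1]),
        },
    )


def log_transform_ba(series: WeeklySeries, offset: float = 1.0) -> WeeklySeries:
    """Variance-stabilizing transform value -> log(offset + value).

    Monotone and zero-preserving at the default offset, so exact-zero
    burning weeks stay exactly zero.  Rejects negative values.
    """
    if series.values.size and np.nanmin(series.values) < 0:
        raise ValueError("burned area values must be >= 0")
    if offset == 1.0:
        vals = np.log1p(series.values)
    else:
        vals = np.log(offset + series.values)
    return WeeklySeries(
        vals, series.week_of_year, meta={**series.meta, "log_offset": offset}
    )


def detrend_linear(series: WeeklySeries) -> tuple[WeeklySeries, ClimatologyModel]:
    """Remove an ordinary-least-squares linear trend in the week index.

    Requires at least 104 non-missing entries (two years of weeks).
    Missing entries stay missing in the output.
    """
    vals = series.values
    ok = ~np.isnan(vals)
    if ok.sum() == 0:
        raise ValueError("cannot detrend an all-missing series")
    if ok.sum() < 104:
        raise ValueError(
            f"need >= 104 non-missing entries to detrend, got {int(ok.sum())}"
        )
    t = np.arange(vals.size, dtype=float)
    slope, intercept = np.polyfit(t[ok], vals[ok], 1)
    resid = vals - (intercept + slope * t)
    model = ClimatologyModel(float(intercept), float(slope))
    return (
        WeeklySeries(resid, series.week_of_year, meta={**series.meta, "detrended": True}),
        model,
    )


def remove_seasonal_cycle(
    series: WeeklySeries, model: ClimatologyModel | None = None
) -> tuple[WeeklySeries, ClimatologyModel]:
    """Subtract the multi-year mean at each week of year.

    anomaly(t) = value(t) - mean over all years of value at the same
    week of year.  Every week of year must be observed at least once
    across the record.  Idempotent: anomalies of anomalies are
    unchanged to numerical precision.
    """
    vals = series.values
    woy = series.week_of_year
    if np.unique(woy[~np.isnan(vals)]).size and vals.size < 2 * WEEKS_PER_YEAR:
        raise ValueError("need at least two complete years")
    means = np.full(WEEKS_PER_YEAR, np.nan)
    for w in range(1, WEEKS_PER_YEAR + 1):
        sel = (woy == w) & ~np.isnan(vals)
        if not sel.any():
            raise ValueError(
                f"week of year {w} has no observations across the record"
            )
        means[w - 1] = vals[sel].mean()
    anom = vals - means[woy - 1]
    out_model = ClimatologyModel(
        model.intercept if model else 0.0,
        model.slope if model else 0.0,
        weekly_means=means,
    )
    return (
        WeeklySeries(
            anom, woy, meta={**series.meta, "anomaly_method": "week_of_year_mean"}
        ),
        out_model,
    )


# ----------------------------------------------------------------------
def preprocess_panel(
    panel: Panel,
    log_vars: tuple[str, ...] | None = None,
    detrend: bool = True,
    deseasonalize: bool = True,
) -> tuple[Panel, dict[str, ClimatologyModel]]:
    """Apply the standard per-variable pipeline to a weekly panel.

    Variables named in ``log_vars`` (default: the panel target) receive
    the log1p transform first; every variable is then detrended and
    converted to week-of-year anomalies.  The applied order is recorded
    in the output metadata.
    """
    if log_vars is None:
        log_vars = (panel.target,) if panel.target else ()
    woy = panel.week_of_year
    out = {}
    models: dict[str, ClimatologyModel] = {}
    for v in panel.variables:
        ws = WeeklySeries(panel.data[v].to_numpy(dtype=float), woy)
        if v in log_vars:
            ws = log_transform_ba(ws)
        model = ClimatologyModel(0.0, 0.0)
        if detrend:
            ws, model = detrend_linear(ws)
        if deseasonalize:
            ws, model = remove_seasonal_cycle(ws, model)
        out[v] = ws.values
        models[v] = model
    df = pd.DataFrame(out, index=panel.data.index)
    meta = {
        **panel.meta,
        "preprocessing": [
            *(["log1p:" + ",".join(log_vars)] if log_vars else []),
            *(["detrend:ols"] if detrend else []),
            *(["anomaly:week_of_year_mean"] if deseasonalize else []),
        ],
    }
    return Panel(df, dict(panel.groups), meta), models
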