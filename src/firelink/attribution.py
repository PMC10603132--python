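"""Dominance attribution of lagged causal links into burned area.

Given per-ecoregion causal graphs, this module computes the headline
quantities of the driver analysis: the dominant precursor and group
(top-down weather versus bottom-up fuel), a predictability score (sum
of squared partial correlations of precursor links into burned area),
sign fractions of the dominant group's links, correlation-weighted mean
time lags, covariate-binned dominance profiles, and per-climate-zone /
per-vegetation-type dominance fractions.

Tie-breaking is deterministic everywhere: larger |rho|, then smaller
lag, then lexicographic identifier.  Before ranking or scoring, each
precursor is collapsed to its single strongest link (max |rho| over
lags); the per-lag table is preserved for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PrecursorGrouping",
    "DEFAULT_GROUPING",
    "DominanceRecord",
    "BinnedProfile",
    "links_to_ba",
    "rank_precursors",
    "dominant_group",
    "predictability_score",
    "sign_fractions",
    "weighted_mean_lag",
    "group_mean_lag",
    "binned_dominance_profile",
    "zone_type_dominance",
    "attribute_results",
]

GROUPS = ("top-down", "bottom-up")


@dataclass(frozen=True)
class PrecursorGrouping:
    """Mapping from precursor variable to its driver group."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v: g for v, g in self.mapping.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"groups must be one of {GROUPS}: {bad}")

    def group_of(self, variable: str) -> str:
        return self.mapping[variable]

    def require_covers(self, variables) -> None:
        missing = [v for v in variables if v not in self.mapping]
        if missing:
            raise ValueError(f"ungrouped precursors: {missing}")


#: Canonical grouping of the ten wildfire precursors: five top-down
#: atmospheric drivers and five bottom-up vegetation/fuel drivers.
DEFAULT_GROUPING = PrecursorGrouping(
    {
        "Tmax": "top-down",
        "VPD": "top-down",
        "ET0": "top-down",
        "Wind": "top-down",
        "AAI": "top-down",
        "FPAR": "bottom-up",
        "GPP": "bottom-up",
        "NDVI": "bottom-up",
        "EVI": "bottom-up",
        "SWDI": "bottom-up",
    }
)

_LINK_COLS = ["source", "lag", "rho"]


def _as_table(table) -> pd.DataFrame:
    df = pd.DataFrame(table) if not isinstance(table, pd.DataFrame) else table
    if df.empty:
        return pd.DataFrame(columns=_LINK_COLS)
    missing = [c for c in _LINK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"link table missing columns {missing}")
    return df


def links_to_ba(results_or_links, target: str) -> pd.DataFrame:
    """Filter retained links to those pointing into ``target``.

    Accepts a fitted :class:`~firelink.pcmci.CausalDiscoveryResults`
    or a raw link DataFrame with source/target columns.
    """
    if hasattr(results_or_links, "links_to"):
        return results_or_links.links_to(target)
    df = pd.DataFrame(results_or_links)
    if df.empty:
        return pd.DataFrame(columns=["source", "target", "lag", "rho"])
    out = df[(df["target"] == target) & (df["source"] != target)]
    return out.reset_index(drop=True)


# ----------------------------------------------------------------------
def _collapse_per_precursor(table: pd.DataFrame) -> pd.DataFrame:
    """One row per precursor: its strongest link (max |rho|; ties to
    smaller lag, then lexicographic source)."""
    df = _as_table(table).copy()
    if df.empty:
        return df
    df["_abs"] = df["rho"].abs()
    df = df.sort_values(
        ["source", "_abs", "lag"], ascending=[True, False, True], kind="stable"
    )
    out = df.groupby("source", as_index=False).first()
    return out.drop(columns="_abs").reset_index(drop=True)


def rank_precursors(table) -> pd.DataFrame:
    """Rank precursors by causal strength (absolute partial correlation).

    Each precursor is first collapsed to its strongest link; the
    precursor ranked first is the *dominant precursor* and its lag the
    *dominant time lag*.  Returns the collapsed table sorted by rank
    (empty for an empty input).
    """
    c = _collapse_per_precursor(table)
    if c.empty:
        return c
    c["_abs"] = c["rho"].abs()
    c = c.sort_values(
        ["_abs", "lag", "source"], ascending=[False, True, True], kind="stable"
    ).drop(columns="_abs")
    return c.reset_index(drop=True)


def dominant_group(table, grouping: PrecursorGrouping = DEFAULT_GROUPING):
    """Group (top-down | bottom-up | None) owning the strongest link.

    Returns ``(group, strengths)`` where strengths maps each group to
    the max |rho| among its links (absent group -> 0).  ``None`` marks
    an ecoregion where no causal relationship is detected.
    """
    ranked = rank_precursors(table)
    if ranked.empty:
        return None, {g: 0.0 for g in GROUPS}
    grouping.require_covers(ranked["source"])
    strengths = {g: 0.0 for g in GROUPS}
    for _, row in ranked.iterrows():
        g = grouping.group_of(row["source"])
        strengths[g] = max(strengths[g], abs(row["rho"]))
    top = ranked.iloc[0]
    return grouping.group_of(top["source"]), strengths


def predictability_score(table) -> float:
    """Sum of squared partial correlations over precursor links.

    One (strongest) link per precursor; precursors without a retained
    link contribute zero.  Higher values mean higher predictability of
    burned area; bounded above by the number of precursors.
    """
    c = _collapse_per_precursor(table)
    if c.empty:
        return 0.0
    return float(np.sum(np.square(c["rho"].to_numpy())))


def weighted_mean_lag(table) -> float:
    """Mean time lag weighted by absolute partial correlation.

    sum(|rho_i| * tau_i) / sum(|rho_i|) over the (collapsed) precursor
    links; lies within [min lag, max lag] of its inputs.
    """
    c = _collapse_per_precursor(table)
    if c.empty:
        raise ValueError("weighted_mean_lag of an empty link table")
    w = c["rho"].abs().to_numpy()
    tau = c["lag"].to_numpy(dtype=float)
    if w.sum() <= 0:
        return float(tau.mean())
    return float((w * tau).sum() / w.sum())


# ----------------------------------------------------------------------
@dataclass
class DominanceRecord:
    """Per-ecoregion attribution result."""

    ecoregion: str
    dominant_group: str | None
    dominant_precursor: str | None
    dominant_lag: int | None
    score: float
    table: pd.DataFrame = field(repr=False)
    group_mean_lags: dict[str, float] = field(default_factory=dict)
    area: float = 1.0

    def __post_init__(self) -> None:
        if (self.dominant_group is None) != self.table.empty:
            raise ValueError(
                "dominant_group must be None exactly when the link table is empty"
            )


def attribute_record(
    table,
    ecoregion: str = "",
    grouping: PrecursorGrouping = DEFAULT_GROUPING,
    area: float = 1.0,
) -> DominanceRecord:
    """Build the :class:`DominanceRecord` for one ecoregion's link table."""
    tbl = _as_table(table)
    ranked = rank_precursors(tbl)
    group, _ = dominant_group(tbl, grouping)
    if ranked.empty:
        return DominanceRecord(ecoregion, None, None, None, 0.0, ranked, {}, area)
    top = ranked.iloc[0]
    gml = {}
    for g in GROUPS:
        sub = ranked[[grouping.group_of(s) == g for s in ranked["source"]]]
        if not sub.empty:
            gml[g] = weighted_mean_lag(sub)
    return DominanceRecord(
        ecoregion,
        group,
        str(top["source"]),
        int(top["lag"]),
        predictability_score(tbl),
        ranked,
        gml,
        area,
    )


def attribute_results(results, grouping: PrecursorGrouping | None = None):
    """Attribution of a fitted causal-discovery results object."""
    grouping = grouping or DEFAULT_GROUPING
    target = results.model.panel.target
    if target is None:
        raise ValueError("panel has no target variable to attribute")
    table = results.links_to(target)[["source", "lag", "rho"]]
    eco = results.model.panel.meta.get("ecoregion", "")
    return attribute_record(table, eco, grouping)


# ----------------------------------------------------------------------
def sign_fractions(
    records, grouping: PrecursorGrouping = DEFAULT_GROUPING
) -> dict[str, tuple[float, float]]:
    """Positive/negative fractions of each group's partial correlations,
    pooled over the ecoregions where that group is dominant.

    Fractions sum to 1 per group; a partial correlation of exactly zero
    counts as positive (deterministic rule for a measure-zero event).
    Groups never dominant map to (nan, nan).
    """
    pooled: dict[str, list[float]] = {g: [] for g in GROUPS}
    for rec in records:
        if rec.dominant_group is None:
            continue
        g = rec.dominant_group
        for _, row in rec.table.iterrows():
            if grouping.group_of(row["source"]) == g:
                pooled[g].append(float(row["rho"]))
    out = {}
    for g in GROUPS:
        vals = np.asarray(pooled[g])
        if vals.size == 0:
            out[g] = (float("nan"), float("nan"))
        else:
            pos = float((vals >= 0).mean())
            out[g] = (pos, 1.0 - pos)
    return out


def group_mean_lag(records, group: str, areas=None) -> float:
    """Area-weighted mean of a group's weighted-mean lags over the
    ecoregions where it is dominant."""
    recs = [r for r in records if r.dominant_group == group]
    if not recs:
        raise ValueError(f"no ecoregion where group {group!r} is dominant")
    if areas is None:
        w = np.asarray([r.area for r in recs], dtype=float)
    else:
        w = np.asarray(areas, dtype=float)
        if w.size != len(recs):
            raise ValueError("areas must align with the dominant records")
    lags = np.asarray([r.group_mean_lags[group] for r in recs])
    return float((w * lags).sum() / w.sum())


# ----------------------------------------------------------------------
@dataclass
class BinnedProfile:
    """Dominance fractions along a covariate, in equal-width bins."""

    covariate: str
    edges: np.ndarray
    top_down_fraction: np.ndarray
    bottom_up_fraction: np.ndarray
    top_down_mean_lag: np.ndarray
    bottom_up_mean_lag: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "top_down_fraction": self.top_down_fraction,
                "bottom_up_fraction": self.bottom_up_fraction,
                "top_down_mean_lag": self.top_down_mean_lag,
                "bottom_up_mean_lag": self.bottom_up_mean_lag,
                "count": self.counts,
            }
        )


def binned_dominance_profile(
    pixels: pd.DataFrame, covariate: str, n_bins: int = 200
) -> BinnedProfile:
    """Dominance fractions of the two groups along a covariate.

    ``pixels`` needs one row per pixel with columns ``covariate`` (its
    mean covariate value), ``dominant_group`` (its ecoregion's label,
    None/NaN for undetected) and optionally ``mean_lag`` and ``area``.
    Bins are equal-width over the observed covariate range.  The
    fraction in a bin is the number of pixels dominated by the group
    divided by the number dominated by either group; bins with no
    dominated pixel are NaN (undefined).  Per-bin group mean lags are
    area-weighted over the group's dominated pixels in the bin.
    """
    df = pixels.copy()
    if covariate not in df.columns:
        raise ValueError(f"missing covariate column {covariate!r}")
    x = df[covariate].to_numpy(dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    dom = df["dominant_group"].to_numpy(dtype=object)
    lag = df["mean_lag"].to_numpy(dtype=float) if "mean_lag" in df else np.full(len(df), np.nan)
    area = df["area"].to_numpy(dtype=float) if "area" in df else np.ones(len(df))

    td_frac = np.full(n_bins, np.nan)
    bu_frac = np.full(n_bins, np.nan)
    td_lag = np.full(n_bins, np.nan)
    bu_lag = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = int(sel.sum())
        d = dom[sel]
        td = d == "top-down"
        bu = d == "bottom-up"
        denom = int(td.sum() + bu.sum())
        if denom == 0:
            continue
        td_frac[b] = td.sum() / denom
        bu_frac[b] = bu.sum() / denom
        for mask, out in ((td, td_lag), (bu, bu_lag)):
            la = lag[sel][mask]
            wa = area[sel][mask]
            ok = ~np.isnan(la)
            if ok.any():
                out[b] = float((la[ok] * wa[ok]).sum() / wa[ok].sum())
    return BinnedProfile(covariate, edges, td_frac, bu_frac, td_lag, bu_lag, counts)


def zone_type_dominance(pixels: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group dominance fractions per climate zone and per vegetation type.

    For each stratum the fraction is (pixels dominated by the group) /
    (pixels dominated by either group); undetected pixels are excluded
    from the denominator.  Strata with no dominated pixel are flagged
    with NaN fractions.
    """
    out = {}
    for stratum in ("climate", "vegetation"):
        if stratum not in pixels.columns:
            continue
        rows = []
        for code, sub in pixels.groupby(stratum, sort=True):
            d = sub["dominant_group"].to_numpy(dtype=object)
            td = int((d == "top-down").sum())
            bu = int((d == "bottom-up").sum())
            denom = td + bu
            rows.append(
                {
                    stratum: code,
                    "top_down_fraction": td / denom if denom else np.nan,
                    "bottom_up_fraction": bu / denom if denom else np.nan,
                    "n_dominated": denom,
                    "n_pixels": len(sub),
                }
            )
        out[stratum] = pd.DataFrame(rows)
    if not out:
        raise ValueError("pixels must carry a 'climate' or 'vegetation' column")
    return out
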