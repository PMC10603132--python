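"""Climate-zone x vegetation-type stratification and ecoregional panels.

An ecoregion is the intersection of one climate zone (Koppen-Geiger
style, 29 usable classes in the global analysis) and one vegetation
type (8 classes: sparse vegetation, grassland, cropland, shrubland,
TBE, TBD, TNE, TND).  Codes are treated as opaque labels supplied in
configuration, so tests never need the real classification maps.

Gridded fields are collapsed to one weekly panel per ecoregion: burned
area is summed over member pixels, precursors are averaged (optionally
cos(latitude)-weighted, the default, since 0.25-degree cells shrink
toward the poles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .panel import Panel

__all__ = [
    "EcoregionKey",
    "VEGETATION_TYPES",
    "build_ecoregion_keys",
    "regrid_quarter_degree",
    "aggregate_to_ecoregion",
]

#: The eight vegetation (land-cover) classes of the stratification.
VEGETATION_TYPES = (
    "sparse vegetation",
    "grassland",
    "cropland",
    "shrubland",
    "TBE",
    "TBD",
    "TNE",
    "TND",
)


@dataclass(frozen=True)
class EcoregionKey:
    """One stratum: a (climate zone, vegetation type) pair."""

    climate: str
    vegetation: str

    @property
    def id(self) -> str:
        """Deterministic join of the two codes."""
        return f"{self.climate}|{self.vegetation}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


def build_ecoregion_keys(
    climate_codes: Sequence, vegetation_codes: Sequence
) -> list[EcoregionKey]:
    """Full cross-product of climate and vegetation codes,
    deterministically ordered climate-major then vegetation.

    With the global analysis's 29 climate zones and 8 vegetation types
    this enumerates 232 ecoregions.
    """
    climate_codes = [str(c) for c in climate_codes]
    vegetation_codes = [str(v) for v in vegetation_codes]
    if not climate_codes or not vegetation_codes:
        raise ValueError("code lists must be non-empty")
    if len(set(climate_codes)) != len(climate_codes):
        raise ValueError("duplicate climate codes")
    if len(set(vegetation_codes)) != len(vegetation_codes):
        raise ValueError("duplicate vegetation codes")
    return [
        EcoregionKey(c, v) for c in climate_codes for v in vegetation_codes
    ]


# ----------------------------------------------------------------------
def _block_mode_lowest(block: np.ndarray) -> float:
    """Most frequent value; ties broken by the lowest code."""
    vals, counts = np.unique(block[~np.isnan(block)], return_counts=True)
    if vals.size == 0:
        return np.nan
    return float(vals[np.argmax(counts)])  # np.unique sorts: first max is lowest


def regrid_quarter_degree(
    field: xr.DataArray, method: str = "mean"
) -> xr.DataArray:
    """Block-aggregate a finer regular lat/lon grid to 0.25 degrees.

    The input resolution must divide 0.25 evenly (integer block size);
    an input already at 0.25 degrees is returned unchanged.  ``method``
    is ``mean`` or ``sum`` for continuous layers and ``mode`` for
    categorical layers (ties resolved to the lowest code).  No
    interpolation is performed.
    """
    if method not in ("mean", "sum", "mode"):
        raise ValueError(f"unknown method {method!r}")
    lat = field["lat"].to_numpy()
    lon = field["lon"].to_numpy()
    res = float(abs(lat[1] - lat[0])) if lat.size > 1 else 0.25
    res_lon = float(abs(lon[1] - lon[0])) if lon.size > 1 else res
    if abs(res - res_lon) > 1e-9:
        raise ValueError("anisotropic grids are not supported")
    ratio = 0.25 / res
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6 or factor < 1:
        raise ValueError(
            f"input resolution {res} does not divide 0.25 degrees evenly"
        )
    if factor == 1:
        return field
    if lat.size % factor or lon.size % factor:
        raise ValueError("grid extent is not a whole number of 0.25-degree cells")

    coarse_lat = lat.reshape(-1, factor).mean(axis=1)
    coarse_lon = lon.reshape(-1, factor).mean(axis=1)
    arr = field.transpose(..., "lat", "lon").to_numpy()
    lead = arr.shape[:-2]
    nlat, nlon = arr.shape[-2] // factor, arr.shape[-1] // factor
    blocks = arr.reshape(*lead, nlat, factor, nlon, factor)
    if method == "mean":
        out = np.nanmean(blocks, axis=(-3, -1))
    elif method == "sum":
        out = np.nansum(blocks, axis=(-3, -1))
        all_nan = np.isnan(blocks).all(axis=(-3, -1))
        out = np.where(all_nan, np.nan, out)
    else:
        flat = blocks.reshape(-1, factor * factor)
        out = np.array([_block_mode_lowest(b) for b in flat]).reshape(
            *lead, nlat, nlon
        )
    dims = [d for d in field.dims if d not in ("lat", "lon")] + ["lat", "lon"]
    coords = {d: field.coords[d] for d in dims if d in field.coords and d not in ("lat", "lon")}
    coords |= {"lat": coarse_lat, "lon": coarse_lon}
    return xr.DataArray(out, dims=dims, coords=coords, name=field.name)


# ----------------------------------------------------------------------
def aggregate_to_ecoregion(
    stack: xr.Dataset,
    keys: Sequence[EcoregionKey],
    ba_var: str = "BA",
    groups: dict[str, str] | None = None,
    weighting: str = "cosine",
) -> tuple[dict[str, Panel], pd.DataFrame]:
    """Collapse a classified gridded stack to one weekly panel per key.

    Per week, the burned-area series is the plain sum of unmasked
    member-pixel values (a masked pixel-week contributes nothing; a
    week with every member missing is missing).  Each precursor is the
    area-weighted mean over member pixels with non-missing values
    (``weighting='cosine'`` uses cos(latitude) weights, ``'uniform'``
    equal weights).

    Returns ``(panels, manifest)`` where the manifest records pixel
    count and total area weight per realized key; keys with zero pixels
    are omitted with a warning.
    """
    if weighting not in ("cosine", "uniform"):
        raise ValueError("weighting must be 'cosine' or 'uniform'")
    climate = stack["climate_code"].to_numpy()
    vegetation = stack["vegetation_code"].to_numpy()
    lat = stack["lat"].to_numpy()
    if weighting == "cosine":
        w_lat = np.cos(np.deg2rad(lat))
    else:
        w_lat = np.ones_like(lat, dtype=float)
    weights2d = np.broadcast_to(w_lat[:, None], climate.shape)

    var_names = [
        v
        for v in stack.data_vars
        if v not in ("confidence", "climate_code", "vegetation_code")
        and "time" in stack[v].dims
    ]
    if groups is None:
        groups = {
            v: ("target" if v == ba_var else "top-down") for v in var_names
        }

    panels: dict[str, Panel] = {}
    manifest_rows = []
    time_index = pd.RangeIndex(stack.sizes["time"])
    for key in keys:
        member = (climate.astype(str) == key.climate) & (
            vegetation.astype(str) == key.vegetation
        )
        n_pix = int(member.sum())
        if n_pix == 0:
            warnings.warn(f"ecoregion {key.id} has no pixels; skipped")
            continue
        w = weights2d[member]
        cols = {}
        for v in var_names:
            arr = stack[v].transpose("time", "lat", "lon").to_numpy()[:, member]
            ok = ~np.isnan(arr)
            if v == ba_var:
                s = np.where(ok, arr, 0.0).sum(axis=1)
                cols[v] = np.where(ok.any(axis=1), s, np.nan)
            else:
                wt = np.where(ok, w[None, :], 0.0)
                denom = wt.sum(axis=1)
                num = (np.where(ok, arr, 0.0) * wt).sum(axis=1)
                cols[v] = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
        df = pd.DataFrame(cols, index=time_index)
        panels[key.id] = Panel(
            df,
            {v: groups[v] for v in var_names},
            meta={
                "ecoregion": key.id,
                "n_pixels": n_pix,
                "total_area_weight": float(w.sum()),
                "weighting": weighting,
            },
        )
        manifest_rows.append(
            {"ecoregion": key.id, "n_pixels": n_pix, "total_area_weight": float(w.sum())}
        )
    manifest = pd.DataFrame(
        manifest_rows, columns=["ecoregion", "n_pixels", "total_area_weight"]
    )
    return panels, manifest
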