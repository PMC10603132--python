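"""Synthetic panels and gridded scenes with planted causal structure.

The generator emulates the statistical shape of ecoregional wildfire
data — weekly series over ~18 years with a seasonal cycle, a linear
trend, Gaussian noise, and a zero-inflated right-skewed burned-area
marginal — while the data-generating process is a known stable linear
lagged system.  Downstream stages (preprocessing, causal discovery,
attribution) are therefore testable against exact ground truth: the
planted links, their signs, strengths and time lags.

No attempt is made to mimic the spatial patterns, units or ranges of
real satellite products; only the structure the analysis assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .panel import Panel, VALID_GROUPS

__all__ = [
    "PlantedLink",
    "ScenarioSpec",
    "SceneSpec",
    "STANDARD_VARIABLES",
    "generate_var_panel",
    "generate_null_panel",
    "generate_gridded_scene",
    "benchmark_scene_spec",
]

#: The standard eleven-variable panel: burned area plus five top-down
#: atmospheric precursors and five bottom-up vegetation/fuel precursors.
STANDARD_VARIABLES: dict[str, str] = {
    "BA": "target",
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


@dataclass(frozen=True)
class PlantedLink:
    """A ground-truth lagged linear causal link ``source -> target``."""

    source: str
    target: str
    lag: int
    coefficient: float

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")
        if self.lag == 0 and self.source == self.target:
            raise ValueError("self-link at lag 0 is not allowed")


def _per_variable(value, variables: Sequence[str], name: str) -> dict[str, float]:
    """Broadcast a scalar, or validate a mapping, to one value per variable."""
    if isinstance(value, Mapping):
        out = {v: float(value.get(v, 0.0)) for v in variables}
    else:
        out = {v: float(value) for v in variables}
    return out


@dataclass
class ScenarioSpec:
    """Complete declarative description of one synthetic ecoregion panel.

    Parameters
    ----------
    variables
        Ordered mapping variable name -> group tag
        ("top-down" | "bottom-up" | "target").
    links
        Planted lagged linear links.  The implied system must be stable
        (spectral radius of the companion matrix < 1) and its lag-0
        sub-graph acyclic.
    noise_sd, seasonal_amplitude, trend_slope
        Scalar (broadcast) or per-variable mapping.  Noise is Gaussian,
        the seasonal cycle is a sinusoid of period ``seasonal_period``
        weeks, the trend is linear in the week index.
    n_weeks
        Panel length; must exceed ``2 * max planted lag + 100``.
    seed
        Master seed; each variable draws from an independent substream
        so outputs are reproducible and uncorrelated across variables.
    ba_zero_inflation
        Fraction of exact-zero weeks planted in the target's marginal.
    ba_skew_transform
        If True, the observed target is ``max(expm1(y - q), 0)`` where
        ``y`` is the latent target plus season/trend and ``q`` its
        ``ba_zero_inflation`` quantile — a right-skewed, zero-inflated
        marginal whose log1p transform recovers the latent anomalies
        (censored at zero).
    tau_max
        Largest admissible lag for planted links (defaults to the
        largest planted lag).
    """

    variables: dict[str, str]
    links: list[PlantedLink] = field(default_factory=list)
    noise_sd: float | Mapping[str, float] = 1.0
    seasonal_amplitude: float | Mapping[str, float] = 0.0
    seasonal_period: int = 52
    trend_slope: float | Mapping[str, float] = 0.0
    n_weeks: int = 936
    seed: int = 0
    ba_zero_inflation: float = 0.0
    ba_skew_transform: bool = False
    tau_max: int | None = None

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        names = list(self.variables)
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        bad = {v: g for v, g in self.variables.items() if g not in VALID_GROUPS}
        if bad:
            raise ValueError(f"invalid group tags: {bad}")
        for lk in self.links:
            if lk.source not in self.variables or lk.target not in self.variables:
                raise ValueError(f"link references unknown variable: {lk}")
        max_lag = max((lk.lag for lk in self.links), default=0)
        if self.tau_max is None:
            self.tau_max = max_lag
        if max_lag > self.tau_max:
            raise ValueError(
                f"planted lag {max_lag} exceeds tau_max {self.tau_max}"
            )
        if self.n_weeks <= 2 * max_lag + 100:
            raise ValueError(
                f"n_weeks={self.n_weeks} too short: need > {2 * max_lag + 100}"
            )
        if not 0.0 <= self.ba_zero_inflation <= 1.0:
            raise ValueError("ba_zero_inflation must be in [0, 1]")
        nsd = _per_variable(self.noise_sd, names, "noise_sd")
        if any(s <= 0 for s in nsd.values()):
            raise ValueError("noise_sd must be > 0 for every variable")
        self._check_stability()

    # ------------------------------------------------------------------
    def _coef_matrices(self) -> tuple[np.ndarray, dict[int, np.ndarray]]:
        """Return (B0, {lag: B_lag}) with B[target, source] = coefficient."""
        names = list(self.variables)
        idx = {v: i for i, v in enumerate(names)}
        n = len(names)
        b0 = np.zeros((n, n))
        blag: dict[int, np.ndarray] = {}
        for lk in self.links:
            i, j = idx[lk.target], idx[lk.source]
            if lk.lag == 0:
                b0[i, j] += lk.coefficient
            else:
                blag.setdefault(lk.lag, np.zeros((n, n)))[i, j] += lk.coefficient
        return b0, blag

    def _check_stability(self) -> None:
        b0, blag = self._coef_matrices()
        n = len(self.variables)
        # lag-0 part must be acyclic so the system is well defined
        m0 = np.eye(n) - b0
        g = np.abs(b0) > 0
        reach = g.copy()
        for _ in range(n):
            reach = reach | (reach @ g)
        if np.any(np.diag(reach)):
            raise ValueError("lag-0 links form a cycle; system ill-defined")
        if not blag:
            return
        m0_inv = np.linalg.inv(m0)
        p = max(blag)
        comp = np.zeros((n * p, n * p))
        for lag, b in blag.items():
            comp[:n, (lag - 1) * n : lag * n] = m0_inv @ b
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        radius = float(np.max(np.abs(np.linalg.eigvals(comp))))
        if radius >= 1.0:
            raise ValueError(
                f"planted system unstable: companion spectral radius "
                f"{radius:.4f} >= 1"
            )


# ----------------------------------------------------------------------
def _simulate_latent(spec: ScenarioSpec, rng_children) -> np.ndarray:
    """Simulate the latent linear lagged system, one noise substream per
    variable, in topological order for lag-0 edges."""
    names = list(spec.variables)
    n = len(names)
    t_total = spec.n_weeks
    noise_sd = _per_variable(spec.noise_sd, names, "noise_sd")
    eps = np.empty((t_total, n))
    for i, v in enumerate(names):
        eps[:, i] = np.random.default_rng(rng_children[i]).normal(
            0.0, noise_sd[v], size=t_total
        )

    b0, blag = spec._coef_matrices()
    # topological order over lag-0 edges (acyclicity already verified)
    order: list[int] = []
    remaining = set(range(n))
    deps = {i: set(np.nonzero(b0[i])[0]) for i in range(n)}
    while remaining:
        ready = sorted(i for i in remaining if deps[i] <= set(order))
        order.extend(ready)
        remaining -= set(ready)

    z = np.zeros((t_total, n))
    lags = sorted(blag)
    for t in range(t_total):
        drive = eps[t].copy()
        for lag in lags:
            if t - lag >= 0:
                drive += blag[lag] @ z[t - lag]
        for i in order:
            z[t, i] = drive[i] + b0[i] @ z[t]
    return z


def _season_trend(spec: ScenarioSpec) -> np.ndarray:
    names = list(spec.variables)
    amp = _per_variable(spec.seasonal_amplitude, names, "seasonal_amplitude")
    slope = _per_variable(spec.trend_slope, names, "trend_slope")
    t = np.arange(spec.n_weeks, dtype=float)
    out = np.zeros((spec.n_weeks, len(names)))
    for i, v in enumerate(names):
        out[:, i] = amp[v] * np.sin(2 * np.pi * t / spec.seasonal_period)
        out[:, i] += slope[v] * t
    return out


def _apply_ba_marginal(y: np.ndarray, zero_inflation: float) -> np.ndarray:
    """Right-skewed zero-inflated marginal: max(expm1(y - q), 0) with q
    the zero_inflation quantile of y.  log1p inverts it above the
    censoring point."""
    q = np.quantile(y, zero_inflation) if zero_inflation > 0 else -np.inf
    shifted = y - (q if np.isfinite(q) else 0.0)
    return np.maximum(np.expm1(shifted), 0.0)


def generate_var_panel(spec: ScenarioSpec) -> tuple[Panel, list[PlantedLink]]:
    """Generate a weekly panel whose data-generating process is exactly
    the planted lagged linear system plus declared season/trend/noise.

    Returns the panel and the planted links verbatim.  Identical
    (spec, seed) gives bit-identical output.
    """
    names = list(spec.variables)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(names))
    latent = _simulate_latent(spec, children)
    obs = latent + _season_trend(spec)

    target = [v for v, g in spec.variables.items() if g == "target"]
    if spec.ba_skew_transform and target:
        ti = names.index(target[0])
        obs[:, ti] = _apply_ba_marginal(obs[:, ti], spec.ba_zero_inflation)

    df = pd.DataFrame(obs, columns=names, index=pd.RangeIndex(spec.n_weeks))
    panel = Panel(
        df,
        dict(spec.variables),
        meta={
            "seed": spec.seed,
            "generator": "planted_var",
            "ba_skew_transform": spec.ba_skew_transform,
            "ba_zero_inflation": spec.ba_zero_inflation,
        },
    )
    return panel, list(spec.links)


def generate_null_panel(n_vars: int, n_weeks: int, seed: int) -> Panel:
    """Mutually independent Gaussian white-noise series; no planted links.

    The global-null surface used to calibrate the false-positive rate of
    the conditional-independence tests at the nominal significance level.
    """
    if n_vars < 2:
        raise ValueError("n_vars must be >= 2")
    if n_weeks < 100:
        raise ValueError("n_weeks must be >= 100")
    children = np.random.SeedSequence(seed).spawn(n_vars)
    names = [f"V{i}" for i in range(n_vars)]
    data = np.column_stack(
        [np.random.default_rng(c).normal(size=n_weeks) for c in children]
    )
    groups = {v: ("target" if i == 0 else "top-down") for i, v in enumerate(names)}
    df = pd.DataFrame(data, columns=names, index=pd.RangeIndex(n_weeks))
    return Panel(df, groups, meta={"seed": seed, "generator": "null"})


# ----------------------------------------------------------------------
@dataclass
class SceneSpec:
    """Declarative description of a gridded multi-ecoregion scene.

    Every pixel carries one (climate, vegetation) pair; pixels sharing a
    pair form an ecoregion driven by a common :class:`ScenarioSpec`
    signal plus independent per-pixel noise.  A per-pixel-week percent
    confidence layer is drawn from a declared discrete distribution on
    [0, 100] so the quality-masking rule can be exercised.
    """

    shape: tuple[int, int]
    climate_code: np.ndarray
    vegetation_code: np.ndarray
    scenarios: dict[str, ScenarioSpec]
    pixel_noise_sd: float = 0.1
    confidence_levels: tuple[float, ...] = (100.0,)
    confidence_probs: tuple[float, ...] = (1.0,)
    seed: int = 0
    lat0: float = 0.0
    lon0: float = 0.0

    def __post_init__(self) -> None:
        self.climate_code = np.asarray(self.climate_code).astype(str)
        self.vegetation_code = np.asarray(self.vegetation_code).astype(str)
        if self.climate_code.shape != self.shape:
            raise ValueError("climate_code shape mismatch")
        if self.vegetation_code.shape != self.shape:
            raise ValueError("vegetation_code shape mismatch")
        if len(self.confidence_levels) != len(self.confidence_probs):
            raise ValueError("confidence levels/probs length mismatch")
        if abs(sum(self.confidence_probs) - 1.0) > 1e-9:
            raise ValueError("confidence_probs must sum to 1")
        specs = list(self.scenarios.values())
        if not specs:
            raise ValueError("at least one ecoregion scenario required")
        vars0 = list(specs[0].variables)
        for s in specs[1:]:
            if list(s.variables) != vars0:
                raise ValueError("all ecoregion scenarios must share variables")


def benchmark_scene_spec(
    n_ecoregions: int = 50,
    n_weeks: int = 936,
    seed: int = 0,
    tau_td: int = 1,
    tau_bu: int = 30,
) -> tuple[SceneSpec, dict[str, dict]]:
    """Standard end-to-end benchmark scene with planted dominance.

    Half the ecoregions are planted top-down dominant (a strong
    ``ET0 -> BA`` link at lag ``tau_td``), half bottom-up dominant (a
    strong ``SWDI -> BA`` link at lag ``tau_bu``); each ecoregion also
    carries a weaker cross-group link.  Panels are 936 weeks (18 years
    of weekly data, the 2003-2020 study span), with seasonal cycle,
    weak trend, a zero-inflated skewed burned-area marginal, per-pixel
    noise, and a confidence layer that masks ~15% of pixel-weeks at
    the 70% threshold.  Each ecoregion occupies a 2x2 pixel block.

    Returns the scene spec and a mapping ecoregion id -> planted truth
    (dominant group, precursor and lag).
    """
    if n_ecoregions < 2:
        raise ValueError("need at least 2 ecoregions")
    rows, cols = 2, 2 * n_ecoregions
    climate = np.empty((rows, cols), dtype=object)
    vegetation = np.empty((rows, cols), dtype=object)
    scenarios: dict[str, ScenarioSpec] = {}
    truth: dict[str, dict] = {}
    veg_cycle = ("grassland", "shrubland", "TBE", "TNE")
    for k in range(n_ecoregions):
        cz = f"C{k:02d}"
        vt = veg_cycle[k % len(veg_cycle)]
        climate[:, 2 * k : 2 * k + 2] = cz
        vegetation[:, 2 * k : 2 * k + 2] = vt
        top_down_dominant = k < n_ecoregions // 2
        if top_down_dominant:
            links = [
                PlantedLink("ET0", "BA", tau_td, 0.8),
                PlantedLink("SWDI", "BA", tau_bu, 0.35),
            ]
            dom = ("top-down", "ET0", tau_td)
        else:
            links = [
                PlantedLink("SWDI", "BA", tau_bu, 0.8),
                PlantedLink("ET0", "BA", tau_td, 0.35),
            ]
            dom = ("bottom-up", "SWDI", tau_bu)
        key = ecoregion_id(cz, vt)
        scenarios[key] = ScenarioSpec(
            variables=dict(STANDARD_VARIABLES),
            links=links,
            noise_sd=1.0,
            seasonal_amplitude=1.0,
            trend_slope=0.001,
            n_weeks=n_weeks,
            seed=seed + k,
            ba_zero_inflation=0.15,
            ba_skew_transform=True,
            tau_max=max(tau_td, tau_bu),
        )
        truth[key] = {
            "dominant_group": dom[0],
            "dominant_precursor": dom[1],
            "dominant_lag": dom[2],
        }
    scene = SceneSpec(
        shape=(rows, cols),
        climate_code=climate,
        vegetation_code=vegetation,
        scenarios=scenarios,
        pixel_noise_sd=0.2,
        confidence_levels=(100.0, 40.0),
        confidence_probs=(0.85, 0.15),
        seed=seed,
        lat0=-30.0,
    )
    return scene, truth


def ecoregion_id(climate, vegetation) -> str:
    """Deterministic join of the two classification codes."""
    return f"{climate}|{vegetation}"


def _planted_dominance(spec: ScenarioSpec, latent: np.ndarray) -> dict:
    """Ground-truth dominance: the group owning the planted link into the
    target with the largest absolute standardized effect
    |coef| * sd(source) / sd(target), measured on the latent signal."""
    names = list(spec.variables)
    target = [v for v, g in spec.variables.items() if g == "target"]
    if not target:
        return {"dominant_group": None, "dominant_precursor": None, "dominant_lag": None}
    tname = target[0]
    sds = {v: float(np.std(latent[:, i])) for i, v in enumerate(names)}
    best, best_eff = None, -np.inf
    for lk in spec.links:
        if lk.target != tname or lk.source == tname:
            continue
        eff = abs(lk.coefficient) * sds[lk.source] / max(sds[tname], 1e-300)
        # deterministic tie-break: larger effect, then smaller lag, then name
        key = (eff, -lk.lag, lk.source)
        if best is None or key > (best_eff, -best.lag, best.source):
            best, best_eff = lk, eff
    if best is None:
        return {"dominant_group": None, "dominant_precursor": None, "dominant_lag": None}
    return {
        "dominant_group": spec.variables[best.source],
        "dominant_precursor": best.source,
        "dominant_lag": best.lag,
    }


def generate_gridded_scene(
    scene: SceneSpec,
) -> tuple[xr.Dataset, pd.DataFrame]:
    """Render per-ecoregion scenarios onto a 0.25-degree grid.

    Returns the scene as an xarray Dataset (dims time, lat, lon; one
    data variable per panel variable plus ``confidence``,
    ``climate_code`` and ``vegetation_code``) and a ground-truth table
    with one row per non-empty ecoregion recording which precursor
    group dominates it by construction.
    """
    rows, cols = scene.shape
    first = next(iter(scene.scenarios.values()))
    names = list(first.variables)
    n_weeks = first.n_weeks
    lat = scene.lat0 + 0.25 * np.arange(rows)
    lon = scene.lon0 + 0.25 * np.arange(cols)

    pixel_keys = np.empty(scene.shape, dtype=object)
    for r in range(rows):
        for c in range(cols):
            pixel_keys[r, c] = ecoregion_id(
                scene.climate_code[r, c], scene.vegetation_code[r, c]
            )

    master = np.random.SeedSequence(scene.seed)
    sig_stream, noise_stream, conf_stream = master.spawn(3)

    data = {v: np.full((n_weeks, rows, cols), np.nan) for v in names}
    truth_rows = []
    keys_in_order = sorted(scene.scenarios)
    sig_children = sig_stream.spawn(len(keys_in_order))
    for key, child in zip(keys_in_order, sig_children):
        spec = scene.scenarios[key]
        if spec.n_weeks != n_weeks or list(spec.variables) != names:
            raise ValueError("ecoregion scenarios must share length and variables")
        member = np.argwhere(pixel_keys == key)
        if member.size == 0:
            warnings.warn(f"ecoregion {key} has no pixels; omitted from ground truth")
            continue
        # common ecoregion signal, seeded from the scene's substream so the
        # grid shape cannot perturb it
        sub = ScenarioSpec(
            variables=dict(spec.variables),
            links=list(spec.links),
            noise_sd=spec.noise_sd,
            seasonal_amplitude=spec.seasonal_amplitude,
            seasonal_period=spec.seasonal_period,
            trend_slope=spec.trend_slope,
            n_weeks=spec.n_weeks,
            seed=spec.seed,
            ba_zero_inflation=spec.ba_zero_inflation,
            ba_skew_transform=spec.ba_skew_transform,
            tau_max=spec.tau_max,
        )
        children = child.spawn(len(names))
        latent = _simulate_latent(sub, children)
        obs = latent + _season_trend(sub)
        tvars = [v for v, g in sub.variables.items() if g == "target"]
        if sub.ba_skew_transform and tvars:
            ti = names.index(tvars[0])
            obs[:, ti] = _apply_ba_marginal(obs[:, ti], sub.ba_zero_inflation)
        for r, c in member:
            prng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=scene.seed, spawn_key=(10_000 + r * cols + c,)
                )
            )
            noise = (
                prng.normal(0.0, scene.pixel_noise_sd, size=obs.shape)
                if scene.pixel_noise_sd > 0
                else 0.0
            )
            for i, v in enumerate(names):
                px = obs[:, i] + (noise[:, i] if np.ndim(noise) else 0.0)
                if sub.ba_skew_transform and tvars and v == tvars[0]:
                    px = np.maximum(px, 0.0)  # burned area cannot go negative
                data[v][:, r, c] = px
        truth = _planted_dominance(sub, latent)
        truth_rows.append(
            {
                "ecoregion": key,
                "n_pixels": int(member.shape[0]),
                **truth,
            }
        )

    conf_rng = np.random.default_rng(conf_stream)
    confidence = conf_rng.choice(
        np.asarray(scene.confidence_levels, dtype=float),
        size=(n_weeks, rows, cols),
        p=np.asarray(scene.confidence_probs, dtype=float),
    )

    ds = xr.Dataset(
        {v: (("time", "lat", "lon"), data[v]) for v in names}
        | {
            "confidence": (("time", "lat", "lon"), confidence),
            "climate_code": (("lat", "lon"), scene.climate_code),
            "vegetation_code": (("lat", "lon"), scene.vegetation_code),
        },
        coords={"time": np.arange(n_weeks), "lat": lat, "lon": lon},
        attrs={"seed": scene.seed, "variables": ",".join(names)},
    )
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["ecoregion", "n_pixels", "dominant_group", "dominant_precursor", "dominant_lag"],
    )
    return ds, truth_df
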