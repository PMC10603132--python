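"""Two-stage lagged causal discovery with linear partial correlation.

The procedure operates on a weekly anomaly panel and recovers a lagged
causal graph in two stages:

1. **Condition selection** (PC stage): for each variable, an iterative
   Markov-set discovery loop removes irrelevant lagged candidates.
   Starting from all (variable, lag) pairs with lag in
   [max(tau_min, 1), tau_max], each sweep conditions every candidate on
   the q currently strongest other candidates and removes those whose
   conditional-independence p-value exceeds ``pc_alpha``; q grows from
   0 to ``q_max``.

2. **Momentary conditional independence** (MCI stage): every ordered
   lagged pair (X at t-tau, Y at t) is tested conditioned on the
   selected parents of Y (excluding the tested link) together with the
   lag-shifted selected parents of X, each side truncated to the
   ``max_conds`` strongest.  Conditioning on both parent sets controls
   false positives due to autocorrelation and acts as the second
   stage's false-positive control.

The conditional-independence statistic throughout is linear partial
correlation: the Pearson correlation of the OLS residuals of the two
tested series on the conditioning set (with intercept), with a
two-sided t test on n - |Z| - 2 degrees of freedom.

The estimator is organised in the style of statsmodels:
:class:`LaggedCausalModel` is constructed from a panel and a
configuration and its :meth:`~LaggedCausalModel.fit` returns a
:class:`CausalDiscoveryResults` carrying the retained links, the full
audit matrices of partial correlations and p-values, and ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import special

from .panel import Panel

__all__ = [
    "PCMCIConfig",
    "CITestResult",
    "partial_correlation",
    "pc_condition_selection",
    "mci_test_all",
    "run_pcmci",
    "LaggedCausalModel",
    "CausalDiscoveryResults",
]


@dataclass(frozen=True)
class PCMCIConfig:
    """Configuration of the two-stage discovery procedure.

    Defaults reproduce the global wildfire analysis settings: a 0.05
    significance level in both stages and a maximum time lag of 156
    weeks (three years).  ``q_max`` bounds the conditioning-set growth
    of the selection stage and ``max_conds`` caps the number of
    conditioners taken from each side in the MCI stage; both bound
    compute without changing the algorithm's character.
    """

    alpha: float = 0.05
    tau_max: int = 156
    tau_min: int = 0
    pc_alpha: float | None = None
    q_max: int = 3
    max_conds: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.pc_alpha is not None and not 0.0 < self.pc_alpha < 1.0:
            raise ValueError("pc_alpha must be in (0, 1)")
        if not 0 <= self.tau_min <= self.tau_max:
            raise ValueError("need 0 <= tau_min <= tau_max")
        if self.q_max < 0 or self.max_conds < 0:
            raise ValueError("q_max and max_conds must be >= 0")

    @property
    def pc_level(self) -> float:
        return self.alpha if self.pc_alpha is None else self.pc_alpha


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test."""

    statistic: float  # partial correlation in [-1, 1]
    pvalue: float
    n_eff: int  # sample size after listwise deletion
    n_conds: int  # conditioning-set size actually used
    degenerate: bool = False


def _t_pvalue(rho: float, dof: int) -> float:
    """Two-sided p-value of a partial correlation on ``dof`` degrees of
    freedom via the exact t transform."""
    if dof <= 0:
        return 1.0
    r2 = min(rho * rho, 1.0)
    if r2 >= 1.0:
        return 0.0
    t = abs(rho) * np.sqrt(dof / (1.0 - r2))
    return float(2.0 * special.stdtr(dof, -t))


# ----------------------------------------------------------------------
def partial_correlation(x, y, Z=None) -> CITestResult:
    """Linear partial correlation of ``x`` and ``y`` given the series in
    ``Z``, with a two-sided t test.

    Rows with a missing value in any involved series are deleted
    listwise.  The statistic is the Pearson correlation of the OLS
    residuals of x and y on Z (with intercept), computed with a
    rank-revealing least-squares solve so collinear conditioners are
    effectively dropped (with a warning).  Degenerate inputs
    (zero-variance residuals) yield statistic 0 and p-value 1, flagged.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    zs = [np.asarray(z, dtype=float).ravel() for z in (Z or [])]
    n0 = x.size
    if y.size != n0 or any(z.size != n0 for z in zs):
        raise ValueError("x, y and all conditioners must have equal length")
    cols = np.column_stack([x, y, *zs]) if zs else np.column_stack([x, y])
    ok = ~np.isnan(cols).any(axis=1)
    cols = cols[ok]
    n = cols.shape[0]
    q = len(zs)
    if n - q - 2 < 10:
        raise ValueError(
            f"insufficient sample: n={n} with {q} conditioners (need n - q - 2 >= 10)"
        )
    design = np.column_stack([np.ones(n), cols[:, 2:]]) if q else np.ones((n, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "collinear conditioners detected; redundant ones dropped",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, cols[:, :2], rcond=None)
    resid = cols[:, :2] - design @ beta
    sx = float(np.sqrt(resid[:, 0] @ resid[:, 0]))
    sy = float(np.sqrt(resid[:, 1] @ resid[:, 1]))
    q_eff = rank - 1
    if sx <= 0.0 or sy <= 0.0:
        return CITestResult(0.0, 1.0, n, q_eff, degenerate=True)
    rho = float(np.clip((resid[:, 0] @ resid[:, 1]) / (sx * sy), -1.0, 1.0))
    return CITestResult(rho, _t_pvalue(rho, n - q_eff - 2), n, q_eff)


# ----------------------------------------------------------------------
class _LagEngine:
    """Fast lagged partial-correlation tests over one panel.

    All columns for a test are taken from the common window
    t in [max involved lag, T); rows with any missing value among the
    involved columns are deleted listwise.  The partial correlation is
    evaluated through the inverse of the sample covariance of the
    involved columns (algebraically identical to the double-regression
    residual form, but one small matrix inversion per test).
    """

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        self.T, self.N = self.values.shape
        self.has_nan = bool(np.isnan(self.values).any())

    def pcorr(self, xi, xlag, yj, conds):
        """rho, p, n for X_{t-xlag} vs Y_t given lagged conditioners.

        ``conds`` is a sequence of (variable index, lag) pairs, lags
        measured backwards from the target time t.  Returns
        (nan, nan, n) when the effective sample is too small.
        """
        vals = self.values
        lags = [xlag, 0, *(l for _, l in conds)]
        start = max(lags)
        n_win = self.T - start
        k = 2 + len(conds)
        if n_win - k < 10:
            return np.nan, np.nan, n_win
        a = np.empty((n_win, k))
        a[:, 0] = vals[start - xlag : self.T - xlag, xi]
        a[:, 1] = vals[start : self.T, yj]
        for m, (ci, cl) in enumerate(conds):
            a[:, 2 + m] = vals[start - cl : self.T - cl, ci]
        if self.has_nan:
            ok = ~np.isnan(a).any(axis=1)
            if not ok.all():
                a = a[ok]
        n = a.shape[0]
        if n - k < 10:
            return np.nan, np.nan, n
        a = a - a.mean(axis=0)
        c = a.T @ a
        try:
            prec = np.linalg.inv(c)
            d0, d1 = prec[0, 0], prec[1, 1]
            if d0 <= 0.0 or d1 <= 0.0:
                raise np.linalg.LinAlgError
            rho = float(np.clip(-prec[0, 1] / np.sqrt(d0 * d1), -1.0, 1.0))
        except np.linalg.LinAlgError:
            # singular covariance: fall back to the rank-revealing path
            res = partial_correlation(a[:, 0], a[:, 1], list(a[:, 2:].T))
            return res.statistic, res.pvalue, n
        return rho, _t_pvalue(rho, n - k), n


# ----------------------------------------------------------------------
def _pc_select_indices(
    engine: _LagEngine, target: int, cfg: PCMCIConfig
) -> tuple[list[tuple[int, int]], dict[tuple[int, int], float]]:
    """PC condition-selection loop for one target variable (by index).

    Returns the surviving (variable, lag) parents sorted by descending
    minimum absolute partial correlation across their tests, plus the
    per-candidate minimum |rho| map.
    """
    level = cfg.pc_level
    tau_lo = max(cfg.tau_min, 1)
    strength: dict[tuple[int, int], float] = {}
    surviving: list[tuple[int, int]] = []
    for i in range(engine.N):
        for tau in range(tau_lo, cfg.tau_max + 1):
            rho, p, _ = engine.pcorr(i, tau, target, [])
            if np.isnan(p) or p > level:
                continue
            strength[(i, tau)] = abs(rho)
            surviving.append((i, tau))

    for q in range(1, cfg.q_max + 1):
        if len(surviving) - 1 < q:
            break
        order = sorted(surviving, key=lambda c: (-strength[c], c))
        keep: list[tuple[int, int]] = []
        for cand in order:
            conds = [c for c in order if c != cand][:q]
            rho, p, _ = engine.pcorr(cand[0], cand[1], target, conds)
            if np.isnan(p):
                continue
            strength[cand] = min(strength[cand], abs(rho))
            if p <= level:
                keep.append(cand)
        if len(keep) == len(surviving):
            surviving = keep
            continue
        surviving = keep
    surviving = sorted(surviving, key=lambda c: (-strength[c], c))
    return surviving, strength


def pc_condition_selection(
    panel: Panel, target: str, cfg: PCMCIConfig | None = None
) -> list[tuple[str, int, float]]:
    """Select the lagged causal parents of ``target`` in the panel.

    Returns (variable, lag, min |partial correlation|) triples sorted
    by descending strength; an empty list is a valid outcome (no
    causal relationship detected).
    """
    cfg = cfg or PCMCIConfig()
    engine = _LagEngine(panel.values)
    j = panel.variables.index(target)
    parents, strength = _pc_select_indices(engine, j, cfg)
    return [(panel.variables[i], tau, strength[(i, tau)]) for i, tau in parents]


# ----------------------------------------------------------------------
def _mci_matrices(
    engine: _LagEngine,
    parents: dict[int, list[tuple[int, int]]],
    cfg: PCMCIConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MCI tests over every ordered (source, target, lag) triple.

    Conditioning set: parents of the target minus the tested link, plus
    the parents of the source shifted by the tested lag, each side
    truncated to the ``max_conds`` strongest, duplicates removed.
    """
    n = engine.N
    n_lags = cfg.tau_max + 1
    rho = np.full((n, n, n_lags), np.nan)
    pval = np.full((n, n, n_lags), np.nan)
    neff = np.full((n, n, n_lags), np.nan)
    for j in range(n):
        pj = parents[j]
        for i in range(n):
            pi_shift_base = parents[i][: cfg.max_conds]
            lo = cfg.tau_min if i != j else max(cfg.tau_min, 1)
            for tau in range(lo, cfg.tau_max + 1):
                conds_y = [c for c in pj if c != (i, tau)][: cfg.max_conds]
                conds_x = [(w, s + tau) for w, s in pi_shift_base]
                conds: list[tuple[int, int]] = []
                seen = {(i, tau), (j, 0)}
                for c in conds_y + conds_x:
                    if c not in seen:
                        conds.append(c)
                        seen.add(c)
                r, p, m = engine.pcorr(i, tau, j, conds)
                rho[i, j, tau] = r
                pval[i, j, tau] = p
                neff[i, j, tau] = m
    return rho, pval, neff


def mci_test_all(
    panel: Panel,
    parents: dict[str, list[tuple[str, int]]],
    cfg: PCMCIConfig | None = None,
) -> xr.Dataset:
    """Momentary conditional-independence tests for all lagged pairs.

    ``parents`` maps each variable to its selected (parent, lag) list,
    strongest first, as produced by :func:`pc_condition_selection`.
    Returns an xarray Dataset with ``rho``, ``pvalue`` and ``n_eff``
    over dimensions (source, target, lag); entries that are untested
    (a variable with itself at lag 0) or had insufficient effective
    sample are NaN.
    """
    cfg = cfg or PCMCIConfig()
    names = panel.variables
    idx = {v: i for i, v in enumerate(names)}
    pidx = {
        idx[v]: [(idx[w], l) for w, l in parents.get(v, [])] for v in names
    }
    engine = _LagEngine(panel.values)
    rho, pval, neff = _mci_matrices(engine, pidx, cfg)
    return xr.Dataset(
        {
            "rho": (("source", "target", "lag"), rho),
            "pvalue": (("source", "target", "lag"), pval),
            "n_eff": (("source", "target", "lag"), neff),
        },
        coords={"source": names, "target": names, "lag": np.arange(cfg.tau_max + 1)},
    )


# ----------------------------------------------------------------------
class LaggedCausalModel:
    """Two-stage lagged causal discovery model over a weekly panel.

    Parameters
    ----------
    panel
        Preprocessed panel (detrended weekly anomalies); one variable
        may be tagged ``target`` (burned area), the rest are precursors.
    config
        :class:`PCMCIConfig`; defaults to the global-analysis settings.

    Examples
    --------
    >>> model = LaggedCausalModel(panel, PCMCIConfig(tau_max=10))
    >>> res = model.fit()
    >>> res.links  # DataFrame of retained lagged links
    """

    def __init__(self, panel: Panel, config: PCMCIConfig | None = None):
        if panel.n_weeks <= (config.tau_max if config else 156) + 50:
            raise ValueError("panel too short for the configured tau_max")
        self.panel = panel
        self.config = config or PCMCIConfig()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        groups: dict[str, str] | None = None,
        target: str | None = None,
        config: PCMCIConfig | None = None,
    ) -> "LaggedCausalModel":
        """Build the model from a wide DataFrame (one column per series).

        If ``groups`` is omitted, ``target`` names the response and all
        other columns are tagged top-down by default.
        """
        if groups is None:
            groups = {
                c: ("target" if c == target else "top-down") for c in data.columns
            }
        return cls(Panel(data.reset_index(drop=True), groups), config)

    # ------------------------------------------------------------------
    def fit(self) -> "CausalDiscoveryResults":
        """Run condition selection then MCI; retain significant links.

        Retention rules: p <= alpha; lag-0 links between two non-target
        variables are discarded (no contemporaneous orientation
        information); lag-0 precursor-target associations are oriented
        precursor -> target a priori (same-week weather/fuel can affect
        burning; reverse same-week causation is excluded by fiat).
        The procedure has no internal randomness.
        """
        cfg = self.config
        names = self.panel.variables
        engine = _LagEngine(self.panel.values)
        parents_idx: dict[int, list[tuple[int, int]]] = {}
        strengths: dict[int, dict[tuple[int, int], float]] = {}
        for j in range(len(names)):
            parents_idx[j], strengths[j] = _pc_select_indices(engine, j, cfg)
        rho, pval, neff = _mci_matrices(engine, parents_idx, cfg)

        target = self.panel.target
        tgt_idx = names.index(target) if target is not None else None
        rows = []
        for i, src in enumerate(names):
            for j, dst in enumerate(names):
                for tau in range(cfg.tau_min, cfg.tau_max + 1):
                    p = pval[i, j, tau]
                    if np.isnan(p) or p > cfg.alpha:
                        continue
                    if tau == 0:
                        if tgt_idx is None or (i != tgt_idx and j != tgt_idx):
                            continue  # contemporaneous non-target pair
                        if i == tgt_idx:
                            continue  # orient lag-0 links toward the target
                    rows.append(
                        {
                            "source": src,
                            "target": dst,
                            "lag": tau,
                            "rho": float(rho[i, j, tau]),
                            "pvalue": float(p),
                            "n_eff": int(neff[i, j, tau]),
                        }
                    )
        links = pd.DataFrame(
            rows, columns=["source", "target", "lag", "rho", "pvalue", "n_eff"]
        )
        links = links.sort_values(
            ["target", "pvalue", "lag", "source"], kind="stable"
        ).reset_index(drop=True)
        parents = {
            names[j]: [
                (names[i], tau, strengths[j][(i, tau)]) for i, tau in parents_idx[j]
            ]
            for j in range(len(names))
        }
        audit = xr.Dataset(
            {
                "rho": (("source", "target", "lag"), rho),
                "pvalue": (("source", "target", "lag"), pval),
                "n_eff": (("source", "target", "lag"), neff),
            },
            coords={
                "source": names,
                "target": names,
                "lag": np.arange(cfg.tau_max + 1),
            },
        )
        return CausalDiscoveryResults(self, links, parents, audit)


@dataclass
class CausalDiscoveryResults:
    """Results of a fitted :class:`LaggedCausalModel`.

    Attributes
    ----------
    links
        Retained lagged links (p <= alpha) with source, target, lag,
        partial correlation ``rho``, ``pvalue`` and effective sample.
    parents
        Per-variable selected parents (variable, lag, min |rho|).
    audit
        Full rho / p-value / effective-sample matrices over
        (source, target, lag), for every tested triple — the retained
        links are exactly the significant, orientation-admissible
        entries of these matrices.
    """

    model: LaggedCausalModel
    links: pd.DataFrame
    parents: dict[str, list[tuple[str, int, float]]]
    audit: xr.Dataset

    @property
    def config(self) -> PCMCIConfig:
        return self.model.config

    @property
    def variables(self) -> list[str]:
        return self.model.panel.variables

    def links_to(self, target: str) -> pd.DataFrame:
        """Retained links pointing into ``target`` (e.g. burned area)."""
        out = self.links[
            (self.links["target"] == target) & (self.links["source"] != target)
        ]
        return out.reset_index(drop=True)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the fit."""
        cfg = self.config
        lines = [
            "Lagged causal discovery (PC condition selection + MCI, partial correlation)",
            "=" * 74,
            f"Variables: {len(self.variables)}   Weeks: {self.model.panel.n_weeks}",
            f"alpha={cfg.alpha}  pc_alpha={cfg.pc_level}  "
            f"tau=[{cfg.tau_min}, {cfg.tau_max}]  q_max={cfg.q_max}  "
            f"max_conds={cfg.max_conds}",
            f"Retained links: {len(self.links)}",
            "-" * 74,
        ]
        if len(self.links):
            lines.append(
                self.links.to_string(
                    index=False,
                    formatters={
                        "rho": "{:+.3f}".format,
                        "pvalue": "{:.2e}".format,
                    },
                )
            )
        else:
            lines.append("(no significant links)")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def to_json(self, path=None):
        """Edge list [{source, target, lag, rho, pvalue}, ...] as JSON."""
        edges = self.links[["source", "target", "lag", "rho", "pvalue"]].to_dict(
            "records"
        )
        if path is None:
            return json.dumps(edges, indent=1)
        with open(path, "w") as fh:
            json.dump(edges, fh, indent=1)
        return None

    def to_csv(self, path) -> None:
        self.links.to_csv(path, index=False)

    def save_audit(self, path) -> None:
        """Audit matrices as NetCDF (dims: source, target, lag)."""
        self.audit.to_netcdf(path)

    # ------------------------------------------------------------------
    def attribution(self, grouping=None):
        """Dominance attribution of the panel's target (see
        :mod:`firelink.attribution`)."""
        from .attribution import attribute_results

        return attribute_results(self, grouping)

    def plot_links(self, ax=None):  # pragma: no cover - plotting
        """Lag-versus-strength scatter of the retained links into the
        target, colored by precursor group."""
        import matplotlib.pyplot as plt

        target = self.model.panel.target
        table = self.links_to(target) if target else self.links
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        groups = self.model.panel.groups
        colors = {"top-down": "tab:red", "bottom-up": "tab:green", "target": "k"}
        for _, row in table.iterrows():
            g = groups.get(row["source"], "target")
            ax.scatter(row["lag"], row["rho"], color=colors[g], s=30)
            ax.annotate(row["source"], (row["lag"], row["rho"]), fontsize=8)
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("lag (weeks)")
        ax.set_ylabel("MCI partial correlation")
        return ax


def run_pcmci(panel: Panel, cfg: PCMCIConfig | None = None) -> CausalDiscoveryResults:
    """Convenience wrapper: fit a :class:`LaggedCausalModel` on the panel."""
    return LaggedCausalModel(panel, cfg or PCMCIConfig()).fit()
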