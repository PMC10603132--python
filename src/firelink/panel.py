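"""Multivariate weekly time-series panel, the unit of causal discovery.

A :class:`Panel` holds a T-by-N matrix of weekly values together with a
group tag per variable.  The tags separate the wildfire-activity target
(burned area) from its two precursor families: "top-down" atmospheric
drivers acting on flammability and "bottom-up" vegetation drivers acting
on fuel amount and condition.  Missing entries are NaN and are never
silently dropped; conditional-independence tests apply listwise deletion
over the lagged index sets they actually use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VALID_GROUPS = ("top-down", "bottom-up", "target")


@dataclass
class Panel:
    """Weekly multivariate panel with per-variable group tags.

    Parameters
    ----------
    data
        DataFrame indexed by integer week index (0-based, consecutive),
        one column per variable.  NaN marks missing entries.
    groups
        Mapping variable name -> "top-down" | "bottom-up" | "target".
    meta
        Free-form provenance metadata (preprocessing steps applied,
        scenario seed, ecoregion membership ...).
    """

    data: pd.DataFrame
    groups: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [v for v in self.data.columns if v not in self.groups]
        if missing:
            raise ValueError(f"variables without group tag: {missing}")
        bad = {v: g for v, g in self.groups.items() if g not in VALID_GROUPS}
        if bad:
            raise ValueError(f"invalid group tags: {bad}")

    # ------------------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_weeks(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def target(self) -> str | None:
        """Name of the (single) variable tagged ``target``, or None."""
        targets = [v for v in self.variables if self.groups.get(v) == "target"]
        if len(targets) > 1:
            raise ValueError(f"multiple target variables: {targets}")
        return targets[0] if targets else None

    @property
    def week_of_year(self) -> np.ndarray:
        """Week-of-year labels 1..52 (fixed 52-week years).

        Honors an explicit ``week_of_year`` entry in ``meta`` (e.g. set by
        calendar-aware weekly aggregation); otherwise derives the labels
        from the integer week index assuming the panel starts at week 1.
        """
        woy = self.meta.get("week_of_year")
        if woy is not None:
            return np.asarray(woy, dtype=int)
        idx = np.asarray(self.data.index, dtype=int)
        return (idx % 52) + 1

    # ------------------------------------------------------------------
    def to_tidy_frame(self) -> pd.DataFrame:
        """Long format: columns week_index, variable, value."""
        tidy = self.data.reset_index(names="week_index").melt(
            id_vars="week_index", var_name="variable", value_name="value"
        )
        return tidy.sort_values(["variable", "week_index"]).reset_index(drop=True)

    def to_wide_csv(self, path) -> None:
        self.data.to_csv(path, index_label="week_index")

    def to_tidy_csv(self, path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)

    @classmethod
    def from_wide_csv(cls, path, groups: Mapping[str, str], **meta) -> "Panel":
        df = pd.read_csv(path, index_col="week_index")
        return cls(df, dict(groups), dict(meta))

    def copy(self) -> "Panel":
        return Panel(self.data.copy(), dict(self.groups), dict(self.meta))
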