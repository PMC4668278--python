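"""Plot-level above-ground-biomass (AGB) field estimates and inclusion filters.

Field crews record diameter at breast height (DBH) for every tree on a
fixed-radius circular plot; a power-law allometry converts each DBH to
tree biomass, tree biomass is totaled per plot and scaled to Mg/ha.
Two inclusion filters mirror common inventory practice:

* plots whose AGB field estimate exceeds 1500 Mg/ha are flagged as
  outliers (allometric extrapolation on a few very thick stems can blow
  up plot-level volume);
* the robustness analysis keeps only a comparable stratum — plots in
  community-owned, closed-canopy forest — because the two field
  campaigns had different scopes.

Canopy closure is classified from LiDAR canopy cover with a strict 70 %
rule: a plot is "closed" iff cover > 0.70.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

OUTLIER_THRESHOLD = 1500.0   # Mg/ha
CANOPY_CLOSED_COVER = 0.70   # strict: closed iff cover > 0.70
DEFAULT_ALLOMETRY = (0.1, 2.4)  # AGB[kg] = a * dbh[cm]**b

PLOT_RADII = (8.92, 12.62)   # m: community / professional designs


def tree_agb(dbh, params: tuple[float, float] = DEFAULT_ALLOMETRY):
    """Single-tree above-ground biomass in kg from DBH in cm.

    A two-parameter power law ``AGB = a * dbh**b``; ``params`` is ``(a, b)``.
    Accepts scalars or arrays; strictly increasing in DBH for b > 0.
    """
    a, b = params
    dbh_arr = np.asarray(dbh, dtype=float)
    if np.any(dbh_arr <= 0):
        raise ConfigError("dbh must be positive")
    out = a * dbh_arr ** b
    return float(out) if np.isscalar(dbh) or dbh_arr.ndim == 0 else out


def plot_area_ha(radius: float) -> float:
    """Area of a circular plot in hectares."""
    if radius <= 0:
        raise ConfigError("plot radius must be positive")
    return math.pi * radius ** 2 / 10_000.0


def plot_agb(trees: pd.DataFrame, radius: float,
             params: tuple[float, float] = DEFAULT_ALLOMETRY,
             include_dead: bool = True) -> float:
    """Plot AGB in Mg/ha from per-tree DBH records.

    ``trees`` needs a ``dbh`` column (cm) and, optionally, an ``alive``
    boolean column.  Dead trees are measured and included by default;
    set ``include_dead=False`` to restrict to living stems.  An empty
    plot has 0 Mg/ha.
    """
    area = plot_area_ha(radius)
    if len(trees) == 0:
        return 0.0
    sel = trees
    if not include_dead and "alive" in trees.columns:
        sel = trees[trees["alive"].astype(bool)]
    if len(sel) == 0:
        return 0.0
    total_kg = float(np.sum(tree_agb(sel["dbh"].to_numpy(float), params)))
    return (total_kg / 1000.0) / area


def plot_agb_table(trees: pd.DataFrame, plots: pd.DataFrame,
                   params: tuple[float, float] = DEFAULT_ALLOMETRY,
                   include_dead: bool = True) -> pd.DataFrame:
    """Aggregate a tree table to plot AGB, joined onto the plot table."""
    for col in ("plot_id", "dbh"):
        if col not in trees.columns:
            raise SchemaError(f"tree table is missing column {col!r}")
    if "radius" not in plots.columns:
        raise SchemaError("plot table is missing column 'radius'")
    out = plots.copy()
    agb = []
    grouped = dict(iter(trees.groupby("plot_id")))
    for rec in out.itertuples(index=False):
        sub = grouped.get(rec.plot_id)
        if sub is None:
            agb.append(0.0)
        else:
            agb.append(plot_agb(sub, rec.radius, params, include_dead))
    out["agb"] = agb
    return out


def filter_outliers(plots: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD,
                    column: str = "agb") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a plot table into (kept, flagged) by the AGB outlier rule.

    Flags rows strictly above ``threshold`` (a plot at exactly 1500 Mg/ha
    is kept).  Row order is preserved in both outputs and
    ``len(kept) + len(flagged) == len(plots)``.
    """
    if threshold <= 0:
        raise ConfigError("outlier threshold must be positive")
    if column not in plots.columns:
        raise SchemaError(f"plot table is missing column {column!r}")
    mask = plots[column].to_numpy(float) > threshold
    return plots.loc[~mask], plots.loc[mask]


def filter_strata(plots: pd.DataFrame,
                  ownership: str = "community",
                  canopy: str = "closed") -> pd.DataFrame:
    """Keep only plots in the comparable stratum (default: community-owned,
    closed-canopy forest)."""
    for col in ("ownership", "canopy"):
        if col not in plots.columns:
            raise SchemaError(f"plot table is missing column {col!r}")
        bad = plots[plots[col].isna()]
        if len(bad):
            ids = bad["plot_id"].tolist()[:10] if "plot_id" in bad else bad.index.tolist()[:10]
            raise SchemaError(f"plots with missing {col!r} label: {ids}")
    mask = (plots["ownership"] == ownership) & (plots["canopy"] == canopy)
    return plots.loc[mask]


def classify_canopy(cover: float) -> str:
    """Map a canopy-cover fraction to 'closed' (cover > 0.70) or 'open'."""
    if not 0.0 <= cover <= 1.0:
        raise ConfigError(f"canopy cover must be in [0, 1], got {cover}")
    return "closed" if cover > CANOPY_CLOSED_COVER else "open"


def filter_report(plots: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD
                  ) -> tuple[pd.DataFrame, dict]:
    """Apply both filters and return the surviving table plus a count audit.

    The report records, per (site, team) group when those labels exist,
    how many plots entered, how many were flagged as outliers, how many
    fell outside the community-owned/closed-canopy stratum and how many
    survive; ``kept + outliers + outside_strata == n_in`` always holds.
    """
    kept, flagged = filter_outliers(plots, threshold)
    final = filter_strata(kept) if {"ownership", "canopy"} <= set(plots.columns) else kept
    group_cols = [c for c in ("site", "team") if c in plots.columns]

    def counts(df: pd.DataFrame) -> dict:
        if not group_cols:
            return {"all": len(df)}
        return {"/".join(map(str, k if isinstance(k, tuple) else (k,))): int(v)
                for k, v in df.groupby(group_cols).size().items()}

    report = {
        "n_in": len(plots),
        "n_outliers": len(flagged),
        "n_outside_strata": len(kept) - len(final),
        "n_kept": len(final),
        "kept_by_group": counts(final),
        "outlier_agb": flagged["agb"].tolist() if "agb" in flagged else [],
    }
    assert report["n_kept"] + report["n_outliers"] + report["n_outside_strata"] == report["n_in"]
    return final, report
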