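"""Annual diversity-change rates and the dry/wet plot grouping."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "annual_rate",
    "classify_wet_dry",
    "rate_table",
    "ba_change_diagnostics",
    "DRY_WET_THRESHOLD_MM",
]

DRY_WET_THRESHOLD_MM = -250.0
MIN_INTERVAL_YEARS = 10.0


def annual_rate(x1: float, x2: float, t1: float, t2: float) -> float:
    """Per-year rate of change ``(x2 - x1) / (t2 - t1)`` (decimal years)."""
    if t2 - t1 <= 0:
        raise ValueError(f"census interval must be positive, got {t2 - t1}")
    return (x2 - x1) / (t2 - t1)


def classify_wet_dry(mcwd_t1: float, threshold: float = DRY_WET_THRESHOLD_MM) -> str:
    """Group a plot by its first-period MCWD: dry iff MCWD <= -250 mm."""
    if not np.isfinite(mcwd_t1):
        raise ValueError("MCWD must be finite")
    return "dry" if mcwd_t1 <= threshold else "wet"


def rate_table(
    diversity: pd.DataFrame,
    mcwd_t1: pd.Series,
    facets: tuple[str, ...] = ("fdis", "simpson", "mpd"),
    threshold: float = DRY_WET_THRESHOLD_MM,
) -> pd.DataFrame:
    """Per-plot annual rates of change and dry/wet group membership.

    ``diversity`` holds one row per plot-census (columns ``plot_id``,
    ``census_date`` and the facet values); every plot needs exactly two
    censuses at least ``10`` years apart. ``mcwd_t1`` maps plot to its
    first-window MCWD (mm).
    """
    rows = []
    for plot, sub in diversity.groupby("plot_id"):
        sub = sub.sort_values("census_date")
        if len(sub) != 2:
            raise ValueError(f"plot {plot} has {len(sub)} censuses, need 2")
        t1, t2 = float(sub["census_date"].iloc[0]), float(sub["census_date"].iloc[1])
        interval = t2 - t1
        if interval < MIN_INTERVAL_YEARS:
            logger.warning(
                "plot %s census interval %.1f yr is below the 10-yr criterion",
                plot, interval,
            )
        row = {"plot_id": plot, "interval": interval,
               "group": classify_wet_dry(float(mcwd_t1[plot]), threshold)}
        for f in facets:
            row[f"d_{f}_r"] = annual_rate(
                float(sub[f].iloc[0]), float(sub[f].iloc[1]), t1, t2
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot_id")


def ba_change_diagnostics(
    ba_change: pd.Series, rates: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of plot basal-area change with each rate facet.

    A diagnostic that diversity-change rates are not an artefact of stand
    growth or loss; returns r and the two-sided p-value per facet.
    """
    if len(ba_change) < 3:
        raise ValueError("need >= 3 plots for correlation diagnostics")
    out = []
    for col in rates.columns:
        if not col.startswith("d_") or not col.endswith("_r"):
            continue
        x = ba_change.loc[rates.index].to_numpy(dtype=float)
        y = rates[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("zero-variance input for %s; correlation missing", col)
            out.append({"facet": col, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(x, y)
        out.append({"facet": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(out).set_index("facet")
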