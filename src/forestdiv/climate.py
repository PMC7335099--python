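"""Water-deficit and drought metrics from monthly plot climate series.

The climatological water deficit (CWD) is a running monthly balance
``WD_m = min(0, WD_{m-1} + P_m - PET_m)`` reset to zero at the start of each
hydrological year (anchored at the climatologically wettest calendar month).
MCWD for a year is the most negative CWD of its 12 months; over a window it
is the mean of yearly minima (a climatology). SPEI standardizes 12-month
rolling sums of P - PET through a per-calendar-month three-parameter
log-logistic distribution fitted by L-moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateSeries",
    "ClimateSummary",
    "DriverChange",
    "cwd_series",
    "mcwd",
    "spei",
    "vpd_summary",
    "driver_changes",
    "WINDOW_T1",
    "WINDOW_T2",
    "WINDOW_FULL",
]

WINDOW_T1 = (1964, 1993)
WINDOW_T2 = (1984, 2013)
WINDOW_FULL = (1964, 2013)


class ClimateSeries:
    """Contiguous monthly precipitation / PET / VPD records for one plot.

    Parameters
    ----------
    plot_id : str
    frame : pandas.DataFrame
        Columns ``year, month, precip_mm, pet_mm, vpd_kpa`` sorted by time
        with no gaps. Precipitation and PET must be non-negative.
    """

    def __init__(self, plot_id: str, frame: pd.DataFrame):
        req = {"year", "month", "precip_mm", "pet_mm", "vpd_kpa"}
        if not req <= set(frame.columns):
            raise ValueError(f"climate frame must have columns {sorted(req)}")
        frame = frame.sort_values(["year", "month"]).reset_index(drop=True)
        seq = frame["year"].to_numpy() * 12 + (frame["month"].to_numpy() - 1)
        if len(seq) and np.any(np.diff(seq) != 1):
            raise ValueError(f"climate series of plot {plot_id} has gaps")
        if (frame["precip_mm"] < 0).any() or (frame["pet_mm"] < 0).any():
            raise ValueError("precipitation and PET must be >= 0")
        self.plot_id = plot_id
        self.frame = frame

    @property
    def years(self) -> tuple[int, int]:
        return int(self.frame["year"].iloc[0]), int(self.frame["year"].iloc[-1])

    def window(self, window: tuple[int, int]) -> pd.DataFrame:
        y0, y1 = window
        lo, hi = self.years
        if y0 < lo or y1 > hi:
            raise ValueError(
                f"window {window} outside series coverage {self.years}"
            )
        f = self.frame
        return f[(f["year"] >= y0) & (f["year"] <= y1)]

    def wettest_month(self) -> int:
        """Calendar month with the highest full-period mean precipitation."""
        clim = self.frame.groupby("month")["precip_mm"].mean()
        return int(clim.idxmax())  # idxmax breaks ties at the earliest month


@dataclass
class ClimateSummary:
    plot_id: str
    window: tuple[int, int]
    mcwd: float          # mm, <= 0
    vpd_mean: float      # kPa
    spei_mean: float     # dimensionless


@dataclass
class DriverChange:
    plot_id: str
    d_mcwd_abs: float    # MCWD_T2 - MCWD_T1, mm
    d_vpd_abs: float     # kPa
    d_spei_abs: float    # dimensionless
    mcwd_full: float     # mm


def cwd_series(series: ClimateSeries, mode: str = "cumulative") -> pd.Series:
    """Monthly climatological water deficit (mm, <= 0).

    ``mode="cumulative"`` runs the reset recursion described in the module
    docstring; ``mode="monthly"`` is the literal month-by-month reading
    ``min(0, P - PET)`` without carry-over.
    """
    f = series.frame
    p = f["precip_mm"].to_numpy(dtype=float)
    pet = f["pet_mm"].to_numpy(dtype=float)
    months = f["month"].to_numpy()
    if mode == "monthly":
        return pd.Series(np.minimum(0.0, p - pet), index=f.index, name="cwd")
    if mode != "cumulative":
        raise ValueError(f"unknown cwd mode {mode!r}")
    anchor = series.wettest_month()
    wd = np.empty(len(p))
    prev = 0.0
    for i in range(len(p)):
        if months[i] == anchor:
            prev = 0.0
        prev = min(0.0, prev + p[i] - pet[i])
        wd[i] = prev
    return pd.Series(wd, index=f.index, name="cwd")


def _yearly_minima(series: ClimateSeries, mode: str) -> pd.Series:
    """Most negative CWD per hydrological year (keyed by starting year)."""
    cwd = cwd_series(series, mode=mode)
    f = series.frame
    anchor = series.wettest_month() if mode == "cumulative" else 1
    # hydrological year y spans anchor..anchor+11; label by calendar year of
    # its starting month
    hyear = f["year"].to_numpy() + (f["month"].to_numpy() < anchor) * -1
    vals = pd.Series(cwd.to_numpy())
    out = vals.groupby(hyear).min()
    counts = vals.groupby(hyear).size()
    return out[counts == 12]


def mcwd(
    series: ClimateSeries, window: tuple[int, int], mode: str = "cumulative"
) -> float:
    """Climatological MCWD: mean of yearly CWD minima over a year window."""
    series.window(window)  # validates coverage
    minima = _yearly_minima(series, mode)
    sel = minima[(minima.index >= window[0]) & (minima.index <= window[1])]
    if sel.empty:
        raise ValueError(f"no complete hydrological years inside {window}")
    return float(sel.mean())


# ---------------------------------------------------------------------------
# SPEI: 12-month rolling P - PET, per-calendar-month log-logistic (L-moments)
# ---------------------------------------------------------------------------

def _loglogistic_pwm(x: np.ndarray):
    """3-parameter log-logistic fit from probability-weighted moments.

    Returns (alpha, beta, gamma) of
    ``F(x) = [1 + (alpha / (x - gamma))**beta]**-1`` or None when the fit is
    degenerate (zero spread, invalid shape).
    """
    x = np.sort(x)
    n = len(x)
    F = (np.arange(1, n + 1) - 0.35) / n
    w0 = x.mean()
    w1 = np.sum(x * (1 - F)) / n
    w2 = np.sum(x * (1 - F) ** 2) / n
    den = 6 * w1 - w0 - 6 * w2
    if den == 0:
        return None
    beta = (2 * w1 - w0) / den
    if beta <= 0:
        return None
    try:
        g1 = gamma_fn(1 + 1 / beta)
        g2 = gamma_fn(1 - 1 / beta)
    except (ValueError, OverflowError):
        return None
    if not (np.isfinite(g1) and np.isfinite(g2)):
        return None
    alpha = (w0 - 2 * w1) * beta / (g1 * g2)
    if alpha <= 0:
        return None
    gamma = w0 - alpha * g1 * g2
    return alpha, beta, gamma


def spei(
    series: ClimateSeries, window_months: int = 12
) -> pd.Series:
    """Standardized precipitation-evapotranspiration index series.

    Monthly ``D = P - PET`` is summed over trailing ``window_months`` windows;
    each calendar month's distribution of window sums is fitted with a
    three-parameter log-logistic (probability-weighted moments) and values
    are mapped through the fitted CDF to standard-normal quantiles. Months
    whose fit is degenerate (for instance zero interannual variance) come
    back as NaN with a warning. The first ``window_months - 1`` entries are
    NaN by construction.
    """
    f = series.frame
    if f["year"].nunique() < 30:
        raise ValueError("SPEI requires at least 30 years of data")
    d = (f["precip_mm"] - f["pet_mm"]).to_numpy(dtype=float)
    roll = pd.Series(d).rolling(window_months).sum().to_numpy()
    months = f["month"].to_numpy()
    out = np.full(len(d), np.nan)
    for m in range(1, 13):
        sel = (months == m) & np.isfinite(roll)
        vals = roll[sel]
        if len(vals) < 10:
            continue
        if np.ptp(vals) == 0:
            logger.warning(
                "plot %s month %d: zero interannual variance; SPEI undefined",
                series.plot_id, m,
            )
            continue
        params = _loglogistic_pwm(vals)
        mirrored = False
        if params is None:
            # left-skewed samples fall outside the (right-skewed) family;
            # fit the mirrored values and map through the complementary CDF
            params = _loglogistic_pwm(-vals)
            mirrored = params is not None
        if params is None:
            logger.warning(
                "plot %s month %d: degenerate log-logistic fit; SPEI missing",
                series.plot_id, m,
            )
            continue
        alpha, beta, gamma = params
        z = (-vals if mirrored else vals) - gamma
        cdf = np.where(
            z > 0, 1.0 / (1.0 + (alpha / np.maximum(z, 1e-12)) ** beta), 0.0
        )
        if mirrored:
            cdf = 1.0 - cdf
        cdf = np.clip(cdf, 1e-8, 1 - 1e-8)
        out[sel] = norm.ppf(cdf)
    return pd.Series(out, index=f.index, name="spei")


def vpd_summary(series: ClimateSeries, window: tuple[int, int]) -> float:
    """Arithmetic mean of monthly VPD (kPa) over an inclusive year window."""
    return float(series.window(window)["vpd_kpa"].mean())


def spei_summary(series: ClimateSeries, window: tuple[int, int]) -> float:
    """Mean SPEI over a window (NaN-aware)."""
    sp = spei(series)
    f = series.frame
    sel = (f["year"] >= window[0]) & (f["year"] <= window[1])
    vals = sp[sel.to_numpy()]
    return float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")


def summarize(
    series: ClimateSeries, window: tuple[int, int], mode: str = "cumulative"
) -> ClimateSummary:
    return ClimateSummary(
        plot_id=series.plot_id,
        window=window,
        mcwd=mcwd(series, window, mode=mode),
        vpd_mean=vpd_summary(series, window),
        spei_mean=spei_summary(series, window),
    )


def driver_changes(
    t1: ClimateSummary, t2: ClimateSummary, full: ClimateSummary
) -> DriverChange:
    """Absolute changes between the two 30-year climatologies.

    ``dX_abs = X_T2 - X_T1``; a drying trend (more negative recent MCWD)
    yields a negative ``d_mcwd_abs``.
    """
    if not (t1.plot_id == t2.plot_id == full.plot_id):
        raise ValueError("summaries belong to different plots")
    for s in (t1, t2, full):
        if not np.isfinite(s.mcwd):
            raise ValueError(f"missing MCWD for window {s.window}")
    return DriverChange(
        plot_id=t1.plot_id,
        d_mcwd_abs=t2.mcwd - t1.mcwd,
        d_vpd_abs=t2.vpd_mean - t1.vpd_mean,
        d_spei_abs=(
            t2.spei_mean - t1.spei_mean
            if np.isfinite(t1.spei_mean) and np.isfinite(t2.spei_mean)
            else float("nan")
        ),
        mcwd_full=full.mcwd,
    )
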