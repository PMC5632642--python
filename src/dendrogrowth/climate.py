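"""Monthly temperature series: lagged standardized design matrices for the
climate-growth models and smoothed monthly anomalies.

The climate-growth models use 15 monthly mean temperatures as candidate
predictors for the ring formed in year t: previous-year August-December and
current-year January-October.  Each column is centred and scaled over the
fitting window, so a coefficient of 0.1 reads as a 10% change in ring-width
index per one standard deviation of that month's temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MonthlyClimate",
    "LagDesign",
    "AnomalySeries",
    "LAG_COLUMNS",
    "build_lag_design",
    "anomaly_smooth",
]

_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

#: the 15 candidate monthly predictors, previous August .. current October
LAG_COLUMNS = tuple(f"prev{_MONTH_ABBR[m - 1]}" for m in range(8, 13)) + \
    tuple(f"cur{_MONTH_ABBR[m - 1]}" for m in range(1, 11))


@dataclass
class MonthlyClimate:
    """Year x month (1..12) mean temperature grid for one site (deg C)."""

    site: str
    years: np.ndarray
    temp: np.ndarray  # shape (n_years, 12)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=np.int64)
        self.temp = np.asarray(self.temp, dtype=float)
        if self.temp.shape != (self.years.size, 12):
            raise ValueError("temp must have shape (n_years, 12)")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive without gaps")

    def value(self, year: int, month: int) -> float:
        return float(self.temp[int(year) - int(self.years[0]), month - 1])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, site: str | None = None) -> "MonthlyClimate":
        """Build from a long table with columns site, year, month, temp_c."""
        need = {"year", "month", "temp_c"}
        if not need <= set(df.columns):
            raise ValueError(f"climate table needs columns {sorted(need)}")
        if site is not None and "site" in df.columns:
            df = df[df["site"] == site]
        elif site is None:
            site = str(df["site"].iloc[0]) if "site" in df.columns else ""
        wide = df.pivot_table(index="year", columns="month", values="temp_c")
        years = wide.index.to_numpy()
        if sorted(wide.columns) != list(range(1, 13)) or wide.isna().any().any():
            raise ValueError("climate table has missing year/month cells")
        return cls(site=site or "", years=years,
                   temp=wide[list(range(1, 13))].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, y in enumerate(self.years):
            for m in range(12):
                rows.append({"site": self.site, "year": int(y),
                             "month": m + 1, "temp_c": self.temp[i, m]})
        return pd.DataFrame(rows)


@dataclass
class LagDesign:
    """Standardized lagged design: one row per usable response year."""

    response_years: np.ndarray
    frame: pd.DataFrame            # indexed by year, 15 columns
    means: pd.Series
    sds: pd.Series
    site: str = ""

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)


@dataclass
class AnomalySeries:
    month: int
    years: np.ndarray
    anomaly: np.ndarray
    smooth: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    ref_period: tuple[int, int]


def build_lag_design(climate: MonthlyClimate,
                     year_range: tuple[int, int] | None = None) -> LagDesign:
    """Standardized 15-column lagged temperature design.

    The row for response year t holds previous-year months Aug-Dec and
    current-year months Jan-Oct; the first usable year is the first climate
    year + 1.  Columns are centred and scaled over the returned years.
    """
    first_usable = int(climate.years[0]) + 1
    last_usable = int(climate.years[-1])
    if year_range is not None:
        lo, hi = int(year_range[0]), int(year_range[1])
        if lo < first_usable or hi > last_usable:
            raise ValueError(
                f"year range {year_range} not covered: climate supports "
                f"{first_usable}-{last_usable} (one prior year is required)")
        first_usable, last_usable = lo, hi
    years = np.arange(first_usable, last_usable + 1)
    if not np.isfinite(climate.temp).all():
        bad = np.argwhere(~np.isfinite(climate.temp))
        gaps = [(int(climate.years[i]), int(m + 1)) for i, m in bad]
        raise ValueError(f"climate has missing months: {gaps[:10]}")
    i0 = years[0] - int(climate.years[0])
    idx = np.arange(i0, i0 + years.size)
    cols = {}
    for m in range(8, 13):
        cols[f"prev{_MONTH_ABBR[m - 1]}"] = climate.temp[idx - 1, m - 1]
    for m in range(1, 11):
        cols[f"cur{_MONTH_ABBR[m - 1]}"] = climate.temp[idx, m - 1]
    raw = pd.DataFrame(cols, index=years)
    means = raw.mean()
    sds = raw.std(ddof=1)
    if (sds == 0).any():
        zero = list(sds.index[sds == 0])
        raise ValueError(f"zero-variance temperature columns: {zero}")
    frame = (raw - means) / sds
    return LagDesign(response_years=years, frame=frame, means=means,
                     sds=sds, site=climate.site)


# ---------------------------------------------------------------------------
# anomalies and local smoothing
# ---------------------------------------------------------------------------

def _local_linear(x: np.ndarray, y: np.ndarray, span: float):
    """Tricube-weighted local linear regression with pointwise variance.

    Returns (fit, var_factor, edf): var(fit_i) = sigma^2 * var_factor_i with
    sigma^2 estimated from the residuals.
    """
    n = x.size
    k = max(int(np.ceil(span * n)), 4)
    fit = np.empty(n)
    var_fac = np.empty(n)
    edf = 0.0
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.partition(d, k - 1)[k - 1]
        h = max(h, 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w > 0
        xs = x[sw] - x[i]
        ws = w[sw]
        ys = y[sw]
        W = np.column_stack([np.ones(xs.size), xs])
        A = (W * ws[:, None]).T @ W
        b = (W * ws[:, None]).T @ ys
        coef = np.linalg.solve(A, b)
        fit[i] = coef[0]
        # l(x_i) row of the smoother: e0' A^-1 W' diag(w)
        l_row = np.linalg.solve(A, (W * ws[:, None]).T)[0]
        var_fac[i] = float(l_row @ l_row)
        ii = np.flatnonzero(sw)
        pos = np.searchsorted(ii, i)
        if pos < ii.size and ii[pos] == i:
            edf += l_row[pos]
    return fit, var_fac, edf


def anomaly_smooth(climate: MonthlyClimate, month: int,
                   ref_period: tuple[int, int] = (1971, 2000),
                   span: float = 0.4) -> AnomalySeries:
    """Monthly anomalies vs a reference-period mean, with a locally weighted
    linear smooth and pointwise 95% confidence band."""
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    lo, hi = int(ref_period[0]), int(ref_period[1])
    if lo < climate.years[0] or hi > climate.years[-1]:
        raise ValueError(f"reference period {ref_period} not covered by climate "
                         f"years {climate.years[0]}-{climate.years[-1]}")
    series = climate.temp[:, month - 1]
    ref_mask = (climate.years >= lo) & (climate.years <= hi)
    anomaly = series - series[ref_mask].mean()
    x = climate.years.astype(float)
    fit, var_fac, edf = _local_linear(x, anomaly, span)
    resid = anomaly - fit
    dof = max(x.size - edf, 2.0)
    sigma2 = float((resid ** 2).sum()) / dof
    half = 1.96 * np.sqrt(sigma2 * var_fac)
    return AnomalySeries(month=month, years=climate.years.copy(),
                         anomaly=anomaly, smooth=fit,
                         ci_low=fit - half, ci_high=fit + half,
                         ref_period=(lo, hi))
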