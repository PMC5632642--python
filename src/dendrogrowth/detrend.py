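"""Ring-width detrending: smoothing-spline indices and regional curve
standardization (RCS) with geometric pith-offset estimation.

Two detrending routes serve two time scales.  For interannual (climate)
analyses each series is divided by a flexible smoothing spline whose
amplitude response is 50% at a 32-year period, removing the age/size trend
together with all slower variability.  For multi-decadal trend analyses,
widths are divided by the population mean width-at-cambial-age curve (RCS),
which preserves low-frequency variability shared across trees; cambial ages
of cores that missed the pith are corrected by a circle-geometry estimate
of the missing inner rings, and cores with more than 10 estimated missing
rings are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .ringwidth_io import RingSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RWISeries",
    "RegionalCurve",
    "PithEstimate",
    "smooth_series",
    "spline_detrend",
    "estimate_pith_offset",
    "apply_pith_exclusion",
    "build_regional_curve",
    "rcs_detrend",
    "truncate_rwi",
    "rwi_frame",
]

#: half the 0.01 mm measurement resolution; zero widths are floored here so
#: ratio indices (and their logs) stay finite
WIDTH_FLOOR_MM = 0.005


@dataclass
class RWISeries:
    """Dimensionless ring-width index series (expected value ~ 1)."""

    series_id: str
    tree_id: str
    first_year: int
    indices: np.ndarray
    method: str                      # {"spline", "rcs"}
    spline_wavelength: float | None = None
    cambial_ages: np.ndarray | None = None
    rc_extended: bool = False        # RCS curve was extended to cover old ages

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=float)
        if np.any(self.indices < 0):
            raise ValueError("indices must be nonnegative")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(self.indices.size)

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class RegionalCurve:
    """Mean ring width by cambial age over a population of series."""

    cambial_age: np.ndarray   # 1..A_max
    mean_width: np.ndarray    # mm
    n_at_age: np.ndarray      # sample depth
    smoothing: str = "none"

    def __call__(self, ages: np.ndarray) -> np.ndarray:
        """Mean width at the requested cambial ages, holding the last value
        for ages beyond the curve (extension is the caller's to record)."""
        ages = np.asarray(ages)
        if np.any(ages < 1):
            raise ValueError("cambial ages start at 1")
        idx = np.minimum(ages, self.cambial_age[-1]) - 1
        return self.mean_width[idx]

    @property
    def max_age(self) -> int:
        return int(self.cambial_age[-1])


@dataclass
class PithEstimate:
    """Geometric estimate of rings missing between core and pith.

    The innermost visible ring arc is treated as a circular segment with
    chord length L and arc height h, giving radius r = (L^2 + 4 h^2)/(8 h);
    the missing-ring count is r divided by the mean of the first five
    measurable ring widths, rounded to the nearest integer.
    """

    chord_length: float
    arc_height: float
    mean_first5_width: float
    estimated_radius_to_pith: float
    missing_rings: int


# ---------------------------------------------------------------------------
# smoothing spline with a 50% frequency-response cutoff
# ---------------------------------------------------------------------------

def _spline_lambda(wavelength: float) -> float:
    """Stiffness giving amplitude response 0.5 at the given period.

    For the discrete smoother minimising ||y - s||^2 + lam ||D2 s||^2 the
    interior frequency response is 1 / (1 + 16 lam sin^4(pi f)), so
    lam = 1 / (16 sin^4(pi / p)) puts the half-power point at period p.
    """
    return 1.0 / (16.0 * np.sin(np.pi / wavelength) ** 4)


def smooth_series(y: np.ndarray, wavelength: float) -> np.ndarray:
    """Cubic-type smoothing spline of an annual series (unit spacing)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        return np.full(n, y.mean())
    lam = _spline_lambda(wavelength)
    # banded (I + lam D2' D2), D2 the (n-2) x n second-difference matrix
    ab = np.zeros((3, n))
    main = np.ones(n)
    main[0] += lam; main[-1] += lam
    main[1] += 5 * lam; main[-2] += 5 * lam
    main[2:-2] += 6 * lam
    off1 = np.full(n - 1, -4.0 * lam)
    off1[0] = -2.0 * lam; off1[-1] = -2.0 * lam
    off2 = np.full(n - 2, lam)
    ab[0, 2:] = off2
    ab[1, 1:] = off1
    ab[2, :] = main
    return solveh_banded(ab, y, lower=False)


def spline_detrend(series: RingSeries, wavelength: float = 32.0) -> RWISeries:
    """Ratio indices from a smoothing-spline fit with 50% response at
    ``wavelength`` years."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    w = series.widths
    if w.size < 5:
        raise ValueError(f"series {series.series_id}: need >= 5 rings to detrend")
    if np.all(w == 0):
        raise ValueError(f"series {series.series_id}: all-zero series")
    fit = smooth_series(w, wavelength)
    fit = np.maximum(fit, WIDTH_FLOOR_MM)
    return RWISeries(series_id=series.series_id, tree_id=series.tree_id,
                     first_year=series.first_year, indices=w / fit,
                     method="spline", spline_wavelength=wavelength)


# ---------------------------------------------------------------------------
# pith-offset geometry
# ---------------------------------------------------------------------------

def estimate_pith_offset(chord_length: float, arc_height: float,
                         mean_first5_width: float) -> PithEstimate:
    """Missing inner rings from the curvature of the innermost ring arc."""
    if chord_length <= 0 or arc_height <= 0 or mean_first5_width <= 0:
        raise ValueError("chord length, arc height and mean width must be positive")
    L, h = float(chord_length), float(arc_height)
    r = (L * L + 4.0 * h * h) / (8.0 * h)
    missing = int(np.floor(r / float(mean_first5_width) + 0.5))
    return PithEstimate(chord_length=L, arc_height=h,
                        mean_first5_width=float(mean_first5_width),
                        estimated_radius_to_pith=r, missing_rings=missing)


def apply_pith_exclusion(series: list[RingSeries], max_missing: int = 10
                         ) -> tuple[list[RingSeries], dict]:
    """Drop series whose estimated missing-ring count exceeds ``max_missing``.

    Pith-hit series pass with offset 0; every other series must carry
    ``pith_offset_rings``.  The exclusion is strict: exactly ``max_missing``
    missing rings is kept, ``max_missing + 1`` is excluded.
    """
    kept, excluded = [], []
    for s in series:
        if s.pith_hit:
            if s.pith_offset_rings is None:
                s.pith_offset_rings = 0
            kept.append(s)
            continue
        if s.pith_offset_rings is None:
            raise ValueError(f"series {s.series_id}: no pith-offset estimate")
        (kept if s.pith_offset_rings <= max_missing else excluded).append(s)
    report = {"kept": len(kept), "excluded": len(excluded),
              "excluded_ids": [s.series_id for s in excluded]}
    if excluded:
        logger.info("pith exclusion: kept %d, excluded %d series",
                    report["kept"], report["excluded"])
    return kept, report


# ---------------------------------------------------------------------------
# regional curve standardization
# ---------------------------------------------------------------------------

def _cambial_ages(s: RingSeries) -> np.ndarray:
    offset = s.pith_offset_rings if s.pith_offset_rings is not None else 0
    return offset + np.arange(s.widths.size) + 1


def build_regional_curve(series: list[RingSeries],
                         smoothing: str | float = "none") -> RegionalCurve:
    """Arithmetic mean ring width at each cambial age across series.

    ``smoothing`` is either ``"none"`` (raw age-aligned mean) or a spline
    wavelength in years applied to the mean curve.
    """
    if not series:
        raise ValueError("need at least one series")
    max_age = max(int(_cambial_ages(s)[-1]) for s in series)
    total = np.zeros(max_age)
    count = np.zeros(max_age, dtype=int)
    for s in series:
        ages = _cambial_ages(s)
        np.add.at(total, ages - 1, s.widths)
        np.add.at(count, ages - 1, 1)
    present = count > 0
    mean = np.full(max_age, np.nan)
    mean[present] = total[present] / count[present]
    # interior ages never observed (offset gaps): fill from neighbours
    if not present.all():
        ages_all = np.arange(1, max_age + 1)
        mean = np.interp(ages_all, ages_all[present], mean[present])
    label = "none"
    if smoothing != "none":
        mean = np.maximum(smooth_series(mean, float(smoothing)), WIDTH_FLOOR_MM)
        label = f"spline({smoothing})"
    return RegionalCurve(cambial_age=np.arange(1, max_age + 1),
                         mean_width=mean, n_at_age=count, smoothing=label)


def rcs_detrend(series: RingSeries, rc: RegionalCurve) -> RWISeries:
    """Divide a series by the regional curve at its cambial ages."""
    ages = _cambial_ages(series)
    rc_vals = rc(ages)
    if np.any(rc_vals <= 0):
        raise ValueError(f"series {series.series_id}: regional curve is zero "
                         "at a required cambial age")
    extended = bool(ages[-1] > rc.max_age)
    if extended:
        logger.info("series %s: regional curve extended beyond age %d",
                    series.series_id, rc.max_age)
    w = np.maximum(series.widths, WIDTH_FLOOR_MM)
    return RWISeries(series_id=series.series_id, tree_id=series.tree_id,
                     first_year=series.first_year, indices=w / rc_vals,
                     method="rcs", cambial_ages=ages, rc_extended=extended)


# ---------------------------------------------------------------------------
# helpers shared by the modelling modules
# ---------------------------------------------------------------------------

def truncate_rwi(rwi: RWISeries, start_year: int = 1850) -> RWISeries | None:
    """Drop years before ``start_year`` (applied after detrending)."""
    if rwi.first_year >= start_year:
        return rwi
    skip = start_year - rwi.first_year
    if skip >= len(rwi):
        return None
    return RWISeries(series_id=rwi.series_id, tree_id=rwi.tree_id,
                     first_year=start_year, indices=rwi.indices[skip:],
                     method=rwi.method, spline_wavelength=rwi.spline_wavelength,
                     cambial_ages=None if rwi.cambial_ages is None
                     else rwi.cambial_ages[skip:],
                     rc_extended=rwi.rc_extended)


def rwi_frame(rwis: list[RWISeries]) -> "pd.DataFrame":
    """Long-format (series_id, tree_id, year, index, method) table."""
    import pandas as pd

    rows = []
    for r in rwis:
        rows.append(pd.DataFrame({"series_id": r.series_id, "tree_id": r.tree_id,
                                  "year": r.years, "index": r.indices,
                                  "method": r.method}))
    if not rows:
        return pd.DataFrame(columns=["series_id", "tree_id", "year", "index", "method"])
    return pd.concat(rows, ignore_index=True)
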