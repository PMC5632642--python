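"""Tree-ring measurement I/O (Tucson/RWL decadal format) and crossdating QC.

Ring widths are carried in the decadal Tucson format: one row per series and
decade, series code in the first field, the decade's first year next, then
up to ten integer widths.  Two field dialects are supported — widths in
0.01 mm terminated by ``999`` (default on write) and widths in 0.001 mm
terminated by ``-9999``; the reader auto-detects the dialect from the
terminator.  Crossdating quality control correlates each high-pass-filtered
series against the leave-one-out mean chronology, overall and in sliding
windows, as a simplified stand-in for the COFECHA workflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RingSeries",
    "TreeMeta",
    "CrossdateReport",
    "read_rwl",
    "write_rwl",
    "crossdate_qc",
    "read_tree_meta",
    "write_tree_meta",
    "crossdate_frame",
]

RESOLUTION_MM = 0.01  # measurement resolution of the ring-width data


@dataclass
class RingSeries:
    """One dated raw ring-width series (mm) from a single core."""

    series_id: str
    first_year: int
    widths: np.ndarray
    tree_id: str = ""
    site: str = ""
    species: str = ""
    coring_height: str = "breast_height"  # {"base", "breast_height"}
    pith_hit: bool = False
    pith_offset_rings: int | None = None

    def __post_init__(self):
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.size == 0:
            raise ValueError(f"series {self.series_id}: widths must be nonempty")
        if np.any(self.widths < 0):
            raise ValueError(f"series {self.series_id}: widths must be >= 0")
        if not self.tree_id:
            self.tree_id = self.series_id

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.widths.size - 1

    def __len__(self) -> int:
        return self.widths.size


@dataclass
class TreeMeta:
    """Per-tree field measurements."""

    tree_id: str
    site: str = ""
    species: str = ""
    elevation: float = np.nan
    dbh: float = np.nan
    height: float = np.nan
    crown_length: float = np.nan
    aspect: float = np.nan
    slope: float = np.nan
    multi_stem: bool = False

    def __post_init__(self):
        if not np.isfinite(self.elevation):
            raise ValueError(f"tree {self.tree_id}: elevation must be finite")
        if np.isfinite(self.dbh) and self.dbh <= 0:
            raise ValueError(f"tree {self.tree_id}: dbh must be positive")


@dataclass
class CrossdateReport:
    series_id: str
    overall_r: float
    window_r: list = field(default_factory=list)  # (window start year, r)
    flags: list = field(default_factory=list)     # window start years below threshold


# ---------------------------------------------------------------------------
# Tucson/RWL format
# ---------------------------------------------------------------------------

_DIALECTS = {"0.01": (100.0, 999), "0.001": (1000.0, -9999)}


class RWLParseError(ValueError):
    pass


def read_rwl(path) -> list[RingSeries]:
    """Read a decadal Tucson ring-width file.

    The units dialect (0.01 mm / terminator 999 vs 0.001 mm / terminator
    -9999) is detected from the end-of-series marker.  Returns one
    :class:`RingSeries` per series code, widths in mm.
    """
    path = Path(path)
    text = path.read_text()
    rows = []  # (lineno, series_id, decade_year, values)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        sid = line[:8].strip()
        rest = line[8:].split()
        if not sid or len(rest) < 2:
            raise RWLParseError(f"{path}:{lineno}: malformed decade row: {line!r}")
        try:
            year = int(rest[0])
            vals = [int(v) for v in rest[1:]]
        except ValueError as exc:
            raise RWLParseError(f"{path}:{lineno}: malformed decade row: {line!r}") from exc
        rows.append((lineno, sid, year, vals))

    if not rows:
        warnings.warn(f"{path}: empty RWL file, no series read")
        return []

    flat = [v for *_, vals in rows for v in vals]
    if -9999 in flat:
        scale, marker = _DIALECTS["0.001"]
    else:
        scale, marker = _DIALECTS["0.01"]

    series: list[RingSeries] = []
    seen: set[str] = set()
    cur_id, cur_first, cur_vals, cur_done = None, None, [], False

    def _flush():
        nonlocal cur_id, cur_first, cur_vals, cur_done
        if cur_id is None:
            return
        if cur_id in seen:
            raise RWLParseError(f"{path}: duplicate series code {cur_id!r}")
        seen.add(cur_id)
        series.append(RingSeries(series_id=cur_id, first_year=cur_first,
                                 widths=np.asarray(cur_vals, dtype=float) / scale))
        cur_id, cur_first, cur_vals, cur_done = None, None, [], False

    for lineno, sid, year, vals in rows:
        if sid != cur_id:
            _flush()
            cur_id, cur_first = sid, year
        else:
            expected = cur_first + len(cur_vals)
            if year != expected:
                raise RWLParseError(
                    f"{path}:{lineno}: decade label {year} does not follow "
                    f"previous rows of series {sid!r} (expected {expected})")
        for v in vals:
            if v == marker:
                cur_done = True
                break
            cur_vals.append(v)
        if cur_done:
            _flush()
    _flush()
    return series


def write_rwl(series: list[RingSeries], path, dialect: str = "0.01") -> None:
    """Write series in decadal Tucson format; round trip with :func:`read_rwl`."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    scale, marker = _DIALECTS[dialect]
    lines = []
    for s in series:
        ivals = np.rint(s.widths * scale).astype(int)
        if np.any(np.abs(ivals - s.widths * scale) > 1e-6):
            raise ValueError(f"series {s.series_id}: widths not representable at "
                             f"{1.0 / scale} mm resolution")
        if np.any(ivals >= abs(marker)) and marker > 0:
            raise ValueError(f"series {s.series_id}: width exceeds dialect maximum")
        vals = list(ivals) + [marker]
        year = int(s.first_year)
        i = 0
        while i < len(vals):
            decade_end = (year // 10) * 10 + 10
            take = min(decade_end - year, len(vals) - i)
            chunk = vals[i:i + take]
            lines.append(f"{s.series_id:<8}{year:>4}" + "".join(f"{v:>6}" for v in chunk))
            year += take
            i += take
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tree metadata CSV
# ---------------------------------------------------------------------------

_META_COLS = ["tree_id", "site", "species", "elevation", "dbh", "height",
              "crown_length", "aspect", "slope", "multi_stem"]


def read_tree_meta(path) -> list[TreeMeta]:
    df = pd.read_csv(path)
    missing = [c for c in ("tree_id", "elevation") if c not in df.columns]
    if missing:
        raise ValueError(f"tree metadata CSV lacks columns {missing}")
    if df["tree_id"].duplicated().any():
        raise ValueError("tree metadata must contain one record per tree_id")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _META_COLS if c in df.columns}
        kwargs["tree_id"] = str(kwargs["tree_id"])
        out.append(TreeMeta(**kwargs))
    return out


def write_tree_meta(meta: list[TreeMeta], path) -> None:
    pd.DataFrame([vars(m) for m in meta])[_META_COLS].to_csv(path, index=False)


def tree_meta_frame(meta: list[TreeMeta]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in meta])


# ---------------------------------------------------------------------------
# quantitative crossdating QC
# ---------------------------------------------------------------------------

def crossdate_qc(series: list[RingSeries], window_length: int = 50,
                 window_offset: int = 25, transform: str = "detrended_correlation",
                 threshold: float = 0.32, spline_wavelength: int = 32,
                 min_overlap: int | None = None) -> list[CrossdateReport]:
    """Correlate each series against the leave-one-out mean chronology.

    Each series is first high-pass filtered by spline detrending (removing
    the growth trend that would otherwise inflate correlations), then the
    Pearson correlation with the mean index of all *other* series is
    computed over the full overlap and in sliding windows of
    ``window_length`` years advanced by ``window_offset``.  Windows with a
    correlation below ``threshold`` are flagged.
    """
    from .detrend import spline_detrend

    if transform != "detrended_correlation":
        raise ValueError(f"unknown transform {transform!r}")
    if len(series) < 2:
        raise ValueError("crossdating requires at least 2 series")
    if min_overlap is None:
        min_overlap = window_length

    idx_series = {}
    for s in series:
        rwi = spline_detrend(s, wavelength=spline_wavelength)
        idx_series[s.series_id] = pd.Series(rwi.indices, index=rwi.years)
    panel = pd.DataFrame(idx_series)

    reports = []
    for sid in panel.columns:
        own = panel[sid].dropna()
        others = panel.drop(columns=sid).mean(axis=1, skipna=True)
        depth = panel.drop(columns=sid).notna().sum(axis=1)
        master = others[depth >= 1]
        common = own.index.intersection(master.index)
        if common.size < min_overlap:
            warnings.warn(f"series {sid}: overlap with master below "
                          f"{min_overlap} years, skipped")
            continue
        x = own.loc[common].to_numpy()
        m = master.loc[common].to_numpy()
        overall = _safe_corr(x, m)
        years = common.to_numpy()
        win_r, flags = [], []
        start, last_start = int(years.min()), int(years.max()) - window_length + 1
        starts = list(range(start, max(last_start, start) + 1, window_offset))
        if starts and starts[-1] < last_start:
            starts.append(last_start)  # cover the tail of the overlap
        for w0 in starts:
            mask = (years >= w0) & (years < w0 + window_length)
            if mask.sum() < max(10, window_length // 2):
                continue
            r = _safe_corr(x[mask], m[mask])
            win_r.append((w0, r))
            if r < threshold:
                flags.append(w0)
        reports.append(CrossdateReport(series_id=sid, overall_r=overall,
                                       window_r=win_r, flags=flags))
    return reports


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def crossdate_frame(reports: list[CrossdateReport]) -> pd.DataFrame:
    """Flatten crossdating reports to a tidy table for CSV export."""
    rows = []
    for r in reports:
        for w0, wr in r.window_r:
            rows.append({"series_id": r.series_id, "overall_r": r.overall_r,
                         "window_start": w0, "window_r": wr,
                         "flagged": w0 in r.flags})
    return pd.DataFrame(rows)
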