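"""Stand-structure analysis along the elevation gradient.

Works on a table of detected trees (id, elevation, height > 2.5 m — in the
field study such tables come from UAV canopy-height models; here they are
consumed ready-made).  Trees are grouped into three elevation classes at
the 25th/75th percentiles, heights are converted to ages via a
site-specific age-height regression fitted on cored trees, ages become
ingrowth times relative to a survey year, and densities are reported per
class and overall.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StandTable",
    "AgeHeightModel",
    "HEIGHT_THRESHOLD_M",
    "elevation_classes",
    "fit_age_height",
    "heights_to_ingrowth",
    "ingrowth_summary",
    "stand_density",
]

HEIGHT_THRESHOLD_M = 2.5  # detection threshold for delineated trees

CLASS_LABELS = ("lower25", "central50", "upper25")


@dataclass
class StandTable:
    """Detected trees: id, elevation (m a.s.l.), height (m), survey year."""

    frame: pd.DataFrame
    survey_year: int = 2015

    def __post_init__(self):
        need = {"id", "elevation", "height"}
        if not need <= set(self.frame.columns):
            raise ValueError(f"stand table needs columns {sorted(need)}")
        if (self.frame["height"] <= HEIGHT_THRESHOLD_M).any():
            raise ValueError(f"stand table heights must exceed {HEIGHT_THRESHOLD_M} m")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class AgeHeightModel:
    """OLS fit of Age = b0 + b1 * height on cored trees."""

    intercept: float
    slope: float
    r_squared: float
    p_value: float
    n: int

    def predict_age(self, height) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(height, dtype=float)


def elevation_classes(table: StandTable | pd.DataFrame) -> pd.Series:
    """Assign each tree to lower25/central50/upper25 elevation classes.

    Breaks are the 25th and 75th percentiles of elevation; boundary values
    go to the lower class (deterministic rule).
    """
    df = table.frame if isinstance(table, StandTable) else table
    if len(df) < 4:
        raise ValueError("need at least 4 trees for elevation classes")
    elev = df["elevation"].to_numpy(dtype=float)
    p25, p75 = np.percentile(elev, [25, 75])
    if p25 == p75:
        warnings.warn("degenerate elevation distribution: all trees in one class")
    labels = np.where(elev <= p25, CLASS_LABELS[0],
                      np.where(elev <= p75, CLASS_LABELS[1], CLASS_LABELS[2]))
    return pd.Series(labels, index=df.index, name="elev_class")


def fit_age_height(ages, heights) -> AgeHeightModel:
    """Site-specific linear regression Age = b0 + b1 * height (OLS)."""
    import statsmodels.api as sm

    ages = np.asarray(ages, dtype=float)
    heights = np.asarray(heights, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(heights)
    ages, heights = ages[ok], heights[ok]
    if ages.size < 3:
        raise ValueError("need at least 3 (age, height) pairs")
    if np.std(heights) == 0:
        raise ValueError("zero-variance heights: regression undefined")
    res = sm.OLS(ages, sm.add_constant(heights)).fit()
    return AgeHeightModel(intercept=float(res.params[0]), slope=float(res.params[1]),
                          r_squared=float(res.rsquared),
                          p_value=float(res.pvalues[1]), n=int(ages.size))


def heights_to_ingrowth(table: StandTable, model: AgeHeightModel,
                        survey_year: int | None = None) -> pd.DataFrame:
    """Estimated age, establishment year and ingrowth time per detected tree.

    Ingrowth time is the estimated tree age at survey, i.e. years since
    establishment; predicted ages are floored at 1.
    """
    if survey_year is None:
        survey_year = table.survey_year
    df = table.frame.copy()
    age = model.predict_age(df["height"])
    n_floor = int((age < 1).sum())
    if n_floor:
        warnings.warn(f"{n_floor} predicted ages below 1 floored at 1")
    age = np.maximum(age, 1.0)
    df["age"] = age
    df["ingrowth_time"] = age
    df["establishment_year"] = survey_year - age
    df["elev_class"] = elevation_classes(table)
    return df


def ingrowth_summary(ingrowth: pd.DataFrame, bin_width: float = 10.0) -> dict:
    """Per-class ingrowth-time distributions: histogram counts and skewness."""
    out = {}
    upper = float(ingrowth["ingrowth_time"].max())
    edges = np.arange(0.0, upper + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    for label, grp in ingrowth.groupby("elev_class", observed=True):
        t = grp["ingrowth_time"].to_numpy()
        counts, _ = np.histogram(t, bins=edges)
        out[label] = {
            "n": int(t.size),
            "bin_edges": edges,
            "counts": counts,
            "skewness": float(stats.skew(t)) if t.size > 2 else np.nan,
            "mean": float(t.mean()),
        }
    return out


def stand_density(table: StandTable, areas: dict | float) -> pd.DataFrame:
    """Trees per hectare, per elevation class and overall.

    ``areas`` maps class label -> area in ha; a scalar is taken as the
    total surveyed area, split equally over the three classes.
    """
    classes = elevation_classes(table)
    counts = classes.value_counts().reindex(CLASS_LABELS, fill_value=0)
    if isinstance(areas, dict):
        if any(a <= 0 for a in areas.values()):
            raise ValueError("areas must be positive")
        total_area = float(sum(areas.values()))
        class_area = {c: float(areas[c]) for c in CLASS_LABELS}
    else:
        if areas <= 0:
            raise ValueError("areas must be positive")
        total_area = float(areas)
        class_area = {c: total_area / 3.0 for c in CLASS_LABELS}
    rows = [{"class": c, "n_trees": int(counts[c]), "area_ha": class_area[c],
             "density_per_ha": counts[c] / class_area[c]} for c in CLASS_LABELS]
    rows.append({"class": "overall", "n_trees": int(counts.sum()),
                 "area_ha": total_area,
                 "density_per_ha": counts.sum() / total_area})
    return pd.DataFrame(rows)
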