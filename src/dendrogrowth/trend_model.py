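"""Long-term growth-trend models on log RCS ring-width indices.

The trend model regresses the natural log of the RCS index of tree j in
year t on calendar year, elevation and their interaction,

    log(RWI_jt) = beta0 + (beta1 + b1j) t + (beta2 + b2j) elev
                  + (beta3 + b3j) t * elev + b0j + eps_jt,

with tree-level diagonal random effects and AR(1) residuals, fitted by
REML.  Year and elevation in metres make (t, elev, t*elev) nearly
collinear, so the fit runs on centred variables internally and the
coefficients are back-transformed to the uncentred scale (with
delta-method standard errors), which is the scale on which slope
magnitudes like beta1 ~ -0.13 with beta3 ~ 6e-5 are interpretable.
Predictions are made at the 0/20/40/60/80/100th percentiles of the sample
elevations, from the fixed effects alone or including each tree's
predicted random effects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ringwidth_io import tree_meta_frame
from .lmm_core import (GroupedData, LMMFit, ModelSpec, fit_lmm,
                       information_criteria, random_effects,
                       significance_stars)

logger = logging.getLogger(__name__)

__all__ = [
    "TrendFit",
    "TrendPrediction",
    "ELEVATION_PERCENTILES",
    "screen_covariates",
    "fit_trend",
    "predict_trend",
]

ELEVATION_PERCENTILES = (0, 20, 40, 60, 80, 100)

_BASE_TERMS = ("t_c", "elev_c", "t_elev_c")


@dataclass
class TrendFit:
    """REML trend fit with centred internals and uncentred coefficients."""

    lmm: LMMFit
    t_mean: float
    elev_mean: float
    coef: pd.Series        # beta0..beta3 on the uncentred scale
    coef_se: pd.Series
    coef_p: pd.Series
    elevations: np.ndarray  # observed tree elevations
    years: tuple[int, int]

    @property
    def phi(self) -> float:
        return self.lmm.phi

    @property
    def sigma(self) -> float:
        return self.lmm.sigma

    @property
    def re_sd(self) -> pd.Series:
        return self.lmm.re_sd

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: beta0..beta3 with SE and p, random-effect SDs
        (b0..b3) and the AR(1) parameter."""
        re = self.lmm.re_sd.to_numpy()
        rows = []
        for i, name in enumerate(["beta0", "beta1_time", "beta2_elev",
                                  "beta3_time_x_elev"]):
            rows.append({"term": name, "estimate": self.coef.iloc[i],
                         "se": self.coef_se.iloc[i], "p": self.coef_p.iloc[i],
                         "stars": significance_stars(self.coef_p.iloc[i]),
                         "re_sd_centred": re[i] if i < re.size else np.nan})
        rows.append({"term": "phi", "estimate": self.lmm.phi, "se": np.nan,
                     "p": np.nan, "stars": "", "re_sd_centred": np.nan})
        return pd.DataFrame(rows)


@dataclass
class TrendPrediction:
    levels: pd.DataFrame              # elevation_percentile, elevation, year, index
    per_tree: pd.DataFrame | None = None
    mode: str = "fixed_only"


def _trend_frame(rwi: pd.DataFrame, meta) -> pd.DataFrame:
    need = {"tree_id", "year", "index"}
    if not need <= set(rwi.columns):
        raise ValueError(f"RWI table needs columns {sorted(need)}")
    mdf = meta if isinstance(meta, pd.DataFrame) else tree_meta_frame(meta)
    df = (rwi.groupby(["tree_id", "year"], as_index=False)["index"].mean()
          .merge(mdf[["tree_id", "elevation"] +
                     [c for c in ("height", "dbh", "crown_length", "aspect", "slope")
                      if c in mdf.columns]],
                 on="tree_id", how="inner"))
    if (df["index"] <= 0).any():
        raise ValueError("RCS indices must be positive (zero widths are "
                         "floored during detrending)")
    df["log_rwi"] = np.log(df["index"])
    return df


def _add_centred(df: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    t_mean = float(df["year"].mean())
    e_mean = float(df["elevation"].mean())
    df = df.assign(t_c=df["year"] - t_mean, elev_c=df["elevation"] - e_mean)
    df["t_elev_c"] = df["t_c"] * df["elev_c"]
    return df, t_mean, e_mean


def _uncentre(lmm: LMMFit, t_mean: float, e_mean: float):
    """Back-transform centred coefficients to the uncentred (year,
    elevation-in-m) scale; SEs and p by the delta method."""
    from scipy import stats

    idx = ["intercept", "t_c", "elev_c", "t_elev_c"]
    c = lmm.beta[idx].to_numpy()
    cov = pd.DataFrame(lmm.cov_beta, index=lmm.beta.index,
                       columns=lmm.beta.index).loc[idx, idx].to_numpy()
    # beta = J c  with  beta3 = c3, beta1 = c1 - c3 e_mean, beta2 = c2 - c3 t_mean,
    # beta0 = c0 - c1 t_mean - c2 e_mean + c3 t_mean e_mean
    J = np.array([
        [1.0, -t_mean, -e_mean, t_mean * e_mean],
        [0.0, 1.0, 0.0, -e_mean],
        [0.0, 0.0, 1.0, -t_mean],
        [0.0, 0.0, 0.0, 1.0],
    ])
    beta = J @ c
    cov_u = J @ cov @ J.T
    se = np.sqrt(np.diag(cov_u))
    df_t = max(lmm.n_obs - lmm.n_groups - 4, 1)
    pvals = 2.0 * stats.t.sf(np.abs(beta / se), df_t)
    names = ["beta0", "beta1", "beta2", "beta3"]
    return (pd.Series(beta, index=names), pd.Series(se, index=names),
            pd.Series(pvals, index=names))


def fit_trend(rwi: pd.DataFrame, meta, start_year: int = 1850,
              n_restarts: int = 0) -> TrendFit:
    """REML fit of the elevation-interaction trend model on log RCS indices."""
    df = _trend_frame(rwi, meta)
    df = df[df["year"] >= start_year]
    if df["tree_id"].nunique() < 3:
        raise ValueError("trend model needs at least 3 trees")
    if df["elevation"].nunique() < 2:
        raise ValueError("all trees share one elevation: the elevation and "
                         "interaction terms are inestimable")
    df, t_mean, e_mean = _add_centred(df)
    spec = ModelSpec(response="log_rwi", fixed=_BASE_TERMS, random=_BASE_TERMS,
                     random_cov="diagonal", ar1=True)
    data = GroupedData.from_frame(df, spec)
    lmm = fit_lmm(spec, data, method="REML", n_restarts=n_restarts)
    coef, se, p = _uncentre(lmm, t_mean, e_mean)
    return TrendFit(lmm=lmm, t_mean=t_mean, elev_mean=e_mean,
                    coef=coef, coef_se=se, coef_p=p,
                    elevations=df.groupby("tree_id")["elevation"].first().to_numpy(),
                    years=(int(df["year"].min()), int(df["year"].max())))


def screen_covariates(rwi: pd.DataFrame, meta,
                      candidates: tuple[str, ...] = ("height", "dbh",
                                                     "crown_length", "aspect",
                                                     "slope"),
                      start_year: int = 1850) -> tuple[tuple[str, ...], pd.DataFrame]:
    """All-subsets AIC screening of extra tree covariates.

    The base terms (t, elev, t x elev, with the trend random structure) are
    always included; every subset of ``candidates`` is added as fixed
    effects and models are compared by AIC under ML.  Returns the winning
    covariate set and the AIC table.
    """
    df = _trend_frame(rwi, meta)
    df = df[df["year"] >= start_year]
    missing = [c for c in candidates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates missing from tree metadata: {missing}")
    n0 = len(df)
    df = df.dropna(subset=list(candidates))
    if len(df) < n0:
        logger.info("listwise exclusion removed %d rows with missing covariates",
                    n0 - len(df))
    df, t_mean, e_mean = _add_centred(df)
    rows = []
    best = (np.inf, ())
    for r in range(len(candidates) + 1):
        for extra in itertools.combinations(candidates, r):
            spec = ModelSpec(response="log_rwi", fixed=_BASE_TERMS + extra,
                             random=_BASE_TERMS, random_cov="diagonal", ar1=True)
            data = GroupedData.from_frame(df, spec)
            fit = fit_lmm(spec, data, method="ML", compute_var_se=False)
            aic, _ = information_criteria(fit)
            rows.append({"covariates": "+".join(extra) or "(base)",
                         "k": fit.k_params, "loglik": fit.loglik, "AIC": aic,
                         "converged": fit.converged})
            # ties favour the smaller subset (iteration is by subset size)
            if fit.converged and aic < best[0] - 1e-9:
                best = (aic, extra)
    table = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    table["delta"] = table["AIC"] - table["AIC"].min()
    return best[1], table


def predict_trend(fit: TrendFit, mode: str = "fixed_only",
                  years: np.ndarray | None = None,
                  allow_extrapolate: bool = False,
                  rwi: pd.DataFrame | None = None, meta=None) -> TrendPrediction:
    """Predicted back-transformed indices at the elevation percentiles.

    ``fixed_only`` uses exp(beta0 + beta1 t + beta2 e + beta3 t e);
    ``per_tree`` additionally needs the fitting data (``rwi``, ``meta``) and
    adds each tree's predicted (BLUP) random effects.
    """
    if mode not in ("fixed_only", "per_tree"):
        raise ValueError(f"unknown mode {mode!r}")
    y0, y1 = fit.years
    if years is None:
        years = np.arange(y0, y1 + 1)
    years = np.asarray(years)
    if (years.min() < y0 or years.max() > y1) and not allow_extrapolate:
        raise ValueError(f"years outside the fitted range {y0}-{y1}; "
                         "pass allow_extrapolate=True to override")
    levels = np.percentile(fit.elevations, ELEVATION_PERCENTILES,
                           method="linear")
    b = fit.coef.to_numpy()
    rows = []
    for pct, e in zip(ELEVATION_PERCENTILES, levels):
        log_idx = b[0] + b[1] * years + b[2] * e + b[3] * years * e
        rows.append(pd.DataFrame({"elevation_percentile": pct, "elevation": e,
                                  "year": years, "index": np.exp(log_idx)}))
    levels_df = pd.concat(rows, ignore_index=True)

    per_tree = None
    if mode == "per_tree":
        if rwi is None or meta is None:
            raise ValueError("per_tree predictions need the fitting data "
                             "(rwi and meta)")
        df = _trend_frame(rwi, meta)
        df = df[df["year"] >= y0]
        df = df.assign(t_c=df["year"] - fit.t_mean,
                       elev_c=df["elevation"] - fit.elev_mean)
        df["t_elev_c"] = df["t_c"] * df["elev_c"]
        spec = fit.lmm.spec
        data = GroupedData.from_frame(df, spec)
        blups = random_effects(fit.lmm, data)
        c = fit.lmm.beta
        parts = []
        bounds = np.r_[data.starts, data.n_obs]
        for i, tree in enumerate(data.group_ids):
            lo, hi = bounds[i], bounds[i + 1]
            eta = data.X[lo:hi] @ c.to_numpy() + data.Z[lo:hi] @ blups.loc[tree].to_numpy()
            parts.append(pd.DataFrame({"tree_id": tree,
                                       "year": data.years[lo:hi],
                                       "index": np.exp(eta)}))
        per_tree = pd.concat(parts, ignore_index=True)
    return TrendPrediction(levels=levels_df, per_tree=per_tree, mode=mode)
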