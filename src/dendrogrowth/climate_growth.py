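"""Exhaustive BIC model selection of monthly temperature effects on growth.

For each species x site, spline ring-width indices of individual trees are
modelled as a linear function of up to 15 standardized monthly mean
temperatures (previous August .. current October) with a tree-level random
intercept and AR(1) residuals.  Every one of the 2^15 fixed-effect subsets
is fitted by ML and ranked by BIC; the winning fixed-effect structure is
then refitted by REML with tree-level random slopes added for every
selected month (diagonal covariance), which quantifies among-tree
variability in the climate response.

Because the temperature columns are centred and scaled, a fixed effect of
0.1 means a 10% change in ring-width index per one standard deviation of
that month's temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import LagDesign
from .lmm_core import (GroupedData, LMMFit, ModelSpec, fit_lmm,
                       information_criteria)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionTable",
    "enumerate_subsets",
    "align_design_response",
    "exhaustive_select",
    "finalize_with_random_slopes",
    "predicted_rwi_change",
]


@dataclass
class SelectionTable:
    """All candidate subsets with their ML fits, ranked by the criterion."""

    table: pd.DataFrame          # subset, terms, k, loglik, AIC, BIC, delta, converged
    best_spec: ModelSpec
    candidates: tuple[str, ...]
    criterion: str

    @property
    def best_terms(self) -> tuple[str, ...]:
        return self.best_spec.fixed

    def __len__(self) -> int:
        return len(self.table)


def enumerate_subsets(n_candidates: int):
    """All 2^n candidate-subset bitmasks, in lexicographic mask order."""
    if n_candidates < 0:
        raise ValueError("candidate count must be nonnegative")
    return range(1 << n_candidates)


def _mask_terms(mask: int, candidates) -> tuple[str, ...]:
    return tuple(c for i, c in enumerate(candidates) if mask >> i & 1)


def align_design_response(design: LagDesign, rwi: pd.DataFrame,
                          response: str = "rwi") -> pd.DataFrame:
    """Merge a long RWI table (tree_id, year, index) with the lagged design.

    Multiple series of one tree in the same year are averaged (growth
    analyses use one breast-height core per tree; averaging covers
    accidental duplicates).  Years outside the design are dropped.
    """
    need = {"tree_id", "year", "index"}
    if not need <= set(rwi.columns):
        raise ValueError(f"RWI table needs columns {sorted(need)}")
    r = (rwi.groupby(["tree_id", "year"], as_index=False)["index"].mean()
         .rename(columns={"index": response}))
    d = design.frame.copy()
    d["year"] = design.response_years
    merged = r.merge(d, on="year", how="inner")
    return merged.sort_values(["tree_id", "year"]).reset_index(drop=True)


def exhaustive_select(design: LagDesign, rwi: pd.DataFrame,
                      candidates: tuple[str, ...] | None = None,
                      criterion: str = "BIC", method: str = "ML",
                      max_candidates: int | None = None,
                      warm_start: bool = True,
                      ar1: bool = True, tol: float = 1e-9) -> SelectionTable:
    """Fit every subset of the candidate months and rank by BIC (or AIC).

    Each candidate model carries the intercept, a tree-level random
    intercept and AR(1) residuals; fits use ML so criteria are comparable
    across fixed-effect structures.  Warm starts propagate each subset's
    variance-parameter optimum to its supersets, which speeds the
    enumeration up without changing the argmin (every subset is still fully
    optimised).  Ties are broken by fewer parameters, then by lexicographic
    bitmask.  Non-converged subsets are flagged and excluded from the
    argmin.
    """
    if criterion not in ("BIC", "AIC"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if candidates is None:
        candidates = tuple(design.frame.columns)
    candidates = tuple(candidates)
    if max_candidates is not None and len(candidates) > max_candidates:
        candidates = candidates[:max_candidates]
    unknown = set(candidates) - set(design.frame.columns)
    if unknown:
        raise ValueError(f"candidates not in design: {sorted(unknown)}")

    df = align_design_response(design, rwi)
    full_spec = ModelSpec(response="rwi", fixed=candidates, random=(), ar1=ar1)
    data_full = GroupedData.from_frame(df, full_spec)

    m = len(candidates)
    n_models = 1 << m
    logger.info("exhaustive selection over %d candidates: %d models", m, n_models)
    theta_store: dict[int, np.ndarray] = {}
    rows = []
    crit_col = []
    for mask in enumerate_subsets(m):
        terms = _mask_terms(mask, candidates)
        spec = ModelSpec(response="rwi", fixed=terms, random=(), ar1=ar1)
        data = data_full.subset_columns(("intercept",) + terms, ("intercept",))
        start = None
        if warm_start and mask:
            start = theta_store.get(mask & (mask - 1))
        fit = fit_lmm(spec, data, method=method, start=start,
                      compute_var_se=False, tol=tol)
        if warm_start:
            theta_store[mask] = fit.theta_opt
        aic, bic = information_criteria(fit)
        rows.append({"subset": mask, "terms": "+".join(terms) or "(intercept)",
                     "k": fit.k_params, "loglik": fit.loglik, "AIC": aic,
                     "BIC": bic, "converged": fit.converged})
        crit_col.append(bic if criterion == "BIC" else aic)
        if (mask + 1) % 1000 == 0:
            logger.info("  fitted %d / %d models", mask + 1, n_models)

    table = pd.DataFrame(rows)
    crit = np.where(table["converged"], crit_col, np.inf)
    order = np.lexsort((table["subset"].to_numpy(), table["k"].to_numpy(), crit))
    table = table.iloc[order].reset_index(drop=True)
    best_value = table.loc[0, criterion]
    table["delta"] = table[criterion] - best_value
    table.loc[~table["converged"], "delta"] = np.nan
    n_bad = int((~table["converged"]).sum())
    if n_bad:
        logger.warning("%d candidate fits did not converge (excluded from argmin)",
                       n_bad)
    best_terms = _mask_terms(int(table.loc[0, "subset"]), candidates)
    best_spec = ModelSpec(response="rwi", fixed=best_terms, random=best_terms,
                          random_cov="diagonal", ar1=ar1)
    return SelectionTable(table=table, best_spec=best_spec,
                          candidates=candidates, criterion=criterion)


def finalize_with_random_slopes(best_spec: ModelSpec | SelectionTable,
                                design: LagDesign, rwi: pd.DataFrame,
                                n_restarts: int = 0) -> LMMFit:
    """REML refit of the selected model with tree-level random slopes.

    Random effects: intercept plus one diagonal slope per selected month.
    Singular slopes are reported with SD 0.
    """
    if isinstance(best_spec, SelectionTable):
        best_spec = best_spec.best_spec
    spec = ModelSpec(response="rwi", fixed=best_spec.fixed,
                     random=best_spec.fixed, random_cov="diagonal",
                     ar1=best_spec.ar1)
    df = align_design_response(design, rwi)
    data = GroupedData.from_frame(df, spec)
    return fit_lmm(spec, data, method="REML", n_restarts=n_restarts)


def predicted_rwi_change(fit: LMMFit, column: str, delta_sd: float = 1.0) -> float:
    """Predicted RWI change for a temperature shift of ``delta_sd`` SDs.

    With standardized predictors and a baseline index of ~1, a coefficient
    of 0.1 maps to a +10% index change per +1 SD.
    """
    if column not in fit.beta.index:
        raise KeyError(f"{column!r} is not a fixed effect of this fit")
    return float(fit.beta[column] * delta_sd)
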