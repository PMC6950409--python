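"""Cross-validation, gridded prediction and guideline exceedance.

``kfold_cv`` re-estimates the model on k-1 folds and scores the held-out
fold; the headline metric is the *pooled* out-of-fold R² / RMSE over the
concatenated predictions.  ``predict_surface`` evaluates the fitted
linear model cellwise on predictor rasters; ``exceedance_summary``
counts cells above named air-quality-guideline thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import selection as _sel
from .design import DesignMatrix
from .grid import FeatureRaster, GridSpec

__all__ = [
    "CVResult",
    "PredictionRaster",
    "kfold_cv",
    "predict_surface",
    "period_average",
    "exceedance_summary",
    "DEFAULT_THRESHOLDS",
]

#: Air-quality-guideline thresholds, ug/m3.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "WHO_annual": 10.0,
    "WHO_24h": 25.0,
    "Indonesia_annual": 15.0,
    "Indonesia_24h": 65.0,
}


@dataclass
class CVResult:
    """k-fold cross-validation outcome.

    ``fold_assignment`` maps each observation (design-matrix row order)
    to its fold; ``predictions`` are out-of-fold.  ``r2``/``rmse`` are
    pooled over the concatenated out-of-fold predictions; per-fold
    metrics are in ``per_fold``.
    """

    k: int
    fold_assignment: np.ndarray
    predictions: np.ndarray
    observed: np.ndarray
    r2: float
    r2_adj: float
    rmse: float
    per_fold: pd.DataFrame

    def plot(self, ax=None):
        """Pooled out-of-fold observed-vs-predicted scatter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.observed, self.predictions, s=12, alpha=0.6)
        lo = min(self.observed.min(), self.predictions.min())
        hi = max(self.observed.max(), self.predictions.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("observed PM2.5 (ug/m3)")
        ax.set_ylabel("out-of-fold predicted PM2.5 (ug/m3)")
        ax.set_title(f"{self.k}-fold CV: R2 = {self.r2:.2f}, RMSE = {self.rmse:.2f}")
        return ax


@dataclass
class PredictionRaster:
    """A predicted PM2.5 surface for one period label
    (``YYYY-MM``, ``YYYY`` or ``pooled``)."""

    grid: GridSpec
    period: str
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("prediction values do not match grid shape")


def _make_folds(n: int, k: int, rng: np.random.Generator,
                groups: np.ndarray | None = None) -> np.ndarray:
    """Random partition into k folds with sizes differing by <= 1; with
    ``groups``, whole groups (stations) are assigned to folds."""
    assign = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            assign[chunk] = f
    else:
        uniq = np.unique(groups)
        if len(uniq) < k:
            raise ValueError(f"only {len(uniq)} stations for {k} folds")
        perm = rng.permutation(len(uniq))
        for f, chunk in enumerate(np.array_split(perm, k)):
            for g in uniq[chunk]:
                assign[groups == g] = f
    return assign


def kfold_cv(
    design: DesignMatrix,
    k: int = 10,
    seed: int = 0,
    refit_selection: bool = False,
    terms: Sequence[str] | None = None,
    p_enter: float = 0.1,
    vif_max: float = 3.0,
    priors: Mapping[str, int] | None = None,
    leave_station_out: bool = False,
) -> CVResult:
    """k-fold cross-validation of the LUR.

    With ``refit_selection=False`` (default) each training fold re-fits
    the coefficients of the fixed ``terms``; with ``True`` the entire
    supervised stepwise selection is re-run per fold.  Folds are random
    station-month observations unless ``leave_station_out``.
    """
    X, y = design.X, np.asarray(design.y, dtype=float)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n folds (n={n}, k={k})")
    if not refit_selection and not terms:
        raise ValueError("terms are required when refit_selection is off")
    rng = np.random.default_rng(seed)
    groups = None
    if leave_station_out:
        groups = design.data.index.get_level_values("station_id").to_numpy()
    assign = _make_folds(n, k, rng, groups)

    preds = np.full(n, np.nan)
    fold_rows = []
    n_terms_used = []
    for f in range(k):
        test = assign == f
        train = ~test
        n_train = int(train.sum())
        Xtr, ytr = X[train], y[train]
        if refit_selection:
            fit, _ = _sel.supervised_stepwise(
                Xtr, ytr, priors or {}, p_enter=p_enter, vif_max=vif_max)
        else:
            if n_train <= len(terms) + 1:
                raise ValueError(
                    f"fold {f}: {n_train} training rows cannot support "
                    f"{len(terms)} terms; reduce the model or k")
            fit = _sel.fit_ols(Xtr, ytr, terms)
        p = fit.predict(X[test]) if fit.terms else np.full(
            int(test.sum()), fit.params["const"])
        preds[test] = p
        n_terms_used.append(len(fit.terms))
        resid = y[test] - p
        sst = float(np.sum((y[test] - y[test].mean()) ** 2))
        fold_rows.append({
            "fold": f,
            "n_train": n_train,
            "n_test": int(test.sum()),
            "r2": 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else np.nan,
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "n_terms": len(fit.terms),
        })

    resid = y - preds
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst
    p_eff = int(np.median(n_terms_used))
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_eff - 1)
    return CVResult(
        k=k,
        fold_assignment=assign,
        predictions=preds,
        observed=y,
        r2=r2,
        r2_adj=r2_adj,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        per_fold=pd.DataFrame(fold_rows),
    )


def predict_surface(results, rasters: Mapping[str, FeatureRaster],
                    period: str = "pooled",
                    floor_at_zero: bool = False) -> PredictionRaster:
    """Evaluate ``b0 + sum b_i * X_i(cell)`` on predictor rasters.

    ``rasters`` must contain one raster per model term (static layers
    are simply reused across periods by the caller).  Negative cells are
    floored at zero only when requested; the floored count is recorded
    in ``provenance``.
    """
    coeffs = {t: float(results.params[t]) for t in results.terms}
    intercept = float(results.params["const"])
    missing = [t for t in coeffs if t not in rasters]
    if missing:
        raise KeyError(f"no predictor raster for term(s) {missing}")
    grid = None
    for t in coeffs:
        g = rasters[t].grid
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"raster for {t!r} is on a different grid")
    if grid is None:  # intercept-only model: need any raster for geometry
        if not rasters:
            raise ValueError("intercept-only prediction needs one raster "
                             "to define the grid")
        grid = next(iter(rasters.values())).grid
    out = np.full(grid.shape, intercept, dtype=float)
    for t, b in coeffs.items():
        out = out + b * rasters[t].values
    note = f"terms={sorted(coeffs)}"
    if floor_at_zero:
        n_floor = int(np.sum(out < 0))
        out = np.maximum(out, 0.0)
        note += f"; floored_cells={n_floor}"
    return PredictionRaster(grid=grid, period=period, values=out, provenance=note)


def period_average(rasters: Iterable[PredictionRaster],
                   period: str) -> PredictionRaster:
    """Cellwise arithmetic mean of monthly surfaces over a period."""
    rasters = list(rasters)
    if not rasters:
        raise ValueError(f"no rasters to average for period {period!r}")
    grid = rasters[0].grid
    if any(r.grid != grid for r in rasters):
        raise ValueError("rasters are on different grids")
    vals = np.mean([r.values for r in rasters], axis=0)
    return PredictionRaster(grid=grid, period=period, values=vals,
                            provenance=f"mean_of_{len(rasters)}")


def exceedance_summary(raster: PredictionRaster,
                       thresholds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Cells above each named guideline threshold (strict >)."""
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
    if any(v <= 0 for v in thresholds.values()):
        raise ValueError("thresholds must be positive")
    vals = raster.values
    finite = np.isfinite(vals)
    n = int(finite.sum())
    rows = []
    for name in sorted(thresholds):
        thr = float(thresholds[name])
        n_exc = int(np.sum(vals[finite] > thr))
        rows.append({"threshold_name": name, "threshold": thr,
                     "n_cells": n, "n_exceed": n_exc,
                     "fraction": n_exc / n if n else np.nan})
    return pd.DataFrame(rows)
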