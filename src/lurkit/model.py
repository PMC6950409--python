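"""Land-use-regression model and results objects.

:class:`LandUseRegression` holds a design matrix and the selection
configuration; :meth:`LandUseRegression.fit` runs the supervised
stepwise procedure (or a plain OLS on a fixed term set) and returns a
:class:`LURResults` carrying coefficients, p-values, VIFs, partial R²,
fit metrics, the selection trace, and methods for cross-validation,
surface prediction and plotting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import selection as _sel
from .design import DesignMatrix

__all__ = ["LandUseRegression", "LURResults"]


class LandUseRegression:
    """PM2.5 land-use-regression model.

    Parameters
    ----------
    design
        A :class:`~lurkit.design.DesignMatrix` of station-month
        observations (response + candidate predictors + priors).
    p_enter
        Coefficient p-value a term must stay below (default 0.1).
    vif_max
        Variance-inflation-factor ceiling (default 3).
    priors
        Direction-prior overrides (name -> -1/0/+1); defaults come from
        the design matrix's candidate variables.
    """

    def __init__(self, design: DesignMatrix, p_enter: float = 0.1,
                 vif_max: float = 3.0,
                 priors: Mapping[str, int] | None = None) -> None:
        self.design = design
        self.p_enter = float(p_enter)
        self.vif_max = float(vif_max)
        self.priors = dict(design.priors)
        if priors:
            self.priors.update(priors)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "pm25",
                       candidates: Sequence[str] | None = None,
                       priors: Mapping[str, int] | None = None,
                       **kwargs) -> "LandUseRegression":
        """Build a model straight from a flat DataFrame.

        Candidate classes and radii are inferred from column names;
        ``candidates`` defaults to every column except the response.
        """
        from .design import _infer_variable

        if candidates is None:
            candidates = [c for c in df.columns if c != response]
        variables = [_infer_variable(c, priors=priors) for c in candidates]
        data = df[[response] + list(candidates)].copy()
        if not isinstance(data.index, pd.MultiIndex):
            data.index = pd.MultiIndex.from_arrays(
                [[f"s{i}" for i in range(len(data))], ["NA"] * len(data)],
                names=["station_id", "period"])
        coords = pd.DataFrame(columns=["x", "y"])
        dm = DesignMatrix(data, variables, coords, response=response)
        return cls(dm, priors=priors, **kwargs)

    def fit(self, method: str = "stepwise",
            terms: Sequence[str] | None = None) -> "LURResults":
        """Fit the model.

        ``method="stepwise"`` runs the supervised selection over all
        candidates; ``method="ols"`` fits the fixed ``terms`` directly
        (no gates applied).
        """
        X, y = self.design.X, self.design.y
        if method == "stepwise":
            fit, trace = _sel.supervised_stepwise(
                X, y, self.priors, p_enter=self.p_enter, vif_max=self.vif_max)
        elif method == "ols":
            if terms is None:
                raise ValueError("method='ols' needs an explicit term list")
            fit = _sel.fit_ols(X, y, terms)
            trace = _sel.SelectionTrace()
        else:
            raise ValueError(f"unknown method {method!r}")
        return LURResults(self, fit, trace)


class LURResults:
    """Fitted LUR: Eq.-style linear model ``Y = b0 + sum b_i X_i``."""

    def __init__(self, model: LandUseRegression, fit: _sel.OLSFit,
                 trace: _sel.SelectionTrace) -> None:
        self.model = model
        self._fit = fit
        self.trace = trace
        self.terms: list[str] = list(fit.terms)
        self.params: pd.Series = fit.params
        self.bse: pd.Series = fit.bse
        self.pvalues: pd.Series = fit.pvalues
        self.rsquared: float = fit.rsquared
        self.rsquared_adj: float = fit.rsquared_adj
        self.rmse: float = fit.rmse
        self.nobs: int = fit.nobs
        X = model.design.X
        self.vif_: pd.Series = (_sel.vif(X, self.terms) if self.terms
                                else pd.Series(dtype=float))
        self.partial_r2_: pd.Series = (
            _sel.partial_r2(X, model.design.y, self.terms, fit=fit)
            if self.terms else pd.Series(dtype=float))

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def resid(self) -> np.ndarray:
        return self._fit.resid

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._fit.fitted

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted PM2.5 for a table with the model's term columns
        (default: the training design matrix)."""
        if X is None:
            return self.fittedvalues.copy()
        return self._fit.predict(X)

    def gates_satisfied(self) -> bool:
        """True iff every retained term passes p, VIF and sign gates."""
        if not self.terms:
            return True
        p_ok = bool((self.pvalues[self.terms] < self.model.p_enter).all())
        v_ok = bool((self.vif_ < self.model.vif_max).all())
        s_ok = all(
            np.sign(self.params[t]) == self.model.priors.get(t, 0)
            for t in self.terms if self.model.priors.get(t, 0) != 0
        )
        return p_ok and v_ok and s_ok

    # -- downstream analyses ---------------------------------------------
    def cross_validate(self, k: int = 10, seed: int = 0,
                       refit_selection: bool = False,
                       leave_station_out: bool = False):
        from .validate import kfold_cv
        return kfold_cv(self.model.design, k=k, seed=seed,
                        refit_selection=refit_selection,
                        terms=self.terms, p_enter=self.model.p_enter,
                        vif_max=self.model.vif_max,
                        priors=self.model.priors,
                        leave_station_out=leave_station_out)

    def predict_surface(self, rasters, period: str = "pooled",
                        floor_at_zero: bool = False):
        from .validate import predict_surface
        return predict_surface(self, rasters, period=period,
                               floor_at_zero=floor_at_zero)

    # -- reporting --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: Variable, beta, p_value, VIF, partial R²."""
        rows = [{"Variable": "Intercept", "beta": self.intercept,
                 "p_value": float(self.pvalues["const"]),
                 "VIF": np.nan, "partial_R2": np.nan}]
        for t in self.terms:
            rows.append({
                "Variable": t,
                "beta": float(self.params[t]),
                "p_value": float(self.pvalues[t]),
                "VIF": float(self.vif_[t]),
                "partial_R2": float(self.partial_r2_[t]),
            })
        df = pd.DataFrame(rows)
        df.attrs.update(R2=self.rsquared, adj_R2=self.rsquared_adj,
                        RMSE=self.rmse, n=self.nobs)
        return df

    def to_json(self, path: str | Path | None = None) -> dict:
        """Portable model description (for `lurkit predict` and archives)."""
        payload = {
            "intercept": self.intercept,
            "coefficients": {t: float(self.params[t]) for t in self.terms},
            "p_values": {t: float(self.pvalues[t]) for t in self.terms},
            "vif": {t: float(self.vif_[t]) for t in self.terms},
            "partial_r2": {t: float(self.partial_r2_[t]) for t in self.terms},
            "r2": self.rsquared,
            "adj_r2": self.rsquared_adj,
            "rmse": self.rmse,
            "n_observations": self.nobs,
            "gates": {"p_enter": self.model.p_enter,
                      "vif_max": self.model.vif_max},
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1))
        return payload

    def summary(self) -> str:
        """Human-readable coefficient table and fit metrics."""
        lines = [
            "Land Use Regression Results",
            "=" * 66,
            f"No. observations: {self.nobs:>6d}    R-squared:     {self.rsquared:8.4f}",
            f"No. terms:        {len(self.terms):>6d}    Adj. R-squared:{self.rsquared_adj:8.4f}",
            f"Gates: p<{self.model.p_enter:g}, VIF<{self.model.vif_max:g}"
            f"       RMSE (ug/m3): {self.rmse:8.4f}",
            "-" * 66,
            f"{'Variable':<28}{'beta':>12}{'p':>9}{'VIF':>7}{'pR2':>8}",
            "-" * 66,
            f"{'Intercept':<28}{self.intercept:>12.4g}"
            f"{float(self.pvalues['const']):>9.3g}{'':>7}{'':>8}",
        ]
        for t in self.terms:
            lines.append(
                f"{t:<28}{float(self.params[t]):>12.4g}"
                f"{float(self.pvalues[t]):>9.3g}"
                f"{float(self.vif_[t]):>7.2f}"
                f"{float(self.partial_r2_[t]):>8.3f}"
            )
        lines.append("=" * 66)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<LURResults terms={self.terms} R2={self.rsquared:.3f} "
                f"RMSE={self.rmse:.2f}>")

    def plot_observed_vs_predicted(self, ax=None):
        """Scatter of observed vs fitted PM2.5 with the 1:1 line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = np.asarray(self.model.design.y, dtype=float)
        ax.scatter(y, self.fittedvalues, s=12, alpha=0.6)
        lo, hi = min(y.min(), self.fittedvalues.min()), max(y.max(), self.fittedvalues.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("observed PM2.5 (ug/m3)")
        ax.set_ylabel("predicted PM2.5 (ug/m3)")
        ax.set_title(f"R2 = {self.rsquared:.2f}, RMSE = {self.rmse:.2f}")
        return ax
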