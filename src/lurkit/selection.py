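"""Direction-constrained supervised stepwise selection.

The model-development procedure for the LUR:

1. *Spearman screen* — drop candidates whose rank correlation with the
   response contradicts their a-priori direction of effect.
2. *Univariate ranking* — order survivors by single-predictor R².
3. *Supervised forward/backward stepwise* — repeatedly add the candidate
   giving the largest R² gain, but only if its coefficient p-value is
   below ``p_enter`` (0.1), no variance inflation factor in the
   tentative model reaches ``vif_max`` (3), and no coefficient with a
   nonzero prior flips sign; after each accepted add, remove terms whose
   p-value has drifted above ``p_enter`` (least significant first).
4. Re-fit the final term set and re-verify every gate.

Every decision (add / remove / skip with reason) is logged to a
:class:`SelectionTrace` so a run is auditable and reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SingularModelError",
    "OLSFit",
    "SelectionTrace",
    "spearman_screen",
    "univariate_rank",
    "fit_ols",
    "vif",
    "partial_r2",
    "supervised_stepwise",
]


class SingularModelError(ValueError):
    """Raised when the requested term set is rank deficient."""


@dataclass
class OLSFit:
    """Plain OLS fit of the response on a term set (plus intercept)."""

    terms: list[str]
    params: pd.Series          # includes "const"
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    rmse: float
    nobs: int
    df_resid: float
    resid: np.ndarray
    fitted: np.ndarray

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.params["const"], dtype=float)
        for t in self.terms:
            out += self.params[t] * X[t].to_numpy(dtype=float)
        return out


def _design(X: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    return sm.add_constant(X[list(terms)].to_numpy(dtype=float), has_constant="add")


def _check_rank(X: pd.DataFrame, terms: Sequence[str]) -> None:
    M = _design(X, terms)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        # identify offending columns: those whose removal restores full rank
        offenders = []
        for t in terms:
            rest = [u for u in terms if u != t]
            R = _design(X, rest)
            if np.linalg.matrix_rank(R) == R.shape[1]:
                offenders.append(t)
        raise SingularModelError(
            f"design is rank deficient; collinear columns: {offenders or list(terms)}"
        )


def fit_ols(X: pd.DataFrame, y: pd.Series | np.ndarray,
            terms: Sequence[str]) -> OLSFit:
    """OLS of ``y`` on ``terms`` with intercept; two-sided t-test
    p-values, adjusted R² and RMSE (root mean squared residual)."""
    terms = list(terms)
    y_arr = np.asarray(y, dtype=float)
    n = len(y_arr)
    if n <= len(terms) + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={len(terms)})")
    if not terms:
        return _intercept_only_fit(y_arr)
    _check_rank(X, terms)
    res = sm.OLS(y_arr, _design(X, terms)).fit()
    index = ["const"] + terms
    return OLSFit(
        terms=terms,
        params=pd.Series(res.params, index=index),
        bse=pd.Series(res.bse, index=index),
        pvalues=pd.Series(res.pvalues, index=index),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        rmse=float(np.sqrt(np.mean(res.resid ** 2))),
        nobs=n,
        df_resid=float(res.df_resid),
        resid=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
    )


def _intercept_only_fit(y_arr: np.ndarray) -> OLSFit:
    n = len(y_arr)
    const = float(np.mean(y_arr))
    resid = y_arr - const
    return OLSFit(
        terms=[],
        params=pd.Series({"const": const}),
        bse=pd.Series({"const": float(np.std(resid, ddof=1) / np.sqrt(n))}),
        pvalues=pd.Series({"const": np.nan}),
        rsquared=0.0,
        rsquared_adj=0.0,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        nobs=n,
        df_resid=float(n - 1),
        resid=resid,
        fitted=np.full(n, const),
    )


def vif(X: pd.DataFrame, terms: Sequence[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R²_j) from regressing
    term j on the remaining terms (with intercept).

    A single-term model has no collinearity to measure; by convention
    each VIF is then 1.  Perfect collinearity yields ``inf``.
    """
    terms = list(terms)
    if len(terms) < 2:
        return pd.Series(1.0, index=terms)
    out = {}
    for t in terms:
        others = [u for u in terms if u != t]
        M = _design(X, others)
        target = X[t].to_numpy(dtype=float)
        beta, _, _, _ = np.linalg.lstsq(M, target, rcond=None)
        resid = target - M @ beta
        sst = float(np.sum((target - target.mean()) ** 2))
        if sst == 0:
            out[t] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst
        out[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def partial_r2(X: pd.DataFrame, y: pd.Series | np.ndarray,
               terms: Sequence[str], fit: OLSFit | None = None) -> pd.Series:
    """Squared partial correlation of each term with the response given
    the other terms, computed as t² / (t² + df_resid)."""
    fit = fit or fit_ols(X, y, terms)
    t = fit.params[fit.terms] / fit.bse[fit.terms]
    return (t ** 2 / (t ** 2 + fit.df_resid)).rename(None)


def spearman_screen(X: pd.DataFrame, y: pd.Series | np.ndarray,
                    priors: Mapping[str, int]) -> pd.DataFrame:
    """Spearman rank correlation of every candidate with the response,
    flagged ``keep`` when the sign agrees with a nonzero prior (or the
    prior is unconstrained).

    Zero-variance columns have undefined rho and are dropped.
    Returns a DataFrame indexed by candidate with columns
    ``rho / keep / reason``.
    """
    y_arr = np.asarray(y, dtype=float)
    if len(y_arr) < 3:
        raise ValueError("need at least 3 observations for the screen")
    rows = {}
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows[name] = (np.nan, False, "zero_variance")
            continue
        rho = float(stats.spearmanr(x, y_arr).statistic)
        prior = int(priors.get(name, 0))
        if prior == 0 or np.sign(rho) == prior:
            rows[name] = (rho, True, "")
        else:
            rows[name] = (rho, False, "wrong_direction")
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["rho", "keep", "reason"])


def univariate_rank(X: pd.DataFrame, y: pd.Series | np.ndarray,
                    candidates: Sequence[str]) -> pd.Series:
    """Candidates ordered by single-predictor R² (descending), ties
    broken lexicographically by name.  Returns R² indexed by name."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to rank")
    r2 = {}
    for name in candidates:
        fit = fit_ols(X, y, [name])
        r2[name] = fit.rsquared
    s = pd.Series(r2)
    return s.loc[sorted(s.index, key=lambda n: (-s[n], n))]


@dataclass
class SelectionTrace:
    """Ordered log of stepwise decisions.

    Each entry is a dict with ``action`` (screen_drop / add / skip /
    remove / stop), the variable involved, the reason, and the relevant
    statistics.  Replaying the same design matrix and configuration
    reproduces the identical trace.
    """

    entries: list[dict] = field(default_factory=list)

    def log(self, action: str, variable: str | None = None, **info) -> None:
        self.entries.append({"action": action, "variable": variable, **info})

    @property
    def selected(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e["action"] == "add":
                out.append(e["variable"])
            elif e["action"] == "remove":
                out.remove(e["variable"])
        return out

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, default=float) + "\n")

    def __len__(self) -> int:
        return len(self.entries)


def _gates_ok(fit: OLSFit, vifs: pd.Series, priors: Mapping[str, int],
              p_enter: float, vif_max: float) -> tuple[bool, str]:
    for t in fit.terms:
        prior = int(priors.get(t, 0))
        if prior != 0 and np.sign(fit.params[t]) != prior:
            return False, f"sign_flip:{t}"
    if (vifs >= vif_max).any():
        return False, f"vif:{vifs.idxmax()}"
    return True, ""


def supervised_stepwise(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    priors: Mapping[str, int] | None = None,
    p_enter: float = 0.1,
    vif_max: float = 3.0,
) -> tuple[OLSFit, SelectionTrace]:
    """Run the full supervised forward/backward selection.

    Returns the final re-fitted model and the decision trace.  When no
    candidate survives screening (or none is addable) the result is an
    intercept-only fit and a warning is issued.
    """
    priors = dict(priors or {})
    y_arr = np.asarray(y, dtype=float)
    trace = SelectionTrace()

    screen = spearman_screen(X, y_arr, priors)
    for name, row in screen[~screen["keep"]].iterrows():
        trace.log("screen_drop", name, reason=row["reason"], rho=row["rho"])
    pool = sorted(screen.index[screen["keep"]])

    selected: list[str] = []
    current_fit: OLSFit | None = None

    while True:
        # rank unused candidates by the R² of the tentatively extended model
        gains: dict[str, float] = {}
        for c in pool:
            if c in selected:
                continue
            try:
                gains[c] = fit_ols(X, y_arr, selected + [c]).rsquared
            except (SingularModelError, ValueError):
                gains[c] = -np.inf
        if not gains:
            trace.log("stop", reason="pool_exhausted")
            break
        order = sorted(gains, key=lambda n: (-gains[n], n))

        added = None
        for c in order:
            if not np.isfinite(gains[c]):
                trace.log("skip", c, reason="singular")
                continue
            fit = fit_ols(X, y_arr, selected + [c])
            p_c = float(fit.pvalues[c])
            if p_c >= p_enter:
                trace.log("skip", c, reason="p_value", p=p_c)
                continue
            vifs = vif(X, fit.terms)
            ok, why = _gates_ok(fit, vifs, priors, p_enter, vif_max)
            if not ok:
                trace.log("skip", c, reason=why,
                          vif_max=float(vifs.max()) if len(vifs) else 1.0)
                continue
            selected.append(c)
            current_fit = fit
            trace.log("add", c, p=p_c, r2=fit.rsquared,
                      vif_max=float(vifs.max()))
            added = c
            break
        if added is None:
            trace.log("stop", reason="no_addable_candidate")
            break

        # backward pass: drop terms whose p-value rose above the gate
        while len(selected) > 1:
            fit = fit_ols(X, y_arr, selected)
            p = fit.pvalues[fit.terms]
            worst = p.idxmax() if p.max() >= p_enter else None
            if worst is None:
                current_fit = fit
                break
            selected.remove(worst)
            trace.log("remove", worst, reason="p_value", p=float(p[worst]))
        if len(selected) == 1:
            current_fit = fit_ols(X, y_arr, selected)

    if not selected:
        warnings.warn("no candidate survived the selection gates; "
                      "returning an intercept-only model")
        return _intercept_only_fit(y_arr), trace

    # final re-fit and gate verification
    final = fit_ols(X, y_arr, sorted(selected, key=selected.index))
    vifs = vif(X, final.terms)
    ok, why = _gates_ok(final, vifs, priors, p_enter, vif_max)
    p_bad = final.pvalues[final.terms].max() >= p_enter
    trace.log("final", reason="" if ok and not p_bad else f"gate_violation:{why}",
              terms=list(final.terms), r2=final.rsquared)
    return final, trace
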