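"""The supervised stepwise engine: screen, ranking, OLS, VIF, stepwise."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lurkit import (
    SingularModelError,
    fit_ols,
    partial_r2,
    spearman_screen,
    supervised_stepwise,
    univariate_rank,
    vif,
)


@pytest.fixture
def random_xy(rng):
    X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x1", "x2", "x3"])
    y = 1.0 + 2.0 * X["x1"] - 0.5 * X["x3"] + rng.normal(0, 0.8, 50)
    return X, y


class TestSpearmanScreen:
    def test_monotone_relation_gives_rho_one(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = np.exp(np.arange(10.0))
        out = spearman_screen(X, y, {})
        assert out.loc["x", "rho"] == pytest.approx(1.0)

    def test_wrong_direction_dropped(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"ndvi": x})
        y = 2 * x + rng.normal(0, 0.5, 100)  # strongly positive relation
        out = spearman_screen(X, y, {"ndvi": -1})
        assert not out.loc["ndvi", "keep"]
        assert out.loc["ndvi", "reason"] == "wrong_direction"

    def test_hand_computed_small_table(self):
        # points (1,2),(2,1),(3,3): ranks give rho = 1 - 6*2/(3*8) = 0.5
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = spearman_screen(X, np.array([2.0, 1.0, 3.0]), {})
        assert out.loc["x", "rho"] == pytest.approx(0.5)

    def test_zero_variance_dropped(self):
        X = pd.DataFrame({"flat": np.ones(10), "x": np.arange(10.0)})
        out = spearman_screen(X, np.arange(10.0), {})
        assert not out.loc["flat", "keep"]
        assert out.loc["flat", "reason"] == "zero_variance"


class TestUnivariateRank:
    def test_exact_predictor_ranks_first(self, rng):
        X = pd.DataFrame({"signal": rng.normal(size=40),
                          "noise": rng.normal(size=40)})
        y = X["signal"].to_numpy()
        ranked = univariate_rank(X, y, ["noise", "signal"])
        assert ranked.index[0] == "signal"
        assert ranked.iloc[0] == pytest.approx(1.0)

    def test_duplicate_column_ties_break_by_name(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"b_copy": x, "a_copy": x})
        y = x + rng.normal(0, 0.1, 40)
        ranked = univariate_rank(X, y, ["b_copy", "a_copy"])
        assert list(ranked.index) == ["a_copy", "b_copy"]

    def test_matches_squared_correlation_oracle(self, random_xy):
        X, y = random_xy
        ranked = univariate_rank(X, y, list(X.columns))
        for name in X.columns:
            r = np.corrcoef(X[name], y)[0, 1]
            assert ranked[name] == pytest.approx(r * r, abs=1e-10)


class TestFitOLS:
    def test_noiseless_line_recovered_exactly(self):
        X = pd.DataFrame({"x": np.linspace(0, 10, 30)})
        y = 2 * X["x"] + 1
        fit = fit_ols(X, y, ["x"])
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_row_permutation_invariance(self, random_xy):
        X, y = random_xy
        fit = fit_ols(X, y, ["x1", "x2"])
        perm = np.random.default_rng(3).permutation(len(y))
        fit2 = fit_ols(X.iloc[perm].reset_index(drop=True),
                       np.asarray(y)[perm], ["x1", "x2"])
        pd.testing.assert_series_equal(fit.params, fit2.params)

    def test_matches_normal_equations_oracle(self, random_xy):
        X, y = random_xy
        fit = fit_ols(X, y, ["x1", "x2", "x3"])
        M = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta = np.linalg.solve(M.T @ M, M.T @ np.asarray(y))
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        resid = np.asarray(y) - M @ beta
        s2 = resid @ resid / (len(y) - M.shape[1])
        se = np.sqrt(np.diag(s2 * np.linalg.inv(M.T @ M)))
        t = beta / se
        p = 2 * stats.t.sf(np.abs(t), len(y) - M.shape[1])
        assert np.allclose(fit.pvalues.to_numpy(), p, atol=1e-10)

    def test_rank_deficiency_names_columns(self, random_xy):
        X, y = random_xy
        X = X.assign(dup=X["x1"])
        with pytest.raises(SingularModelError, match="dup|x1"):
            fit_ols(X, y, ["x1", "x2", "dup"])

    def test_too_few_rows_raises(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_ols(X, np.array([1.0, 2.0]), ["x"])


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        assert np.allclose(vif(X, ["a", "b"]), 1.0)

    def test_duplicate_predictor_is_infinite(self, random_xy):
        X, _ = random_xy
        X = X.assign(dup=X["x1"])
        v = vif(X, ["x1", "dup"])
        assert np.isinf(v).all()

    def test_matches_auxiliary_regression_oracle(self, rng):
        z = rng.normal(size=80)
        X = pd.DataFrame({
            "a": z + rng.normal(0, 0.6, 80),
            "b": z + rng.normal(0, 0.8, 80),
            "c": rng.normal(size=80),
        })
        got = vif(X, ["a", "b", "c"])
        import statsmodels.api as sm
        for t in ["a", "b", "c"]:
            others = [u for u in ["a", "b", "c"] if u != t]
            r2 = sm.OLS(X[t], sm.add_constant(X[others])).fit().rsquared
            assert got[t] == pytest.approx(1 / (1 - r2))
        assert (got >= 1).all()

    def test_single_term_is_one_by_convention(self, random_xy):
        X, _ = random_xy
        assert vif(X, ["x1"]).tolist() == [1.0]


class TestPartialR2:
    def test_single_term_equals_r2(self, random_xy):
        X, y = random_xy
        fit = fit_ols(X, y, ["x1"])
        pr2 = partial_r2(X, y, ["x1"], fit=fit)
        assert pr2["x1"] == pytest.approx(fit.rsquared)

    def test_matches_residual_on_residual_oracle(self, random_xy):
        X, y = random_xy
        terms = ["x1", "x3"]
        pr2 = partial_r2(X, y, terms)
        import statsmodels.api as sm
        for t in terms:
            others = [u for u in terms if u != t]
            ry = sm.OLS(np.asarray(y), sm.add_constant(X[others])).fit().resid
            rx = sm.OLS(X[t], sm.add_constant(X[others])).fit().resid
            r = np.corrcoef(rx, ry)[0, 1]
            assert pr2[t] == pytest.approx(r * r, abs=1e-10)

    def test_values_in_unit_interval(self, random_xy):
        X, y = random_xy
        pr2 = partial_r2(X, y, ["x1", "x2", "x3"])
        assert ((pr2 >= 0) & (pr2 <= 1)).all()


def _engineered_instance(seed, n=120):
    """Strong x1/x2 signals, three null candidates, one near-clone of x1."""
    g = np.random.default_rng(seed)
    X = pd.DataFrame({f"c{i}": g.normal(size=n) for i in range(1, 6)})
    X["c6"] = X["c1"] + 0.05 * g.normal(size=n)
    y = 2.0 * X["c1"] + 1.0 * X["c2"] + 0.5 * g.normal(size=n)
    priors = {"c1": 1, "c2": 1, "c6": 1}
    return X, y, priors


def _exhaustive_best_subset(X, y, priors, p_enter=0.1, vif_max=3.0):
    """All-subsets search under the same gates (independent oracle)."""
    best, best_r2 = None, -np.inf
    for k in range(1, len(X.columns) + 1):
        for combo in itertools.combinations(sorted(X.columns), k):
            try:
                fit = fit_ols(X, y, list(combo))
            except (SingularModelError, ValueError):
                continue
            if (fit.pvalues[list(combo)] >= p_enter).any():
                continue
            if (vif(X, list(combo)) >= vif_max).any():
                continue
            if any(np.sign(fit.params[t]) != priors[t]
                   for t in combo if priors.get(t, 0) != 0):
                continue
            if fit.rsquared > best_r2:
                best, best_r2 = set(combo), fit.rsquared
    return best


class TestSupervisedStepwise:
    def test_single_signal_among_noise(self):
        g = np.random.default_rng(1)
        X = pd.DataFrame(g.normal(size=(200, 11)),
                         columns=[f"n{i}" for i in range(10)] + ["x1"])
        y = 2 * X["x1"] + g.normal(0, 0.05, 200)
        fit, trace = supervised_stepwise(X, y, {})
        assert fit.terms == ["x1"]
        assert trace.selected == ["x1"]

    def test_collinear_clone_blocked_by_vif_gate(self, rng):
        x = rng.normal(size=150)
        X = pd.DataFrame({"x1": x, "clone": x + 0.02 * rng.normal(size=150),
                          "other": rng.normal(size=150)})
        y = 3 * x + rng.normal(0, 0.5, 150)
        fit, _ = supervised_stepwise(X, y, {})
        assert len({"x1", "clone"} & set(fit.terms)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_best_subset(self, seed):
        X, y, priors = _engineered_instance(seed)
        fit, _ = supervised_stepwise(X, y, priors)
        oracle = _exhaustive_best_subset(X, y, priors)
        assert set(fit.terms) == oracle

    def test_deterministic_trace(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 6)),
                         columns=list("abcdef"))
        y = X["a"] - X["b"] + rng.normal(0, 0.5, 80)
        fit1, tr1 = supervised_stepwise(X, y, {})
        fit2, tr2 = supervised_stepwise(X, y, {})
        assert tr1.entries == tr2.entries
        assert fit1.terms == fit2.terms

    def test_intercept_only_when_nothing_survives(self):
        X = pd.DataFrame({"x": np.ones(20) * 5})  # zero variance
        y = np.random.default_rng(0).normal(10, 1, 20)
        with pytest.warns(UserWarning, match="intercept-only"):
            fit, _ = supervised_stepwise(X, y, {})
        assert fit.terms == []
        assert fit.params["const"] == pytest.approx(np.mean(y))

    def test_null_response_selects_few(self):
        """Pure-noise response: runaway selection is prevented by the
        gates (median model size <= 2 across seeds)."""
        sizes = []
        for seed in range(12):
            g = np.random.default_rng(seed)
            X = pd.DataFrame(g.normal(size=(200, 30)),
                             columns=[f"v{i:02d}" for i in range(30)])
            priors = {f"v{i:02d}": (1 if i % 3 == 0 else -1 if i % 3 == 1 else 0)
                      for i in range(30)}
            y = g.normal(size=200)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fit, _ = supervised_stepwise(X, y, priors)
            sizes.append(len(fit.terms))
        assert np.median(sizes) <= 2
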