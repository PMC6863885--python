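"""Likelihood oracles, parameter recovery and multimodel inference."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from ibrscape.model_engine import (MLPEStructure, average_and_importance,
                                   dredge, enumerate_subsets, fit_gls,
                                   fit_lmm, fit_mlpe, lrt, rank_models,
                                   standardize)

RNG = np.random.default_rng(1)


def mvn_loglik(y, mu, Sigma):
    return float(multivariate_normal.logpdf(y, mu, Sigma, allow_singular=True))


class TestGLS:
    def _data(self, n=40, seed=1):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 20, (n, 2))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        L = np.linalg.cholesky(np.exp(-d / 5.0) + 1e-9 * np.eye(n))
        x = rng.normal(size=n)
        y = 1 + 0.5 * x + L @ rng.normal(size=n)
        return pd.DataFrame({"y": y, "x": x}), coords

    def test_identity_covariance_equals_ols(self):
        data, _ = self._data()
        fit = fit_gls(data, "y", ["x"], family="none")
        X = np.column_stack([np.ones(len(data)), data["x"]])
        beta_ols = np.linalg.lstsq(X, data["y"], rcond=None)[0]
        assert np.allclose(fit.coef, beta_ols, atol=1e-8)

    @pytest.mark.parametrize("family", ["exponential", "gaussian",
                                        "spherical", "linear"])
    def test_loglik_matches_mvn_oracle(self, family):
        data, coords = self._data()
        fit = fit_gls(data, "y", ["x"], coords=coords, family=family)
        mu = np.column_stack([np.ones(len(data)), data["x"]]) @ fit.coef
        assert fit.loglik == pytest.approx(
            mvn_loglik(data["y"], mu, fit.Sigma), abs=1e-6)

    def test_range_and_beta_recovery(self):
        # exponential range 10, n=100; median over replicates
        ranges, betas = [], []
        for rep in range(20):
            rng = np.random.default_rng(2000 + rep)
            n = 100
            coords = rng.uniform(0, 50, (n, 2))
            d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
            L = np.linalg.cholesky(np.exp(-d / 10.0) + 1e-9 * np.eye(n))
            x = rng.normal(size=n)
            y = 1 + 2.0 * x + L @ rng.normal(size=n)
            fit = fit_gls(pd.DataFrame({"y": y, "x": x}), "y", ["x"],
                          coords=coords, family="exponential")
            ranges.append(fit.cov_params["range"])
            betas.append(fit["x"])
        assert np.median(ranges) == pytest.approx(10.0, rel=0.30)
        assert np.median(betas) == pytest.approx(2.0, rel=0.05)

    def test_variance_weights_recovered(self):
        rng = np.random.default_rng(3)
        g = np.repeat(["a", "b"], 100)
        y = np.where(g == "a", rng.normal(0, 1, 200), rng.normal(0, 3, 200))
        fit = fit_gls(pd.DataFrame({"y": y, "g": g}), "y", [],
                      weights_group="g")
        w = fit.cov_params["variance_weights"]
        assert w[0] == 1.0
        assert np.sqrt(w[1]) == pytest.approx(3.0, rel=0.3)


class TestLMM:
    def test_zero_group_effect_degenerates_to_ols(self):
        rng = np.random.default_rng(4)
        g = np.repeat(np.arange(10), 10)
        x = rng.normal(size=100)
        y = 1 + 0.5 * x + rng.normal(size=100)
        data = pd.DataFrame({"y": y, "x": x, "g": g})
        lmm = fit_lmm(data, "y", ["x"], ["g"])
        ols = fit_gls(data, "y", ["x"], family="none")
        assert abs(lmm["x"] - ols["x"]) < ols.se[1]
        assert lmm.cov_params["group_variances"]["g"] < 0.05

    def test_loglik_matches_mvn_oracle(self):
        rng = np.random.default_rng(5)
        g = np.repeat(np.arange(8), 5)
        b = rng.normal(0, 1, 8)
        x = rng.normal(size=40)
        y = 2 + 0.3 * x + b[g] + rng.normal(size=40)
        fit = fit_lmm(pd.DataFrame({"y": y, "x": x, "g": g}), "y", ["x"], ["g"])
        mu = np.column_stack([np.ones(40), x]) @ fit.coef
        assert fit.loglik == pytest.approx(mvn_loglik(y, mu, fit.Sigma),
                                           abs=1e-6)

    def test_group_variance_recovery(self):
        vars_ = []
        for rep in range(20):
            rng = np.random.default_rng(3000 + rep)
            g = np.repeat(np.arange(20), 10)
            b = rng.normal(0, 1, 20)
            x = rng.normal(size=200)
            y = 1 + 0.5 * x + b[g] + rng.normal(size=200)
            fit = fit_lmm(pd.DataFrame({"y": y, "x": x, "g": g}),
                          "y", ["x"], ["g"])
            vars_.append(fit.cov_params["group_variances"]["g"])
        assert 0.7 <= np.median(vars_) <= 1.3


class TestMLPE:
    def test_incidence_structure(self):
        # AA': diagonal 2, 1 when pairs share an individual, else 0
        for m in (4, 6, 8):
            pairs = np.array(list(combinations(range(m), 2)))
            st = MLPEStructure(pairs)
            AA = st.A @ st.A.T
            assert np.allclose(np.diag(AA), 2.0)
            for a in range(len(pairs)):
                for b in range(a + 1, len(pairs)):
                    shared = len(set(pairs[a]) & set(pairs[b]))
                    assert AA[a, b] == shared

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            MLPEStructure(np.array([[0, 1], [1, 0]]))

    def test_zero_pair_variance_matches_ols(self):
        rng = np.random.default_rng(6)
        pairs = np.array(list(combinations(range(12), 2)))
        x = rng.normal(size=len(pairs))
        y = 1 + 0.8 * x + rng.normal(size=len(pairs))
        tbl = pd.DataFrame({"id1": pairs[:, 0], "id2": pairs[:, 1],
                            "y": y, "x": x})
        fit = fit_mlpe(tbl, "y", ["x"])
        assert fit.cov_params["rho"] < 0.05
        ols = fit_gls(tbl, "y", ["x"], family="none")
        assert abs(fit["x"] - ols["x"]) < 2 * ols.se[1]

    def test_loglik_matches_mvn_oracle(self):
        rng = np.random.default_rng(7)
        pairs = np.array(list(combinations(range(10), 2)))
        st = MLPEStructure(pairs)
        V = np.eye(len(pairs)) + 0.75 * (st.A @ st.A.T)
        L = np.linalg.cholesky(V)
        x = rng.normal(size=len(pairs))
        y = x + L @ rng.normal(size=len(pairs))
        tbl = pd.DataFrame({"id1": pairs[:, 0], "id2": pairs[:, 1],
                            "y": y, "x": x})
        fit = fit_mlpe(tbl, "y", ["x"], structure=st)
        mu = np.column_stack([np.ones(len(pairs)), x]) @ fit.coef
        assert fit.loglik == pytest.approx(mvn_loglik(y, mu, fit.Sigma),
                                           abs=1e-6)

    def test_extra_group_factor_fits(self):
        rng = np.random.default_rng(8)
        pairs = np.array(list(combinations(range(10), 2)))
        same = rng.integers(0, 2, len(pairs))
        y = rng.normal(size=len(pairs)) + 0.5 * same
        tbl = pd.DataFrame({"id1": pairs[:, 0], "id2": pairs[:, 1],
                            "y": y, "g": same})
        fit = fit_mlpe(tbl, "y", [], extra_group="g")
        assert "extra_group_variance" in fit.cov_params
        assert np.isfinite(fit.loglik)


class TestInference:
    def _fits(self, aics):
        return [type("F", (), {"aic": a, "aicc": a, "method": "ML",
                               "n_obs": 10, "model_name": f"m{i}",
                               "n_params": 2, "loglik": -a / 2 + 2})()
                for i, a in enumerate(aics)]

    def test_single_model(self):
        t = rank_models(self._fits([100.0]))
        assert t.table["dAIC"].iloc[0] == 0
        assert t.table["wAIC"].iloc[0] == pytest.approx(1.0)

    def test_two_units_apart_weight_ratio_e(self):
        t = rank_models(self._fits([100.0, 102.0]))
        w = t.table.sort_values("AIC")["wAIC"].to_numpy()
        assert w[0] / w[1] == pytest.approx(np.e, rel=1e-9)

    def test_weights_sum_to_one(self):
        t = rank_models(self._fits([5.0, 7.0, 20.0, 3.3]))
        assert t.table["wAIC"].sum() == pytest.approx(1.0)

    def test_lrt_identical_models(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame({"y": rng.normal(size=30),
                             "x": rng.normal(size=30)})
        full = fit_gls(data, "y", ["x"], family="none")
        with pytest.raises(ValueError):
            lrt(full, full)  # zero df difference

    def test_lrt_nonnegative_and_type1(self):
        rejections = 0
        n_rep = 500
        for rep in range(n_rep):
            rng = np.random.default_rng(4000 + rep)
            x = rng.normal(size=100)
            y = 1 + rng.normal(size=100)
            data = pd.DataFrame({"y": y, "x": x})
            full = fit_gls(data, "y", ["x"], family="none")
            reduced = fit_gls(data, "y", [], family="none")
            D, p, df = lrt(full, reduced)
            assert D >= 0 and df == 1
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.08

    def test_averaging_single_model(self):
        rng = np.random.default_rng(10)
        data = pd.DataFrame({"y": rng.normal(size=30),
                             "x": rng.normal(size=30)})
        fit = fit_gls(data, "y", ["x"], family="none", model_name="x")
        table = rank_models([fit])
        out = average_and_importance(table)
        assert out["averaged"].loc["x", "coef"] == pytest.approx(fit["x"])

    def test_averaging_two_equal_models(self):
        f1 = type("F", (), {"aic": 10.0, "aicc": 10.0, "method": "ML",
                            "n_obs": 5, "model_name": "a", "n_params": 2,
                            "loglik": -3.0, "names": ["(Intercept)", "v"],
                            "se": np.array([1.0, 0.5]),
                            "__getitem__": lambda s, k: {"(Intercept)": 0.0,
                                                         "v": 1.0}[k]})()
        f2 = type("F", (), {"aic": 10.0, "aicc": 10.0, "method": "ML",
                            "n_obs": 5, "model_name": "b", "n_params": 2,
                            "loglik": -3.0, "names": ["(Intercept)", "v"],
                            "se": np.array([1.0, 0.5]),
                            "__getitem__": lambda s, k: {"(Intercept)": 0.0,
                                                         "v": 3.0}[k]})()
        out = average_and_importance(rank_models([f1, f2]))
        assert out["averaged"].loc["v", "coef"] == pytest.approx(2.0)
        assert all(0 <= v <= 1 for v in out["importance"].values())


class TestDredge:
    def _fit_fn(self, data, response, predictors, model_name=""):
        return fit_gls(data, response, list(predictors), family="none",
                       model_name=model_name)

    def test_collinear_pair_excluded(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(size=60)
        x2 = x1 + rng.normal(0, 0.1, 60)  # |r| >= 0.6 with x1
        x3 = rng.normal(size=60)
        y = x1 + rng.normal(size=60)
        data = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})
        table = dredge(data, "y", ["x1", "x2", "x3"], self._fit_fn)
        # 2^3 = 8 subsets minus the 2 containing {x1, x2} -> 6 incl. null
        assert len(table.table) == 6

    def test_zero_predictors_null_only(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame({"y": rng.normal(size=20)})
        table = dredge(data, "y", [], self._fit_fn)
        assert len(table.table) == 1

    def test_enumeration_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        names = [f"x{i}" for i in range(5)]
        data = pd.DataFrame(rng.normal(size=(50, 5)), columns=names)
        data["x1"] = data["x0"] * 0.9 + rng.normal(0, 0.1, 50)
        corr = data[names].corr()
        subsets = enumerate_subsets(names, corr, 0.6)
        banned = {(a, b) for a in names for b in names
                  if a < b and abs(corr.loc[a, b]) >= 0.6}
        import itertools
        expected = [s for k in range(6)
                    for s in itertools.combinations(names, k)
                    if not any(set(p) <= set(s) for p in banned)]
        assert sorted(subsets) == sorted(expected)

    def test_aic_invariant_to_predictor_order(self):
        rng = np.random.default_rng(14)
        data = pd.DataFrame({"y": rng.normal(size=40),
                             "a": rng.normal(size=40),
                             "b": rng.normal(size=40)})
        f1 = self._fit_fn(data, "y", ["a", "b"])
        f2 = self._fit_fn(data, "y", ["b", "a"])
        assert f1.aic == pytest.approx(f2.aic, abs=1e-9)


def test_standardize_constant_input():
    assert np.allclose(standardize(np.full(5, 3.0)), 0.0)
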