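"""Logistic-regression design assessment: fitting, LRTs, Nagelkerke R2."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from secoer.models import (
    ModelSpec,
    add_pseudo_observation,
    drop_variable,
    find_separated_cells,
    fit_logistic,
    lrt,
    model_spec,
    nagelkerke_r2,
    predict_success,
    standardize_covariates,
    type2_term_tests,
    variable_lrt_table,
)


def crossed_grid(rng, n_per_cell=10, crosses=("1:1_1f", "dil:mt"),
                 beta=None):
    """Fully crossed synthetic records (cross x h x N), with continuous s and
    af; responses from a known logistic model when beta is given."""
    rows = []
    for cross in crosses:
        for h in (0.5, 1.0):
            for N in (300, 1200, 4800, 19200):
                for _ in range(n_per_cell):
                    rows.append(dict(cross=cross, h=h, N=N,
                                     s=rng.uniform(0.07, 0.1),
                                     af=rng.uniform(0.05, 0.6)))
    df = pd.DataFrame(rows)
    if beta is None:
        df["success_b"] = rng.integers(0, 2, len(df))
    else:
        lp = (beta["intercept"]
              + beta["cross"] * (df["cross"] == crosses[-1])
              + beta["h"] * (df["h"] == 1.0)
              + beta["s"] * df["s"] * 100
              + beta["af"] * df["af"] * 100)
        df["success_b"] = rng.random(len(df)) < 1 / (1 + np.exp(-lp))
    df["success_b"] = df["success_b"].astype(int)
    return df


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        df = crossed_grid(rng)
        out, params = standardize_covariates(df)
        assert out["s"].mean() == pytest.approx(0, abs=1e-12)
        assert out["s"].std(ddof=0) == pytest.approx(1, abs=1e-12)
        assert set(params) == {"s", "af"}

    def test_constant_column_rejected(self, rng):
        df = crossed_grid(rng)
        df["af"] = 0.5
        with pytest.raises(ValueError, match="af"):
            standardize_covariates(df)

    def test_stored_transform_reproduces_training(self, rng):
        df = crossed_grid(rng)
        out1, params = standardize_covariates(df)
        out2, _ = standardize_covariates(df, params=params)
        assert np.allclose(out1["s"], out2["s"])
        assert np.allclose(out1["af"], out2["af"])


class TestFit:
    def test_intercept_only_is_logit_of_proportion(self):
        df = pd.DataFrame({"success_b": [1] * 30 + [0] * 70})
        fit = fit_logistic(df, ModelSpec("success_b", ()))
        assert fit.params["Intercept"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_coefficient_recovery(self):
        """Parameter-recovery oracle: data simulated from known coefficients
        (n = 10,000); every fitted coefficient within 3 SE of the truth."""
        rng = np.random.default_rng(100)
        df = crossed_grid(rng, n_per_cell=625,
                          beta=dict(intercept=0.4, cross=-1.2, h=-0.8,
                                    s=0.35, af=0.12))
        assert len(df) == 10_000
        df, _ = standardize_covariates(df)
        spec = ModelSpec("success_b", (("cross",), ("h",), ("s",), ("af",)))
        fit = fit_logistic(df, spec)
        # map the generating coefficients onto the standardized scale
        raw = crossed_grid(np.random.default_rng(100), n_per_cell=625)
        sd_s = (raw["s"] * 100).std(ddof=0)
        sd_af = (raw["af"] * 100).std(ddof=0)
        truth = {"cross[dil:mt]": -1.2, "h[1.0]": -0.8,
                 "s": 0.35 * sd_s, "af": 0.12 * sd_af}
        for name, b in truth.items():
            assert abs(fit.params[name] - b) < 3 * fit.bse[name], name

    def test_duplicated_rows_double_loglik(self, rng):
        df = crossed_grid(rng, n_per_cell=5)
        spec = ModelSpec("success_b", (("h",), ("s",)))
        f1 = fit_logistic(df, spec)
        f2 = fit_logistic(pd.concat([df, df], ignore_index=True), spec)
        assert np.allclose(f1.params, f2.params, atol=1e-6)
        assert f2.llf == pytest.approx(2 * f1.llf, rel=1e-6)

    def test_rank_deficiency_raises(self, rng):
        df = crossed_grid(rng, n_per_cell=5)
        df["s2"] = df["s"]
        spec = ModelSpec("success_b", (("s",), ("s2",)))
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(df, spec)

    def test_separation_flagged(self):
        df = pd.DataFrame({
            "x": [0.0] * 20 + [1.0] * 20,
            "success_b": [0] * 20 + [1] * 20,
        })
        fit = fit_logistic(df, ModelSpec("success_b", (("x",),)))
        assert fit.separation


class TestLRT:
    def test_identical_models(self, rng):
        df = crossed_grid(rng, n_per_cell=5)
        spec = ModelSpec("success_b", (("h",),))
        f = fit_logistic(df, spec)
        chi2, dof, p = lrt(f, f)
        assert chi2 == 0 and dof == 0

    def test_arithmetic(self):
        from secoer.models import FitResult
        mk = lambda llf, k: FitResult(  # noqa: E731
            spec=ModelSpec("success_b", ()), params=pd.Series(np.zeros(k)),
            bse=pd.Series(np.zeros(k)), cov=pd.DataFrame(np.zeros((k, k))),
            llf=llf, df_resid=100 - k, n=100, converged=True, separation=False)
        chi2, dof, p = lrt(mk(-10.0, 3), mk(-15.0, 1))
        assert chi2 == pytest.approx(10.0)
        assert dof == 2
        assert p == pytest.approx(sps.chi2.sf(10, 2))

    def test_different_data_raises(self, rng):
        df = crossed_grid(rng, n_per_cell=5)
        spec = ModelSpec("success_b", (("h",),))
        f1 = fit_logistic(df, spec)
        f2 = fit_logistic(df.iloc[: len(df) // 2], spec)
        with pytest.raises(ValueError):
            lrt(f1, f2)

    def test_null_pvalues_uniform(self):
        """Under the null (coefficient truly zero) LRT p-values are
        approximately uniform (KS test over repeated refits)."""
        rng = np.random.default_rng(7)
        pvals = []
        spec_full = ModelSpec("success_b", (("h",), ("s",)))
        spec_red = ModelSpec("success_b", (("h",),))
        for _ in range(300):
            df = pd.DataFrame({
                "h": rng.choice([0.5, 1.0], 150),
                "s": rng.normal(size=150),
                "success_b": rng.integers(0, 2, 150),
            })
            chi2, dof, p = lrt(fit_logistic(df, spec_full),
                               fit_logistic(df, spec_red))
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestDfBookkeeping:
    def test_model1_variable_df(self, rng):
        """Dropping a variable removes its main effect and all its
        interactions: cross -> 8 df, N -> 12, af -> 2, h -> 9, s -> 1 at the
        canonical codings (2 crosses x 2 h x 4 N)."""
        df, _ = standardize_covariates(crossed_grid(rng))
        spec = model_spec(1)
        full = fit_logistic(df, spec)
        expected = {"cross": 8, "N": 12, "af": 2, "h": 9, "s": 1}
        for var, k in expected.items():
            red = fit_logistic(df, drop_variable(spec, var))
            assert full.n_params - red.n_params == k, var

    def test_drop_unknown_variable(self):
        with pytest.raises(ValueError):
            drop_variable(model_spec(1), "bogus")

    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec("success_b", (("cross", "h"),))

    def test_model2_has_no_af(self):
        assert all("af" not in t for t in model_spec(2).terms)


class TestNagelkerke:
    def test_full_equals_null_gives_zero(self, rng):
        df = crossed_grid(rng, n_per_cell=5)
        f = fit_logistic(df, ModelSpec("success_b", ()))
        assert nagelkerke_r2(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit_worked_example(self):
        """n=4, ll_null = 4 ln 0.5, ll_full = 0 -> R2 = 1 (formula
        evaluation)."""
        from secoer.models import FitResult
        mk = lambda llf: FitResult(  # noqa: E731
            spec=ModelSpec("success_b", ()), params=pd.Series(dtype=float),
            bse=pd.Series(dtype=float), cov=pd.DataFrame(),
            llf=llf, df_resid=4, n=4, converged=True, separation=False)
        assert nagelkerke_r2(mk(0.0), mk(4 * np.log(0.5)), n=4) == pytest.approx(1.0)

    def test_bounded_and_monotone(self, rng):
        df, _ = standardize_covariates(crossed_grid(rng))
        spec = model_spec(1)
        full = fit_logistic(df, spec)
        null = fit_logistic(df, ModelSpec("success_b", ()))
        r2 = nagelkerke_r2(full, null)
        assert 0 <= r2 <= 1
        mid = fit_logistic(df, ModelSpec("success_b", (("cross",), ("h",))))
        assert nagelkerke_r2(mid, null) <= r2 + 1e-9


class TestType2:
    def test_structure_and_df(self, rng):
        df, _ = standardize_covariates(crossed_grid(rng))
        tab = type2_term_tests(df, model_spec(1))
        assert set(tab["term"]) == {":".join(t) for t in model_spec(1).terms}
        by_term = tab.set_index("term")["df"]
        assert by_term["s"] == 1
        assert by_term["cross:h:N"] == 3
        assert by_term["N"] == 3

    def test_null_term_rejection_rate(self):
        """A term with zero true effect is rejected at ~ the nominal 5%
        rate."""
        rng = np.random.default_rng(21)
        rejections = []
        spec = ModelSpec("success_b", (("h",), ("s",)))
        for _ in range(200):
            df = pd.DataFrame({
                "h": rng.choice([0.5, 1.0], 200),
                "s": rng.normal(size=200),
                # response depends on h only; s is a null term
                "success_b": 0,
            })
            p_h = 1 / (1 + np.exp(-(df["h"] == 1.0) * 1.0 + 0.5))
            df["success_b"] = (rng.random(200) < p_h).astype(int)
            tab = type2_term_tests(df, spec).set_index("term")
            rejections.append(tab.loc["s", "p"] < 0.05)
        assert 0.01 <= np.mean(rejections) <= 0.10


class TestPseudoObservation:
    def test_separated_cell_fixed(self, rng):
        df = crossed_grid(rng, n_per_cell=6)
        mask = (df["cross"] == "dil:mt") & (df["h"] == 0.5)
        df.loc[mask, "success_b"] = 0
        cells = find_separated_cells(df, "success_b", ("cross", "h"))
        assert any(c["cross"] == "dil:mt" and c["h"] == 0.5 for c in cells)
        out = add_pseudo_observation(df, {"cross": "dil:mt", "h": 0.5},
                                     "success_b", 1)
        assert len(out) == len(df) + 1
        sub = out[(out["cross"] == "dil:mt") & (out["h"] == 0.5)]
        assert sub["success_b"].nunique() == 2
        assert out["pseudo"].sum() == 1

    def test_non_separated_cell_noop(self, rng):
        df = crossed_grid(rng, n_per_cell=20)
        with pytest.warns(UserWarning):
            out = add_pseudo_observation(df, {"cross": "1:1_1f"}, "success_b", 1)
        assert len(out) == len(df)


class TestPredict:
    def make_fit(self, rng):
        df = crossed_grid(rng, n_per_cell=30)
        df, scale = standardize_covariates(df)
        spec = ModelSpec("success_b", (("cross",), ("h",), ("s",), ("af",)))
        return fit_logistic(df, spec, scale_params=scale)

    def test_inverse_logit_values(self):
        from secoer.models import FitResult
        fit = FitResult(
            spec=ModelSpec("success_b", ()),
            params=pd.Series({"Intercept": 2.0}),
            bse=pd.Series({"Intercept": 0.1}),
            cov=pd.DataFrame([[0.01]], index=["Intercept"], columns=["Intercept"]),
            llf=-1.0, df_resid=10, n=11, converged=True, separation=False)
        p, lo, hi = predict_success(fit, {})
        assert p == pytest.approx(np.exp(2) / (1 + np.exp(2)), abs=1e-9)  # 0.8808
        fit.params["Intercept"] = 0.0
        assert predict_success(fit, {})[0] == pytest.approx(0.5)

    def test_ci_inside_unit_interval(self, rng):
        fit = self.make_fit(rng)
        p, lo, hi = predict_success(
            fit, {"cross": "1:1_1f", "h": 1.0, "s": 0.085, "af": 0.3})
        assert 0 < lo <= p <= hi < 1

    def test_unknown_level_rejected(self, rng):
        fit = self.make_fit(rng)
        with pytest.raises(ValueError, match="level"):
            predict_success(fit, {"cross": "bogus", "h": 1.0, "s": 0.08,
                                  "af": 0.3})


class TestVariableTable:
    def test_report_columns(self, rng):
        df, _ = standardize_covariates(crossed_grid(rng))
        tab = variable_lrt_table(df, model_spec(1))
        assert set(tab.columns) == {"variable", "chi2", "df", "p", "nagelkerke_r2"}
        assert set(tab["variable"]) == {"cross", "h", "s", "af", "N"}
        assert (tab["nagelkerke_r2"] >= -1e-9).all()
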