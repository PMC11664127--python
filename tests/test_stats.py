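import numpy as np
import pandas as pd
import pytest

from bcehi.stats import (
    covariate_trend,
    fit_random_intercept,
    latitudinal_trend,
    sobol_first_order,
)

ADDITIVE_S1 = np.array([1.0, 4.0, 9.0]) / 14.0  # Var = (1+4+9)/12, V_i = i^2/12


def additive_model(x):
    return x[:, 0] + 2.0 * x[:, 1] + 3.0 * x[:, 2]


def uniform_sampler(rng, n):
    return rng.uniform(0.0, 1.0, size=(n, 3))


def ishigami(x, a=7.0, b=0.1):
    return (
        np.sin(x[:, 0])
        + a * np.sin(x[:, 1]) ** 2
        + b * x[:, 2] ** 4 * np.sin(x[:, 0])
    )


def ishigami_sampler(rng, n):
    return rng.uniform(-np.pi, np.pi, size=(n, 3))


def ishigami_analytic_s1(a=7.0, b=0.1):
    # closed-form variance decomposition, evaluated independently:
    # V1 = (1 + b pi^4 / 5)^2 / 2, V2 = a^2 / 8, V3 = 0
    # V  = a^2/8 + b pi^4/5 + b^2 pi^8/18 + 1/2
    v1 = 0.5 * (1.0 + b * np.pi**4 / 5.0) ** 2
    v2 = a**2 / 8.0
    v = a**2 / 8.0 + b * np.pi**4 / 5.0 + b**2 * np.pi**8 / 18.0 + 0.5
    return np.array([v1 / v, v2 / v, 0.0])


class TestSobol:
    def test_additive_oracle(self):
        result = sobol_first_order(
            additive_model, uniform_sampler, n_base=2**13, seed=0
        )
        np.testing.assert_allclose(result.s1, ADDITIVE_S1, atol=0.02)
        assert np.all(result.q05 == result.s1 - 1.645 * result.se)

    def test_single_input_model(self):
        result = sobol_first_order(
            lambda x: x[:, 0], uniform_sampler, n_base=2**12, seed=1
        )
        assert result.s1[0] == pytest.approx(1.0, abs=0.03)
        assert abs(result.s1[1]) < 0.03 and abs(result.s1[2]) < 0.03

    def test_ishigami_oracle(self):
        expected = ishigami_analytic_s1()
        result = sobol_first_order(
            ishigami, ishigami_sampler, n_base=2**13, seed=2
        )
        np.testing.assert_allclose(result.s1, expected, atol=0.03)

    def test_deterministic_under_seed(self):
        a = sobol_first_order(additive_model, uniform_sampler, 512, seed=7)
        b = sobol_first_order(additive_model, uniform_sampler, 512, seed=7)
        np.testing.assert_array_equal(a.s1, b.s1)
        np.testing.assert_array_equal(a.se, b.se)

    def test_output_affine_invariance(self):
        base = sobol_first_order(additive_model, uniform_sampler, 1024, seed=3)
        scaled = sobol_first_order(
            lambda x: 7.0 * additive_model(x) + 1000.0,
            uniform_sampler, 1024, seed=3,
        )
        np.testing.assert_allclose(base.s1, scaled.s1, atol=1e-10)

    def test_additive_indices_sum_to_one(self):
        result = sobol_first_order(
            additive_model, uniform_sampler, n_base=2**13, seed=4
        )
        assert result.s1.sum() == pytest.approx(1.0, abs=0.03)

    def test_small_n_base_rejected(self):
        with pytest.raises(ValueError, match="n_base"):
            sobol_first_order(additive_model, uniform_sampler, 32)

    def test_non_finite_model_output_names_row(self):
        def bad(x):
            y = additive_model(x)
            y[5] = np.nan
            return y

        with pytest.raises(ValueError, match="row 5"):
            sobol_first_order(bad, uniform_sampler, 128, seed=0)

    def test_labels(self):
        result = sobol_first_order(
            additive_model, uniform_sampler, 128, seed=0,
            labels=("area", "height", "t"),
        )
        assert result.to_frame()["variable"].tolist() == ["area", "height", "t"]


def _trend_table(latitudes, ehi):
    return pd.DataFrame({
        "ecotone": "mangrove", "latitude": latitudes, "ehi": ehi,
    })


class TestLatitudinalTrend:
    def test_noiseless_linear_gradient(self, rng):
        # records at band centres: EHI = 0.8 - 0.007 |lat| exactly
        lat = rng.integers(-38, 29, size=400) + 0.5
        table = _trend_table(lat, 0.8 - 0.007 * np.abs(lat))
        fit = latitudinal_trend(table, "mangrove")
        assert fit.slope == pytest.approx(-0.007, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.p_value < 0.001

    def test_constant_response_zero_slope(self):
        lat = np.arange(-10, 10) + 0.5
        fit = latitudinal_trend(_trend_table(lat, np.full(20, 0.5)), "mangrove")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_band_means_used(self):
        # two records per band; the band mean drives the fit
        lat = np.repeat([0.2, 1.3, 2.4], 2)
        ehi = np.array([0.1, 0.3, 0.3, 0.5, 0.5, 0.7])
        fit = latitudinal_trend(_trend_table(lat, ehi), "mangrove")
        assert fit.n == 3
        assert fit.slope == pytest.approx(0.2, abs=1e-12)

    def test_too_few_bins(self):
        table = _trend_table(np.array([0.5, 1.5]), np.array([0.4, 0.5]))
        with pytest.raises(ValueError, match="bins"):
            latitudinal_trend(table, "mangrove")

    def test_ci_covers_true_slope(self, rng):
        lat = rng.uniform(-38.5, 29.5, size=2000)
        ehi = 0.8 - 0.007 * np.abs(lat) + rng.normal(0, 0.03, size=2000)
        fit = latitudinal_trend(_trend_table(lat, ehi), "mangrove")
        lo, hi = fit.slope_ci()
        assert lo <= -0.007 <= hi


class TestCovariateTrend:
    def test_noiseless(self):
        x = np.linspace(0.1, 0.9, 50)
        table = pd.DataFrame({"ehi": x, "soc": 689.16 * x})
        fit = covariate_trend(table, "ehi", "soc")
        assert fit.slope == pytest.approx(689.16, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_independent_variables(self, rng):
        table = pd.DataFrame({
            "ehi": rng.uniform(size=2000), "soc": rng.uniform(size=2000),
        })
        fit = covariate_trend(table, "ehi", "soc")
        assert fit.r_squared < 0.01

    def test_noise_tuned_r2(self, rng):
        # noise sd back-solved from R^2 = slope^2 Var(x) / (slope^2 Var(x) + sd^2)
        slope, r2 = 689.16, 0.37
        x = rng.uniform(0.0, 1.0, size=1000)
        var_x = 1.0 / 12.0
        sd = np.sqrt(slope**2 * var_x * (1 - r2) / r2)
        table = pd.DataFrame({"ehi": x, "soc": slope * x + rng.normal(0, sd, 1000)})
        fit = covariate_trend(table, "ehi", "soc")
        assert fit.slope == pytest.approx(slope, rel=0.10)
        assert fit.r_squared == pytest.approx(r2, abs=0.08)

    def test_missing_pairs_dropped(self):
        table = pd.DataFrame({
            "ehi": [0.1, 0.2, np.nan, 0.4],
            "soc": [1.0, 2.0, 3.0, np.nan],
        })
        with pytest.raises(ValueError, match="pairs"):
            covariate_trend(table, "ehi", "soc")

    def test_ols_matches_normal_equations(self):
        # 5-point hand-checkable case solved by the closed form
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 3.1, 4.4, 4.9])
        table = pd.DataFrame({"ehi": x, "soc": y})
        fit = covariate_trend(table, "ehi", "soc")
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)


def _grouped_data(rng, beta=(0.5, -0.2), sigma_b=0.1, sigma_e=0.05,
                  n_groups=6, n_per=200):
    rows = []
    intercepts = rng.normal(0, sigma_b, size=n_groups)
    for g in range(n_groups):
        x1 = rng.uniform(size=n_per)
        x2 = rng.uniform(size=n_per)
        y = (beta[0] * x1 + beta[1] * x2 + intercepts[g]
             + rng.normal(0, sigma_e, size=n_per))
        rows.append(pd.DataFrame({
            "ehi": y, "x1": x1, "x2": x2, "continent": f"g{g}",
        }))
    return pd.concat(rows, ignore_index=True)


class TestRandomIntercept:
    def test_sigma_b_zero_reduces_to_ols(self, rng):
        table = _grouped_data(rng, sigma_b=0.0, sigma_e=0.1)
        fit = fit_random_intercept(table, ["x1", "x2"])
        assert fit.sigma_b == pytest.approx(0.0, abs=0.02)
        x = np.column_stack([
            np.ones(len(table)), table["x1"], table["x2"],
        ])
        beta_ols = np.linalg.lstsq(x, table["ehi"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, atol=1e-3)

    def test_parameter_recovery(self, rng):
        table = _grouped_data(rng, beta=(0.5, -0.2), sigma_b=0.1, sigma_e=0.05)
        fit = fit_random_intercept(table, ["x1", "x2"])
        assert fit.beta["x1"] == pytest.approx(0.5, abs=0.02)
        assert fit.beta["x2"] == pytest.approx(-0.2, abs=0.02)
        assert fit.sigma_e == pytest.approx(0.05, rel=0.1)

    def test_balanced_anova_closed_form(self, rng):
        # intercept-only REML on balanced one-way data equals the ANOVA
        # moment estimators: sigma_e^2 = MSW, sigma_b^2 = (MSB - MSW) / n_per
        n_groups, n_per = 8, 50
        table = _grouped_data(rng, beta=(0.0, 0.0), sigma_b=0.3, sigma_e=0.2,
                              n_groups=n_groups, n_per=n_per)
        fit = fit_random_intercept(table, [], add_intercept=True)
        y = table["ehi"].to_numpy()
        groups = table["continent"].to_numpy()
        names = sorted(set(groups))
        group_means = np.array([y[groups == g].mean() for g in names])
        msw = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
                  for g in names) / (len(y) - n_groups)
        msb = n_per * ((group_means - group_means.mean()) ** 2).sum() / (n_groups - 1)
        sigma_e2 = msw
        sigma_b2 = (msb - msw) / n_per
        assert fit.sigma_e**2 == pytest.approx(sigma_e2, abs=1e-6)
        assert fit.sigma_b**2 == pytest.approx(sigma_b2, abs=1e-6)

    def test_matches_statsmodels_reml(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        table = _grouped_data(rng, n_groups=5, n_per=60)
        fit = fit_random_intercept(table, ["x1", "x2"])
        sm_fit = statsmodels.MixedLM.from_formula(
            "ehi ~ x1 + x2", groups="continent", data=table
        ).fit(reml=True)
        np.testing.assert_allclose(
            fit.beta.to_numpy(), sm_fit.fe_params.to_numpy(), atol=1e-5
        )
        assert fit.sigma_e**2 == pytest.approx(sm_fit.scale, rel=1e-4)
        assert fit.sigma_b**2 == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-8
        )

    def test_fitted_plus_residual_reproduces_response(self, rng):
        table = _grouped_data(rng, n_groups=4, n_per=40)
        fit = fit_random_intercept(table, ["x1", "x2"])
        np.testing.assert_allclose(
            fit.fitted + fit.residuals, table["ehi"].to_numpy(), atol=1e-10
        )

    def test_intercept_only_grand_mean(self, rng):
        table = _grouped_data(rng, beta=(0.0, 0.0), sigma_b=1e-8, sigma_e=0.1,
                              n_groups=4, n_per=100)
        fit = fit_random_intercept(table, [])
        assert fit.beta["intercept"] == pytest.approx(
            table["ehi"].mean(), abs=1e-3
        )
        # shrinkage: intercepts collapse toward 0 as sigma_b / sigma_e -> 0
        assert max(abs(v) for v in fit.random_intercepts.values()) < 0.05

    def test_single_group_warns_and_matches_ols(self, rng):
        table = _grouped_data(rng, n_groups=1, n_per=100)
        with pytest.warns(UserWarning, match="single group"):
            fit = fit_random_intercept(table, ["x1", "x2"])
        assert fit.sigma_b == 0.0

    def test_rank_deficient_design_named(self, rng):
        table = _grouped_data(rng, n_groups=3, n_per=30)
        table["x3"] = 2.0 * table["x1"]
        with pytest.raises(ValueError, match="collinear"):
            fit_random_intercept(table, ["x1", "x2", "x3"])
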