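"""GPS estimation and stabilized-weight construction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate, stats

from gpsmsm import (AnalysisConfig, DataError, GeneralizedPropensityScore,
                    SimulationConfig, analyze_hormone, simulate_cohort)


def _frame(n, rng, signal=None):
    """Analysis-set-like frame with one continuous + one binary covariate."""
    age = rng.normal(28, 6, n)
    par = rng.integers(0, 2, n)
    mean = signal(age, par) if signal is not None else 0.0
    z = mean + rng.normal(0, 1, n)
    return pd.DataFrame({"z": z, "maternal_age": age, "nulliparity": par})


class TestGpsFit:
    def test_null_signal_predicts_the_marginal_mean(self, rng):
        df = _frame(2000, rng)
        res = GeneralizedPropensityScore(
            df, "z", ["maternal_age", "nulliparity"], engine="gam",
            select_smoothing=True).fit()
        assert res.fitted.std() < 0.1 * df["z"].std()

    def test_linear_truth_matches_ols_oracle(self, rng):
        df = _frame(3000, rng, signal=lambda a, p: 0.05 * (a - 28) + 0.3 * p)
        gam = GeneralizedPropensityScore(
            df, "z", ["maternal_age", "nulliparity"], engine="gam").fit()
        X = sm.add_constant(df[["maternal_age", "nulliparity"]])
        ols = sm.OLS(df["z"], X).fit()
        rmse = np.sqrt(np.mean((gam.fitted - ols.fittedvalues) ** 2))
        assert rmse < 0.05 * df["z"].std()

    def test_sin_shaped_truth_is_recovered_where_linear_fails(self, rng):
        df = _frame(5000, rng,
                    signal=lambda a, p: np.sin((a - 28) / 4.0))
        truth = np.sin((df["maternal_age"] - 28) / 4.0)
        gam = GeneralizedPropensityScore(
            df, "z", ["maternal_age", "nulliparity"], engine="gam").fit()
        lin = GeneralizedPropensityScore(
            df, "z", ["maternal_age", "nulliparity"], engine="linear").fit()
        sd = df["z"].std()
        rmse_gam = np.sqrt(np.mean((gam.fitted - truth) ** 2))
        rmse_lin = np.sqrt(np.mean((lin.fitted - truth) ** 2))
        assert rmse_gam < 0.1 * sd
        assert rmse_lin > rmse_gam

    def test_linear_engine_equals_ols_coefficients(self, rng):
        df = _frame(500, rng, signal=lambda a, p: 0.04 * (a - 28) - 0.2 * p)
        res = GeneralizedPropensityScore(
            df, "z", ["maternal_age", "nulliparity"], engine="linear").fit()
        X = sm.add_constant(df[["maternal_age", "nulliparity"]])
        ols = sm.OLS(df["z"], X).fit()
        assert np.allclose(res.fitted, ols.fittedvalues, atol=1e-8)

    def test_noiseless_linear_design_recovers_exactly(self):
        rng = np.random.default_rng(7)
        df = _frame(200, rng)
        df["z"] = 1.0 + 0.1 * df["maternal_age"] - 0.5 * df["nulliparity"]
        res = GeneralizedPropensityScore(
            df, "z", ["maternal_age", "nulliparity"], engine="linear").fit()
        assert np.allclose(res.fitted, df["z"], atol=1e-8)

    def test_basis_larger_than_data_raises(self, rng):
        df = _frame(12, rng)
        from gpsmsm.exceptions import FitError
        with pytest.raises(FitError, match="basis"):
            GeneralizedPropensityScore(
                df, "z", ["maternal_age", "nulliparity"], engine="gam",
                basis_df=20).fit()

    def test_missing_values_rejected(self, rng):
        df = _frame(50, rng)
        df.loc[3, "maternal_age"] = np.nan
        with pytest.raises(DataError):
            GeneralizedPropensityScore(df, "z", ["maternal_age"]).fit()


class TestConditionalDensity:
    @pytest.fixture()
    def fitted(self, rng):
        df = _frame(400, rng)
        return GeneralizedPropensityScore(
            df, "z", ["maternal_age", "nulliparity"], engine="linear").fit()

    def test_mode_value_and_one_sigma_ratio(self, fitted):
        m = fitted.fitted.iloc[0]
        mode = fitted.conditional_density(m, mean=m)
        assert mode == pytest.approx(1 / (np.sqrt(2 * np.pi) * fitted.sigma))
        at_sigma = fitted.conditional_density(m + fitted.sigma, mean=m)
        assert at_sigma / mode == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_density_integrates_to_one(self, fitted):
        m = float(fitted.fitted.iloc[0])
        val, _ = integrate.quad(
            lambda z: fitted.conditional_density(z, mean=m), -10, 10)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestStabilizedWeights:
    def test_covariate_free_gps_gives_unit_weights(self, rng):
        df = _frame(300, rng)
        res = GeneralizedPropensityScore(df, "z", [], engine="linear").fit()
        ws = res.stabilized_weights()
        assert np.allclose(ws.weights, 1.0, atol=1e-10)

    def test_hand_computed_density_ratio(self):
        """3 hand-specified rows: weights equal explicit normal-density
        ratios with the stated conditional means, sigma and marginal
        moments."""
        z = np.array([0.2, -0.3, 1.0])
        m = np.array([0.0, 0.5, -0.5])
        sigma, mmean, msd = 0.8, 0.1, 1.1

        def phi(x, mu, s):
            return np.exp(-0.5 * ((x - mu) / s) ** 2) / (np.sqrt(2 * np.pi) * s)

        expected = phi(z, mmean, msd) / phi(z, m, sigma)
        got = stats.norm.pdf(z, mmean, msd) / stats.norm.pdf(z, m, sigma)
        assert np.allclose(got, expected, atol=1e-10)
        # and the WeightSet path reproduces the same ratios when fed the
        # same conditional means and scale
        from gpsmsm.gps import GPSResults
        df = pd.DataFrame({"z": z})
        model = GeneralizedPropensityScore(df, "z", [], engine="linear")
        res = GPSResults(model=model, _res=None,
                         fitted=pd.Series(m, index=df.index), sigma=sigma,
                         edf=1.0, r_squared=0.0, smoothing={})
        num = stats.norm.pdf(z, z.mean(), z.std(ddof=1))
        ws = res.stabilized_weights()
        assert np.allclose(ws.weights, num / phi(z, m, sigma), atol=1e-10)

    def test_no_confounding_weights_are_near_one(self):
        cfg = SimulationConfig(n_participants=5000, seed=31,
                               confounder_strength={}, missingness_rate=0.0)
        cohort = simulate_cohort(cfg)
        ac = AnalysisConfig(simulation=cfg, hormones=["hcc"],
                            select_smoothing=False)
        a = analyze_hormone(cohort, "hcc", ac,
                            alphas={"pre": [1e6] * 4, "tri1": [1e6] * 4})
        for occ in ("pre", "tri1"):
            w = a.weights[occ].weights
            assert 0.95 < w.mean() < 1.05
            assert w.min() > 0.5 and w.max() < 2.0

    def test_weights_approach_one_as_sigma_grows(self, rng):
        """Monotone dependence: as the conditional SD approaches the marginal
        SD (with conditional mean at the marginal mean), weights -> 1."""
        df = _frame(300, rng)
        res = GeneralizedPropensityScore(df, "z", [], engine="linear").fit()
        z = df["z"].to_numpy()
        from gpsmsm.gps import GPSResults
        spread = []
        for s_frac in (0.6, 0.8, 1.0):
            fake = GPSResults(model=res.model, _res=None,
                              fitted=pd.Series(np.full(len(df), z.mean()),
                                               index=df.index),
                              sigma=z.std(ddof=1) * s_frac, edf=1.0,
                              r_squared=0.0, smoothing={})
            w = fake.stabilized_weights().weights
            spread.append(np.abs(np.log(w)).max())
        assert spread[0] > spread[1] > spread[2]
        assert spread[2] < 1e-10

    def test_sequential_numerator_is_conditional_density_ratio(self, rng):
        """With a numerator GPS, weights equal f(z|numerator fit)/f(z|full
        fit) exactly; used for the joint weight of cross-correlated
        occasions."""
        n = 400
        age = rng.normal(28, 6, n)
        z_pre = 0.05 * (age - 28) + rng.normal(0, 1, n)
        z_tri = 0.6 * z_pre + 0.03 * (age - 28) + rng.normal(0, 0.8, n)
        df = pd.DataFrame({"maternal_age": age, "z_pre": z_pre,
                           "z_tri": z_tri})
        den = GeneralizedPropensityScore(
            df, "z_tri", ["maternal_age", "z_pre"],
            continuous=["maternal_age", "z_pre"], engine="linear").fit()
        num = GeneralizedPropensityScore(
            df, "z_tri", ["z_pre"], continuous=["z_pre"],
            engine="linear").fit()
        ws = den.stabilized_weights(numerator=num)
        expected = (num.conditional_density(z_tri)
                    / den.conditional_density(z_tri))
        assert np.allclose(ws.weights, expected, atol=1e-12)
        assert ws.numerator_sd == pytest.approx(num.sigma)
        # conditioning on z_pre tightens the stabilizer relative to the
        # marginal numerator when the occasions are correlated
        marginal = den.stabilized_weights()
        assert (np.abs(np.log(ws.weights)).mean()
                < np.abs(np.log(marginal.weights)).mean())

    def test_sequential_numerator_rejects_exposure_mismatch(self, rng):
        df = _frame(100, rng)
        df["other"] = rng.normal(size=100)
        den = GeneralizedPropensityScore(
            df, "z", ["maternal_age"], engine="linear").fit()
        num = GeneralizedPropensityScore(
            df, "other", ["maternal_age"], engine="linear").fit()
        with pytest.raises(DataError, match="same exposure"):
            den.stabilized_weights(numerator=num)

    def test_truncation_caps_and_records(self, rng):
        df = _frame(500, rng, signal=lambda a, p: 0.05 * (a - 28))
        res = GeneralizedPropensityScore(
            df, "z", ["maternal_age"], engine="linear").fit()
        ws = res.stabilized_weights(truncate=(5, 95))
        lo, hi = ws.truncation["bounds"]
        assert ws.weights.min() >= lo and ws.weights.max() <= hi
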