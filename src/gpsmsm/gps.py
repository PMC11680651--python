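"""Generalized propensity scores for a continuous exposure and the stabilized
inverse-probability weights they induce.

The GPS is the conditional density of the standardized log exposure given the
measured covariates.  It is modelled as a normal density around an additive
conditional mean — penalized regression splines for continuous covariates and
indicator coding for categorical ones (engine ``"gam"``), or a plain linear
model (engine ``"linear"``, the sensitivity analysis) — with a homoscedastic
residual SD.  The stabilized weight of participant i is

    sw_i = f_hat(Z_i) / f_hat(Z_i | X_i),

where the numerator is a normal density with the analysis set's estimated
marginal mean and SD of Z.  Weights near 1 with mean ~1 indicate a stable
weighting scheme; the ratio renders the exposure independent of the measured
covariates in the weighted population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from . import schema
from .exceptions import DataError, FitError

__all__ = ["GeneralizedPropensityScore", "GPSResults", "WeightSet"]


def _design_linear_part(data: pd.DataFrame, covariates: list[str],
                        continuous: list[str]) -> pd.DataFrame:
    """Intercept + binary covariates + dummy-coded categoricals (reference
    level dropped).  Continuous covariates are handled by the caller (spline
    basis or appended linearly)."""
    cols = {"const": np.ones(len(data))}
    for name in covariates:
        if name in continuous:
            continue
        kind = schema.covariate_kind(name)
        if kind == "binary":
            cols[name] = data[name].to_numpy(float)
        else:  # categorical
            dummies = pd.get_dummies(data[name], prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(float)
    X = pd.DataFrame(cols, index=data.index)
    for c in X.columns[1:]:
        if X[c].nunique() <= 1:
            raise FitError(f"covariate column {c!r} is constant (aliased) "
                           "in the analysis set")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FitError("linear design is rank deficient; check categorical "
                       "coding for aliased columns")
    return X


class GeneralizedPropensityScore:
    """Model of the standardized log exposure given covariates.

    Parameters
    ----------
    data : DataFrame
        Complete-case analysis set containing the standardized exposure column
        and every covariate.
    exposure : str
        Name of the standardized log-exposure column (Z).
    covariates : list of str
        Covariate names; continuous ones receive penalized spline terms under
        the GAM engine.
    engine : {"gam", "linear"}
    basis_df : int
        B-spline basis dimension per continuous covariate (GAM engine).
    alpha : sequence of float, optional
        Fixed penalty weights (one per smooth term); skips selection.
    select_smoothing : bool
        Select penalty weights by GCV when no fixed alpha is given.
    """

    def __init__(self, data: pd.DataFrame, exposure: str,
                 covariates: list[str], continuous: list[str] | None = None,
                 engine: str = "gam", basis_df: int = 10,
                 spline_degree: int = 3, alpha=None,
                 select_smoothing: bool = True):
        if engine not in ("gam", "linear"):
            raise FitError("engine must be 'gam' or 'linear'")
        if data[covariates + [exposure]].isna().any().any():
            raise DataError("GPS input must be complete cases "
                            "(missing values found)")
        self.data = data
        self.exposure = exposure
        self.covariates = list(covariates)
        if continuous is None:
            continuous = [c for c in covariates
                          if schema.covariate_kind(c) == "continuous"]
        self.continuous = list(continuous)
        self.engine = engine
        self.basis_df = basis_df
        self.spline_degree = spline_degree
        self.alpha = alpha
        self.select_smoothing = select_smoothing

    def fit(self) -> "GPSResults":
        y = self.data[self.exposure].to_numpy(float)
        n = len(y)
        X_lin = _design_linear_part(self.data, self.covariates, self.continuous)

        if self.engine == "linear" or not self.continuous:
            X = X_lin.copy()
            for c in self.continuous:
                X[c] = self.data[c].to_numpy(float)
            if n <= X.shape[1]:
                raise FitError("fewer rows than regression columns")
            res = sm.OLS(y, X).fit()
            fitted = np.asarray(res.fittedvalues)
            edf = float(X.shape[1])
            record = {"engine": "linear", "n_params": X.shape[1]}
            model_res = res
        else:
            Xc = self.data[self.continuous].to_numpy(float)
            k = len(self.continuous)
            total_basis = self.basis_df * k + X_lin.shape[1]
            if n <= total_basis:
                raise FitError(
                    f"n={n} rows cannot support a basis of dimension "
                    f"{total_basis}; reduce basis_df")
            smoother = BSplines(Xc, df=[self.basis_df] * k,
                                degree=[self.spline_degree] * k,
                                variable_names=self.continuous)
            alpha = self.alpha
            gam = GLMGam(y, exog=X_lin.to_numpy(), smoother=smoother,
                         alpha=(alpha if alpha is not None else [1.0] * k),
                         family=sm.families.Gaussian())
            if alpha is None and self.select_smoothing:
                gam.fit()  # select_penweight needs an initial fitted scale
                alpha = gam.select_penweight(criterion="gcv",
                                             method="minimize")[0]
                gam = GLMGam(y, exog=X_lin.to_numpy(), smoother=smoother,
                             alpha=alpha, family=sm.families.Gaussian())
            elif alpha is None:
                alpha = [1.0] * k
            res = gam.fit()
            fitted = np.asarray(res.fittedvalues)
            edf = float(np.sum(res.edf))
            record = {"engine": "gam", "criterion": "gcv",
                      "alpha": [float(a) for a in np.atleast_1d(alpha)],
                      "basis_df": self.basis_df, "edf_total": edf}
            model_res = res

        resid = y - fitted
        dof = max(n - edf, 1.0)
        sigma = float(np.sqrt((resid ** 2).sum() / dof))
        if not sigma > 0:
            raise FitError("residual SD is zero; exposure is perfectly "
                           "predicted by covariates")
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = float(1.0 - (resid ** 2).sum() / ss_tot) if ss_tot > 0 else np.nan
        return GPSResults(model=self, _res=model_res,
                          fitted=pd.Series(fitted, index=self.data.index),
                          sigma=sigma, edf=edf, r_squared=r2,
                          smoothing=record)


@dataclass
class GPSResults:
    """Fitted GPS: conditional mean, residual SD, diagnostics, weights."""

    model: GeneralizedPropensityScore
    _res: object
    fitted: pd.Series
    sigma: float
    edf: float
    r_squared: float
    smoothing: dict

    def conditional_density(self, z, mean=None) -> np.ndarray:
        """Normal GPS density f(z | x) = phi((z - m(x)) / sigma) / sigma."""
        if not self.sigma > 0:
            raise FitError("sigma must be positive")
        if mean is None:
            mean = self.fitted.to_numpy()
        return stats.norm.pdf(np.asarray(z, float), loc=np.asarray(mean, float),
                              scale=self.sigma)

    def residual_normality(self) -> dict:
        """Shapiro/D'Agostino-style residual diagnostics for the normal-GPS
        assumption (skewness, excess kurtosis, KS distance)."""
        z = self.model.data[self.model.exposure].to_numpy(float)
        r = (z - self.fitted.to_numpy()) / self.sigma
        ks = stats.kstest(r, "norm").statistic
        return {"skewness": float(stats.skew(r)),
                "excess_kurtosis": float(stats.kurtosis(r)),
                "ks_statistic": float(ks)}

    def stabilized_weights(self, truncate: tuple[float, float] | None = None,
                           numerator: "GPSResults | None" = None,
                           ) -> "WeightSet":
        """Stabilized inverse-probability weights sw = f(Z) / f(Z | X).

        By default the numerator is a normal density with the analysis set's
        marginal mean and SD of Z.  For a joint MSM of two cross-correlated
        occasions, pass another fitted GPS as ``numerator`` to obtain the
        sequential stabilizer f(Z | numerator covariates) — e.g. the
        first-trimester weight conditions its numerator on the pre-pregnancy
        exposure so that the product of the two occasion weights is a valid
        joint stabilized weight.

        ``truncate`` optionally caps weights at symmetric percentiles, e.g.
        ``(1, 99)``; off by default (no truncation is applied unless asked).
        """
        data = self.model.data
        z = data[self.model.exposure].to_numpy(float)
        if numerator is None:
            num_mean = float(z.mean())
            num_sd = float(z.std(ddof=1))
            num = stats.norm.pdf(z, loc=num_mean, scale=num_sd)
        else:
            if numerator.model.exposure != self.model.exposure:
                raise DataError("numerator GPS must model the same exposure")
            num_mean = float(numerator.fitted.mean())
            num_sd = numerator.sigma
            num = numerator.conditional_density(z)
        den = self.conditional_density(z)
        sw = num / den
        bad = ~np.isfinite(sw) | (sw <= 0)
        if bad.any():
            raise DataError(
                f"non-finite stabilized weights at rows "
                f"{data.index[bad][:5].tolist()}")
        trunc_info = None
        if truncate is not None:
            lo, hi = np.percentile(sw, truncate)
            sw = np.clip(sw, lo, hi)
            trunc_info = {"percentiles": list(truncate),
                          "bounds": [float(lo), float(hi)]}
        weights = pd.Series(sw, index=data.index, name="sipw")
        ws = WeightSet(weights=weights, numerator_mean=num_mean,
                       numerator_sd=num_sd, exposure=self.model.exposure,
                       truncation=trunc_info)
        if not 0.5 <= ws.diagnostics["mean"] <= 2.0:
            warnings.warn(
                f"mean stabilized weight {ws.diagnostics['mean']:.3f} outside "
                "[0.5, 2]; weighting may be unstable", stacklevel=2)
        return ws


@dataclass
class WeightSet:
    """Per-participant stabilized weights with summary diagnostics."""

    weights: pd.Series
    numerator_mean: float
    numerator_sd: float
    exposure: str
    truncation: dict | None = None
    diagnostics: dict = field(init=False)

    def __post_init__(self):
        w = self.weights.to_numpy()
        self.diagnostics = {
            "mean": float(w.mean()), "min": float(w.min()),
            "max": float(w.max()),
            "p1": float(np.percentile(w, 1)),
            "p99": float(np.percentile(w, 99)),
            "n": int(len(w)),
        }

    def to_dict(self) -> dict:
        return {"exposure": self.exposure,
                "numerator_mean": self.numerator_mean,
                "numerator_sd": self.numerator_sd,
                "truncation": self.truncation,
                "diagnostics": self.diagnostics}
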