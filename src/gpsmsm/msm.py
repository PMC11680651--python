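"""Marginal structural Poisson models for a binary outcome.

A weighted Poisson regression of the 0/1 outcome on the standardized log
exposures returns risk ratios directly (log link), avoiding the
non-collapsibility of odds ratios.  Uncertainty comes from the weighted
sandwich (robust) covariance

    V = B^{-1} M B^{-1},   B = sum_i w_i mu_i x_i x_i',
                           M = sum_i w_i^2 (y_i - mu_i)^2 x_i x_i',

which is consistent under weighting and under the working-model
misspecification inherent in using Poisson variance for Bernoulli outcomes.
Weights are normalized to mean 1 before fitting (configurable) so weighted
pseudo-log-likelihoods — and hence likelihood-ratio statistics — do not
depend on the weights' scale.  LRTs on weighted pseudo-likelihoods are
approximate; the simulation harness quantifies their null calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .exceptions import DataError, FitError
from .gps import WeightSet

__all__ = ["MarginalStructuralPoisson", "MSMResults",
           "interaction_test", "InteractionResult",
           "curvilinearity_test", "CurvilinearityResult",
           "combine_weights"]

_Z95 = stats.norm.ppf(0.975)  # 1.959964...


def _as_weight_array(weights, index) -> np.ndarray:
    if weights is None:
        return np.ones(len(index))
    if isinstance(weights, WeightSet):
        weights = weights.weights
    w = np.asarray(pd.Series(weights).reindex(index)
                   if isinstance(weights, pd.Series) else weights, float)
    if len(w) != len(index):
        raise DataError("weights are not aligned with the analysis rows")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise DataError("weights must be finite and positive")
    return w


def combine_weights(*weight_sets) -> pd.Series:
    """Elementwise product of stabilized weight sets.

    For a joint MSM of cross-correlated occasions, combine the marginal
    pre-pregnancy weight with the *sequential* first-trimester weight (whose
    stabilizer conditions on the pre-pregnancy exposure); the product of two
    marginal stabilized weights is not a valid joint weight in that case."""
    out = None
    for ws in weight_sets:
        w = ws.weights if isinstance(ws, WeightSet) else pd.Series(ws)
        out = w if out is None else out * w
    return out


class MarginalStructuralPoisson:
    """Weighted Poisson MSM of a binary outcome on standardized exposures.

    Parameters
    ----------
    data : DataFrame with the outcome and exposure columns.
    outcome : str, 0/1 column.
    exposures : list of str — both occasions enter one model jointly.
    weights : WeightSet, Series, array or None (unweighted).
    interaction : bool — add the product of the first two exposure columns.
    normalize_weights : bool — rescale weights to mean 1 before fitting.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, exposures: list[str],
                 weights=None, interaction: bool = False,
                 normalize_weights: bool = True, label: str = "msm"):
        y = data[outcome].to_numpy(float)
        if not np.isin(y[~np.isnan(y)], [0, 1]).all():
            raise DataError("outcome must be coded 0/1")
        self.data = data
        self.outcome = outcome
        self.exposures = list(exposures)
        self.interaction = interaction
        self.label = label
        w = _as_weight_array(weights, data.index)
        self.raw_weights = w
        self.weights = w / w.mean() if normalize_weights else w

    def _design(self) -> pd.DataFrame:
        X = pd.DataFrame({"const": np.ones(len(self.data))},
                         index=self.data.index)
        for c in self.exposures:
            X[c] = self.data[c].to_numpy(float)
        if self.interaction:
            a, b = self.exposures[:2]
            X[f"{a}*{b}"] = X[a] * X[b]
        return X

    def fit(self, maxiter: int = 100, gtol: float = 1e-8) -> "MSMResults":
        y = self.data[self.outcome].to_numpy(float)
        X = self._design()
        Xv = X.to_numpy()
        w = self.weights
        model = sm.GLM(y, Xv, family=sm.families.Poisson(), freq_weights=w)
        res = model.fit(maxiter=maxiter)
        beta = np.asarray(res.params)

        # Newton refinement of the weighted score to the requested tolerance.
        n_newton = 0
        for n_newton in range(1, 26):
            mu = np.exp(Xv @ beta)
            score = Xv.T @ (w * (y - mu))
            if np.linalg.norm(score) < gtol:
                break
            H = (Xv * (w * mu)[:, None]).T @ Xv
            try:
                beta = beta + np.linalg.solve(H, score)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"singular Hessian during refinement: {exc}")
        mu = np.exp(Xv @ beta)
        gnorm = float(np.linalg.norm(Xv.T @ (w * (y - mu))))
        if gnorm >= max(gtol, 1e-6):
            raise FitError(
                f"weighted Poisson fit did not converge (|score|={gnorm:.2e} "
                f"after IRLS + {n_newton} Newton steps)")
        if mu.max() < 1e-10:
            warnings.warn("all fitted means are ~0 (separation-like "
                          "degeneracy)", stacklevel=2)

        bread = (Xv * (w * mu)[:, None]).T @ Xv
        meat = (Xv * ((w ** 2) * (y - mu) ** 2)[:, None]).T @ Xv
        binv = np.linalg.inv(bread)
        cov = binv @ meat @ binv
        cov = (cov + cov.T) / 2.0
        llf = float(model.loglike(beta))
        return MSMResults(
            label=self.label,
            params=pd.Series(beta, index=X.columns),
            cov_robust=pd.DataFrame(cov, index=X.columns, columns=X.columns),
            llf=llf, nobs=len(y),
            exposures=self.exposures,
            interaction=self.interaction,
            convergence={"newton_steps": n_newton, "score_norm": gnorm},
        )


@dataclass
class MSMResults:
    """Weighted Poisson MSM fit: coefficients, robust covariance, RRs."""

    label: str
    params: pd.Series
    cov_robust: pd.DataFrame
    llf: float
    nobs: int
    exposures: list[str]
    interaction: bool
    convergence: dict

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)),
                         index=self.params.index)

    def risk_ratios(self) -> pd.DataFrame:
        """Per-term RR = exp(beta) with robust Wald 95% CI (log scale)."""
        terms = [t for t in self.params.index if t != "const"]
        beta = self.params[terms]
        se = self.bse[terms]
        return pd.DataFrame({
            "rr": np.exp(beta),
            "ci_low": np.exp(beta - _Z95 * se),
            "ci_high": np.exp(beta + _Z95 * se),
            "se_log": se,
            "p_wald": 2 * stats.norm.sf(np.abs(beta / se)),
        }, index=terms)

    def cumulative_rr(self) -> dict:
        """RR of a simultaneous one-SD increase at both occasions:
        exp(beta_pre + beta_tri1), CI from the summed robust variance
        including the off-diagonal term."""
        a, b = self.exposures[:2]
        for t in (a, b):
            if t not in self.cov_robust.index:
                raise DataError(f"covariance entry for {t!r} missing")
        s = self.params[a] + self.params[b]
        var = (self.cov_robust.loc[a, a] + self.cov_robust.loc[b, b]
               + 2 * self.cov_robust.loc[a, b])
        se = np.sqrt(var)
        return {"rr": float(np.exp(s)),
                "ci_low": float(np.exp(s - _Z95 * se)),
                "ci_high": float(np.exp(s + _Z95 * se)),
                "se_log": float(se)}

    def summary(self) -> str:
        """Plain-text table: term, RR (95%CI), per-term Wald p."""
        rows = [f"Marginal structural Poisson model [{self.label}], "
                f"n={self.nobs}"]
        rr = self.risk_ratios()
        for term, r in rr.iterrows():
            rows.append(f"  {term:<24s} {r.rr:.2f} ({r.ci_low:.2f},"
                        f"{r.ci_high:.2f})   p={r.p_wald:.3f}")
        if len(self.exposures) >= 2 and not self.interaction:
            c = self.cumulative_rr()
            rows.append(f"  {'cumulative (both +1 SD)':<24s} {c['rr']:.2f} "
                        f"({c['ci_low']:.2f},{c['ci_high']:.2f})")
        return "\n".join(rows)

    def to_dict(self) -> dict:
        return {"label": self.label,
                "params": self.params.to_dict(),
                "bse_robust": self.bse.to_dict(),
                "risk_ratios": self.risk_ratios().to_dict(orient="index"),
                "llf": self.llf, "nobs": self.nobs,
                "convergence": self.convergence}


@dataclass
class InteractionResult:
    full: MSMResults
    reduced: MSMResults
    coefficient: float      # b of the Z_pre * Z_tri1 product term
    lrt_statistic: float
    p_value: float


def interaction_test(data: pd.DataFrame, outcome: str, exposures: list[str],
                     weights=None, **kwargs) -> InteractionResult:
    """Effect-modification between occasions: compare the MSM with and
    without the product term by a (pseudo-)likelihood-ratio test, 1 df."""
    reduced = MarginalStructuralPoisson(
        data, outcome, exposures, weights, interaction=False,
        label="reduced", **kwargs).fit()
    full = MarginalStructuralPoisson(
        data, outcome, exposures, weights, interaction=True,
        label="interaction", **kwargs).fit()
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(stat, df=1))
    b = float(full.params.iloc[-1])
    return InteractionResult(full=full, reduced=reduced, coefficient=b,
                             lrt_statistic=float(stat), p_value=p)


@dataclass
class CurvilinearityResult:
    linear: MSMResults
    spline_llf: float
    spline_edf: float
    lrt_statistic: float
    df: float              # edf difference; approximate
    p_value: float
    fitted_linpred: pd.Series


def curvilinearity_test(data: pd.DataFrame, outcome: str,
                        exposures: list[str], weights=None,
                        basis_df: int = 10, spline_degree: int = 3,
                        alpha=None, select_smoothing: bool = True,
                        ) -> CurvilinearityResult:
    """Non-linearity of the exposure–risk relation: replace each linear
    exposure term with a penalized spline in the weighted Poisson MSM and
    compare to the linear MSM by an approximate LRT with the effective-
    degrees-of-freedom difference as df."""
    linear = MarginalStructuralPoisson(
        data, outcome, exposures, weights, label="linear").fit()
    y = data[outcome].to_numpy(float)
    w = _as_weight_array(weights, data.index)
    w = w / w.mean()
    Xs = data[list(exposures)].to_numpy(float)
    k = Xs.shape[1]
    if len(y) <= basis_df * k + 1:
        raise FitError("spline basis larger than the data support")
    smoother = BSplines(Xs, df=[basis_df] * k, degree=[spline_degree] * k,
                        variable_names=list(exposures))
    exog = np.ones((len(y), 1))
    gam = GLMGam(y, exog=exog, smoother=smoother,
                 alpha=(alpha if alpha is not None else [1.0] * k),
                 family=sm.families.Poisson(), freq_weights=w)
    if alpha is None and select_smoothing:
        gam.fit()  # select_penweight needs an initial fitted scale
        alpha = gam.select_penweight(criterion="gcv", method="minimize")[0]
        gam = GLMGam(y, exog=exog, smoother=smoother, alpha=alpha,
                     family=sm.families.Poisson(), freq_weights=w)
    res = gam.fit()
    edf = float(np.sum(res.edf))
    stat = max(0.0, 2.0 * (res.llf - linear.llf))
    df = max(edf - len(linear.params), 0.0)
    p = float(stats.chi2.sf(stat, df=df)) if df > 1e-8 else 1.0
    linpred = pd.Series(np.log(np.asarray(res.fittedvalues)),
                        index=data.index)
    return CurvilinearityResult(linear=linear, spline_llf=float(res.llf),
                                spline_edf=edf, lrt_statistic=float(stat),
                                df=float(df), p_value=p,
                                fitted_linpred=linpred)
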