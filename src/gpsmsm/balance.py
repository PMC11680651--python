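"""Covariate-balance diagnostics for a continuous, weighted exposure.

For a continuous treatment the binary-treatment standardized-mean-difference
idiom does not apply; balance is instead measured by the (weighted) Pearson
correlation between the standardized log exposure and each covariate.  A
weighted absolute correlation below 0.1 for every covariate is taken as
satisfactory balance, and the average absolute correlation (AAC) summarises
overall performance with and without the stabilized weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema
from .exceptions import DataError
from .gps import WeightSet

__all__ = ["weighted_correlation", "balance_table", "BalanceReport",
           "plot_balance"]


def weighted_correlation(x, y, w=None) -> float:
    """Weighted Pearson correlation with weighted means and variances:

        r_w = sum w (x - xbar_w)(y - ybar_w)
              / sqrt(sum w (x - xbar_w)^2 * sum w (y - ybar_w)^2).

    Reduces exactly to the unweighted Pearson correlation under constant
    weights and is invariant to rescaling all weights by a positive constant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, float)
    if not (len(x) == len(y) == len(w)):
        raise DataError("x, y and w must have equal lengths")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise DataError("weights must be positive and finite")
    xc = x - np.average(x, weights=w)
    yc = y - np.average(y, weights=w)
    vx = np.sum(w * xc * xc)
    vy = np.sum(w * yc * yc)
    if vx <= 0:
        raise DataError("zero weighted variance in x")
    if vy <= 0:
        raise DataError("zero weighted variance in y")
    return float(np.sum(w * xc * yc) / np.sqrt(vx * vy))


def _covariate_abs_correlation(data: pd.DataFrame, zcol: str, name: str,
                               w: np.ndarray | None) -> float:
    """|correlation| of a covariate with the exposure; categorical covariates
    are expanded to indicator contrasts and the maximum over contrasts is
    reported."""
    z = data[zcol].to_numpy(float)
    kind = schema.covariate_kind(name)
    if kind in ("continuous", "binary"):
        return abs(weighted_correlation(data[name].to_numpy(float), z, w))
    dummies = pd.get_dummies(data[name], prefix=name, drop_first=True)
    vals = [abs(weighted_correlation(dummies[c].to_numpy(float), z, w))
            for c in dummies.columns]
    return max(vals)


@dataclass
class BalanceReport:
    """Per-covariate unweighted/weighted absolute correlations and AACs."""

    table: pd.DataFrame         # index: covariate; columns: unweighted, weighted
    aac_unweighted: float
    aac_weighted: float
    threshold: float
    passed: bool                # all weighted |corr| < threshold
    exposure: str
    excluded: list[str]         # constant covariates, excluded from AAC

    def to_dict(self) -> dict:
        return {"exposure": self.exposure,
                "threshold": self.threshold,
                "passed": bool(self.passed),
                "aac_unweighted": self.aac_unweighted,
                "aac_weighted": self.aac_weighted,
                "excluded": self.excluded,
                "covariates": self.table.to_dict(orient="index")}


def balance_table(data: pd.DataFrame, zcol: str, covariates: list[str],
                  weights=None, threshold: float = 0.1) -> BalanceReport:
    """Compute unweighted and SIPW-weighted absolute correlations between the
    standardized log exposure and each covariate, plus their averages."""
    if isinstance(weights, WeightSet):
        w = weights.weights.reindex(data.index).to_numpy(float)
    elif weights is None:
        w = np.ones(len(data))
    else:
        w = np.asarray(pd.Series(weights).reindex(data.index)
                       if isinstance(weights, pd.Series) else weights, float)
    if len(w) != len(data) or np.any(~np.isfinite(w)):
        raise DataError("weights are not aligned with the analysis rows")

    rows, excluded = {}, []
    for name in covariates:
        try:
            un = _covariate_abs_correlation(data, zcol, name, None)
            we = _covariate_abs_correlation(data, zcol, name, w)
        except DataError:
            excluded.append(name)
            warnings.warn(f"covariate {name!r} is constant in the analysis "
                          "set; excluded from the balance table", stacklevel=2)
            continue
        rows[name] = {"unweighted": un, "weighted": we}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty:
        raise DataError("no usable covariates for the balance table")
    return BalanceReport(
        table=table,
        aac_unweighted=float(table["unweighted"].mean()),
        aac_weighted=float(table["weighted"].mean()),
        threshold=threshold,
        passed=bool((table["weighted"] < threshold).all()),
        exposure=zcol,
        excluded=excluded,
    )


def plot_balance(report: BalanceReport, path) -> None:
    """Write a love-plot-style figure (paired unweighted/weighted markers per
    covariate, vertical reference line at the threshold) and the underlying
    table as delimited text next to it."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = report.table.sort_values("unweighted")
    ypos = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(7, max(3, 0.4 * len(tab) + 1)))
    ax.scatter(tab["unweighted"], ypos, marker="o", facecolors="none",
               edgecolors="tab:red", label="unweighted")
    ax.scatter(tab["weighted"], ypos, marker="o", color="tab:blue",
               label="SIPW weighted")
    ax.axvline(report.threshold, linestyle="--", color="grey",
               label=f"threshold {report.threshold}")
    ax.set_yticks(ypos)
    ax.set_yticklabels(tab.index)
    ax.set_xlabel("absolute correlation with exposure")
    ax.set_title(f"Covariate balance: {report.exposure}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    csv_path = str(path).rsplit(".", 1)[0] + ".csv"
    report.table.to_csv(csv_path, index_label="covariate")
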