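"""Exposure preparation: percentile trimming, log transform, standardization,
complete-case restriction.

The pipeline order is fixed: trim on the raw pg/mg scale, then take natural
logs, then standardize to mean 0 / SD 1 within the trimmed table.  Every
row-dropping step returns its removal count so that the analytic-n flow is
fully accounted for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .exceptions import DataError

__all__ = ["ExposureSpec", "trim_extremes", "log_standardize",
           "complete_cases", "prepare_analysis_set", "AnalysisSet"]


@dataclass(frozen=True)
class ExposureSpec:
    """Identifies one exposure: hormone (hcc/hcnc) x occasion (pre/tri1)."""

    hormone: str
    occasion: str

    def __post_init__(self):
        if self.hormone not in schema.HORMONES:
            raise DataError(f"unknown hormone {self.hormone!r}")
        if self.occasion not in schema.OCCASIONS:
            raise DataError(f"unknown occasion {self.occasion!r}")

    @property
    def column(self) -> str:
        return schema.EXPOSURE_COLUMNS[self.hormone][self.occasion]

    @property
    def zcolumn(self) -> str:
        """Name of the standardized-log column this spec produces."""
        return f"z_log_{self.column}"


def trim_extremes(cohort: pd.DataFrame, columns: str | list[str],
                  lower_pct: float = 1.0, upper_pct: float = 99.0,
                  ) -> tuple[pd.DataFrame, int]:
    """Drop rows whose raw exposure lies strictly outside the [lower, upper]
    percentile band.

    Percentiles are computed per column on its non-missing values with the
    linear-interpolation ("type 7") definition.  A row is removed if ANY of
    the listed columns is non-missing and extreme; rows missing an exposure
    are retained for downstream complete-case handling.  Returns the trimmed
    table and the number of rows removed.
    """
    if isinstance(columns, str):
        columns = [columns]
    if not lower_pct < upper_pct:
        raise DataError("lower_pct must be < upper_pct")
    drop = np.zeros(len(cohort), dtype=bool)
    for col in columns:
        vals = cohort[col].to_numpy(float)
        ok = ~np.isnan(vals)
        if not ok.any():
            raise DataError(f"exposure column {col!r} has no non-missing values")
        lo, hi = np.percentile(vals[ok], [lower_pct, upper_pct])
        drop |= ok & ((vals < lo) | (vals > hi))
    trimmed = cohort.loc[~drop].copy()
    return trimmed, int(drop.sum())


def log_standardize(cohort: pd.DataFrame, spec: ExposureSpec | str,
                    ) -> tuple[pd.DataFrame, dict]:
    """Add Z = (ln x - mean) / SD for one exposure column.

    Mean and SD (denominator n-1) are computed on the non-missing logged
    values of the current table, so standardization reflects the analysis set
    after trimming.  Returns the augmented table and the standardization
    statistics {mean, sd, n}.
    """
    col = spec.column if isinstance(spec, ExposureSpec) else spec
    zcol = spec.zcolumn if isinstance(spec, ExposureSpec) else f"z_log_{col}"
    vals = cohort[col].to_numpy(float)
    nonmissing = ~np.isnan(vals)
    if (vals[nonmissing] <= 0).any():
        bad = cohort.index[nonmissing & (vals <= 0)][:5].tolist()
        raise DataError(f"non-positive exposure in {col!r} at rows {bad}")
    logx = np.full_like(vals, np.nan)
    logx[nonmissing] = np.log(vals[nonmissing])
    mean = np.nanmean(logx)
    sd = np.nanstd(logx, ddof=1)
    if not sd > 0:
        raise DataError(f"zero variance in log {col!r}; cannot standardize")
    out = cohort.copy()
    out[zcol] = (logx - mean) / sd
    return out, {"column": col, "mean": float(mean), "sd": float(sd),
                 "n": int(nonmissing.sum())}


def complete_cases(cohort: pd.DataFrame, required_columns: list[str],
                   ) -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing value among the required columns."""
    missing_cols = [c for c in required_columns if c not in cohort.columns]
    if missing_cols:
        raise DataError(f"required columns not in table: {missing_cols}")
    keep = cohort[required_columns].notna().all(axis=1)
    out = cohort.loc[keep].copy()
    n_removed = int((~keep).sum())
    if out.empty:
        warnings.warn("complete-case restriction removed every row",
                      stacklevel=2)
    return out, n_removed


@dataclass
class AnalysisSet:
    """A per-hormone analysis table with its preprocessing provenance."""

    hormone: str
    data: pd.DataFrame
    standardization: dict[str, dict]  # occasion -> {mean, sd, n}
    counts: dict[str, int] = field(default_factory=dict)

    def zcolumn(self, occasion: str) -> str:
        return ExposureSpec(self.hormone, occasion).zcolumn


def prepare_analysis_set(cohort: pd.DataFrame, hormone: str,
                         covariates: list[str],
                         lower_pct: float = 1.0, upper_pct: float = 99.0,
                         ) -> AnalysisSet:
    """Run the fixed preprocessing chain for one hormone.

    Trimming is joint across the hormone's two occasions (a row leaves the
    analysis if either segment's value is extreme), then both occasions are
    log-standardized, then the table is restricted to complete cases on the
    exposures, covariates and outcome.
    """
    specs = [ExposureSpec(hormone, occ) for occ in schema.OCCASIONS]
    n0 = len(cohort)
    trimmed, n_trim = trim_extremes(
        cohort, [s.column for s in specs], lower_pct, upper_pct)
    std: dict[str, dict] = {}
    df = trimmed
    for s in specs:
        df, stats = log_standardize(df, s)
        std[s.occasion] = stats
    required = ([s.column for s in specs] + list(covariates)
                + [schema.OUTCOME_COLUMN])
    df, n_cc = complete_cases(df, required)
    counts = {"n_initial": n0, "n_trimmed": n_trim,
              "n_incomplete": n_cc, "n_final": len(df)}
    assert counts["n_initial"] == (counts["n_final"] + counts["n_trimmed"]
                                   + counts["n_incomplete"])
    return AnalysisSet(hormone=hormone, data=df, standardization=std,
                       counts=counts)
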