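"""Cohort table schema: column names, covariate metadata, validation, I/O.

One row per participant. Exposures are hair cortisol (HCC) and cortisone
(HCNC) concentrations in pg/mg for two hair segments: the distal segment
covering the ~3 months before conception ("pre") and the proximal segment
covering the first trimester ("tri1"). The outcome is spontaneous preterm
birth (<37 completed gestational weeks), coded 0/1.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import DataError

ID_COLUMN = "participant_id"
OUTCOME_COLUMN = "preterm"

# Continuous covariates: name -> (mean, sd, lower bound, upper bound) used as
# the synthetic generator's marginal targets.
CONTINUOUS_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "maternal_age": (28.0, 6.2, 18.0, 45.0),
    "bmi_prepregnancy": (25.5, 4.0, 15.0, 45.0),
    "bmi_pregnancy": (25.7, 4.1, 15.0, 46.0),
    "gestage_collection": (14.8, 7.5, 4.0, 36.0),
}

# Binary covariates: name -> P(indicator = 1).
BINARY_COVARIATES: dict[str, float] = {
    "nulliparity": 0.468,
    "difficulty_paying": 0.451,
    "employed": 0.494,
    "married_partner": 0.827,
    "mestizo": 0.804,
    "planned_pregnancy": 0.407,
    "infant_male": 0.512,
    "hair_dye": 0.147,
    "hair_tint": 0.427,
}

# Hair-wash frequency, three levels.
HAIR_WASH_COLUMN = "hair_wash"
HAIR_WASH_LEVELS = ("1-2_per_week", "3-5_per_week", "6-7_per_week")
HAIR_WASH_PROBS = (0.038, 0.712, 0.250)

CRP_COLUMN = "crp"  # serum C-reactive protein, mg/L; optional

DEFAULT_COVARIATES: list[str] = (
    list(CONTINUOUS_COVARIATES) + list(BINARY_COVARIATES) + [HAIR_WASH_COLUMN]
)

HORMONES = ("hcc", "hcnc")
OCCASIONS = ("pre", "tri1")

EXPOSURE_COLUMNS: dict[str, dict[str, str]] = {
    "hcc": {"pre": "hcc_pre", "tri1": "hcc_tri1"},
    "hcnc": {"pre": "hcnc_pre", "tri1": "hcnc_tri1"},
}
ALL_EXPOSURE_COLUMNS = [c for h in HORMONES for c in EXPOSURE_COLUMNS[h].values()]

TRUTH_COLUMNS = ("true_linpred", "true_prob")


def covariate_kind(name: str) -> str:
    """Classify a covariate as 'continuous', 'binary' or 'categorical'."""
    if name in CONTINUOUS_COVARIATES or name == CRP_COLUMN:
        return "continuous"
    if name in BINARY_COVARIATES:
        return "binary"
    if name == HAIR_WASH_COLUMN:
        return "categorical"
    raise DataError(f"unknown covariate {name!r}")


def validate_cohort(df: pd.DataFrame, require_truth: bool = False) -> None:
    """Check the fixed column schema and basic invariants.

    Raises DataError listing the offending columns/rows.
    """
    required = (
        [ID_COLUMN, OUTCOME_COLUMN] + DEFAULT_COVARIATES + ALL_EXPOSURE_COLUMNS
    )
    if require_truth:
        required += list(TRUTH_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"cohort is missing columns: {missing}")
    if df[ID_COLUMN].duplicated().any():
        dups = df.loc[df[ID_COLUMN].duplicated(), ID_COLUMN].tolist()[:5]
        raise DataError(f"duplicated participant_id values, e.g. {dups}")
    out = df[OUTCOME_COLUMN]
    if not out.dropna().isin([0, 1]).all():
        raise DataError("preterm outcome must be 0/1")
    for col in ALL_EXPOSURE_COLUMNS:
        vals = df[col].dropna()
        if (vals <= 0).any():
            bad = df.index[df[col] <= 0][:5].tolist()
            raise DataError(
                f"exposure {col!r} must be strictly positive; offending rows {bad}"
            )


def read_cohort(path, validate: bool = True) -> pd.DataFrame:
    """Read a cohort from comma-separated text (empty field = missing)."""
    df = pd.read_csv(path)
    if validate:
        validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort as comma-separated text with a header row."""
    df.to_csv(path, index=False)
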