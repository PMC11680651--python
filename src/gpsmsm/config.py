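"""Configuration objects for simulation and analysis runs.

Both configs are plain dataclasses serialisable to/from YAML so runs are
reproducible from a single structured file plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from . import schema
from .exceptions import ConfigurationError

# Target marginal mean/SD (pg/mg) for each hormone and hair segment;
# converted to lognormal parameters by moment inversion.
EXPOSURE_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    "hcc": {"pre": (4.12, 5.10), "tri1": (5.10, 6.54)},
    "hcnc": {"pre": (5.33, 5.85), "tri1": (9.95, 9.50)},
}


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Return (mu, sigma) of the lognormal with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("lognormal moments must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _default_logmean() -> dict[str, dict[str, float]]:
    return {
        h: {o: lognormal_params_from_moments(*EXPOSURE_TARGETS[h][o])[0]
            for o in schema.OCCASIONS}
        for h in schema.HORMONES
    }


def _default_logsd() -> dict[str, dict[str, float]]:
    return {
        h: {o: lognormal_params_from_moments(*EXPOSURE_TARGETS[h][o])[1]
            for o in schema.OCCASIONS}
        for h in schema.HORMONES
    }


def _default_confounders() -> dict[str, tuple[float, float]]:
    # (effect on log exposure, effect on log outcome risk); continuous
    # covariates enter standardized, binary as centred indicators.  Strength
    # is chosen so the unweighted RR is biased upward by well over 0.10 while
    # weighted balance is recoverable — see docs/methods.md.
    return {
        "maternal_age": (0.22, 0.42),
        "bmi_prepregnancy": (0.18, 0.33),
        "gestage_collection": (0.12, 0.20),
        "nulliparity": (0.22, 0.42),
        "difficulty_paying": (0.18, 0.36),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    ``true_rr_per_sd`` is the marginal causal risk ratio of preterm birth per
    one SD of the standardized log exposure, per occasion.  ``baseline_risk``
    is the outcome probability when every standardized exposure and every
    confounder effect is zero.
    """

    n_participants: int = 1807
    seed: int = 0
    true_rr_per_sd: dict[str, float] = field(
        default_factory=lambda: {"pre": 1.0, "tri1": 1.37})
    baseline_risk: float = 0.072
    confounder_strength: dict[str, tuple[float, float]] = field(
        default_factory=_default_confounders)
    cross_period_correlation: float = 0.6
    exposure_logmean: dict[str, dict[str, float]] = field(
        default_factory=_default_logmean)
    exposure_logsd: dict[str, dict[str, float]] = field(
        default_factory=_default_logsd)
    missingness_rate: float = 0.005
    interaction_coefficient: float = 0.0
    causal_hormone: str = "hcc"
    include_crp: bool = False

    def validate(self) -> None:
        if not isinstance(self.n_participants, int) or self.n_participants < 1:
            raise ConfigurationError("n_participants must be a positive integer")
        if not (0.0 <= self.baseline_risk < 1.0):
            raise ConfigurationError("baseline_risk must lie in [0, 1)")
        if abs(self.cross_period_correlation) >= 1.0:
            raise ConfigurationError(
                "cross_period_correlation must lie strictly inside (-1, 1)")
        if not (0.0 <= self.missingness_rate <= 0.05):
            raise ConfigurationError("missingness_rate must lie in [0, 0.05]")
        if self.causal_hormone not in schema.HORMONES:
            raise ConfigurationError("causal_hormone must be 'hcc' or 'hcnc'")
        for occ in schema.OCCASIONS:
            if occ not in self.true_rr_per_sd:
                raise ConfigurationError(f"true_rr_per_sd missing occasion {occ!r}")
            if self.true_rr_per_sd[occ] <= 0:
                raise ConfigurationError("true_rr_per_sd entries must be positive")
        for h in schema.HORMONES:
            for occ in schema.OCCASIONS:
                if self.exposure_logsd[h][occ] <= 0:
                    raise ConfigurationError(
                        f"exposure_logsd[{h}][{occ}] must be positive")
        known = set(schema.DEFAULT_COVARIATES) | {schema.CRP_COLUMN}
        for name in self.confounder_strength:
            if name not in known:
                raise ConfigurationError(
                    f"confounder_strength references unknown covariate {name!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["confounder_strength"] = {
            k: list(v) for k, v in self.confounder_strength.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "confounder_strength" in d:
            d["confounder_strength"] = {
                k: tuple(v) for k, v in d["confounder_strength"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class AnalysisConfig:
    """End-to-end analysis settings (input, covariate set, engine, outputs)."""

    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    hormones: list[str] = field(default_factory=lambda: list(schema.HORMONES))
    covariates: list[str] = field(
        default_factory=lambda: list(schema.DEFAULT_COVARIATES))
    engine: str = "gam"
    include_crp: bool = False
    trim_lower_pct: float = 1.0
    trim_upper_pct: float = 99.0
    weight_truncation: tuple[float, float] | None = None
    balance_threshold: float = 0.1
    basis_df: int = 10
    select_smoothing: bool = True
    output_dir: str | None = None
    seed: int = 0
    n_replicates: int = 500

    def validate(self) -> None:
        if self.engine not in ("gam", "linear"):
            raise ConfigurationError("engine must be 'gam' or 'linear'")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for h in self.hormones:
            if h not in schema.HORMONES:
                raise ConfigurationError(f"unknown hormone {h!r}")
        known = set(schema.DEFAULT_COVARIATES) | {schema.CRP_COLUMN}
        unknown = [c for c in self.covariates if c not in known]
        if unknown:
            raise ConfigurationError(f"unknown covariates {unknown}")
        if not (0 <= self.trim_lower_pct < self.trim_upper_pct <= 100):
            raise ConfigurationError(
                "trim percentiles must satisfy 0 <= lower < upper <= 100")
        if self.simulation is not None:
            self.simulation.validate()

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        if self.weight_truncation is not None:
            d["weight_truncation"] = list(self.weight_truncation)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if d.get("weight_truncation") is not None:
            d["weight_truncation"] = tuple(d["weight_truncation"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
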