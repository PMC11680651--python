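"""End-to-end orchestration: primary analysis, secondary analyses, and the
Monte-Carlo evaluation harness.

``run_primary`` executes, per hormone: 1/99-percentile trimming (joint across
the two hair segments) -> natural-log transform and standardization ->
complete-case restriction -> GPS fit per occasion -> stabilized weights ->
joint weighted Poisson MSM, together with balance diagnostics and a run
manifest.  Because the two occasions' exposures are strongly cross-correlated,
the joint MSM weight is built sequentially: the pre-pregnancy weight uses the
marginal stabilizer, while the first-trimester weight stabilizes by the
conditional density f(Z_tri1 | Z_pre) and conditions its denominator GPS on
Z_pre in addition to the covariates.  A product of the two *marginal*
per-occasion stabilized weights is not a valid joint weight under
cross-correlation and is kept only for per-occasion balance diagnostics.  ``run_secondary`` adds the cumulative RR, the between-occasion
interaction test and the curvilinearity test.  ``run_simulation_study``
measures bias, RMSE, CI coverage, type-I error and balance achievement of the
weighted and unweighted estimators against the generator's known truth.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .balance import BalanceReport, balance_table, plot_balance
from .config import AnalysisConfig, SimulationConfig
from .exceptions import ConfigurationError, DataError
from .gps import GeneralizedPropensityScore, GPSResults, WeightSet
from .msm import (MarginalStructuralPoisson, MSMResults, combine_weights,
                  curvilinearity_test, interaction_test)
from .preprocess import AnalysisSet, prepare_analysis_set
from .simulate import simulate_cohort

__all__ = ["analyze_hormone", "run_primary", "run_secondary",
           "run_simulation_study", "HormoneAnalysis", "SimulationStudyReport"]


@dataclass
class HormoneAnalysis:
    """Everything the pipeline produced for one hormone."""

    hormone: str
    analysis: AnalysisSet
    gps: dict[str, GPSResults]            # occasion (or "tri1_seq") -> fit
    weights: dict[str, WeightSet]         # marginal per occasion + "tri1_seq"
    balance: dict[str, BalanceReport]
    msm: MSMResults                        # joint weighted MSM
    msm_unweighted: MSMResults

    @property
    def joint_weights(self) -> pd.Series:
        """Sequential joint stabilized weight sw_pre * sw_tri1|pre."""
        return combine_weights(self.weights["pre"], self.weights["tri1_seq"])

    def to_dict(self) -> dict:
        return {
            "hormone": self.hormone,
            "counts": self.analysis.counts,
            "standardization": self.analysis.standardization,
            "gps": {occ: {"sigma": g.sigma, "edf": g.edf,
                          "r_squared": g.r_squared,
                          "smoothing": g.smoothing}
                    for occ, g in self.gps.items()},
            "weights": {occ: w.to_dict() for occ, w in self.weights.items()},
            "balance": {occ: b.to_dict() for occ, b in self.balance.items()},
            "msm": self.msm.to_dict(),
            "msm_unweighted": self.msm_unweighted.to_dict(),
            "cumulative_rr": self.msm.cumulative_rr(),
        }


def _occasion_covariates(config: AnalysisConfig, occasion: str) -> list[str]:
    cov = list(config.covariates)
    # CRP (inflammation) is measured in pregnancy serum, so it can confound
    # only the first-trimester exposure models.
    if config.include_crp and occasion == "tri1":
        cov.append(schema.CRP_COLUMN)
    return cov


def _sequential_tri1_weights(aset: AnalysisSet, config: AnalysisConfig,
                             alphas: dict[str, list] | None,
                             ) -> tuple[GPSResults, WeightSet]:
    """First-trimester weight for the joint MSM: denominator GPS conditions
    on the covariates AND the pre-pregnancy exposure; the stabilizing
    numerator is the fitted normal density f(Z_tri1 | Z_pre)."""
    z_pre = aset.zcolumn("pre")
    z_tri = aset.zcolumn("tri1")
    cov = _occasion_covariates(config, "tri1")
    continuous = [c for c in cov
                  if schema.covariate_kind(c) == "continuous"] + [z_pre]
    den = GeneralizedPropensityScore(
        aset.data, z_tri, cov + [z_pre], continuous=continuous,
        engine=config.engine, basis_df=config.basis_df,
        alpha=None if alphas is None else alphas.get("tri1_seq"),
        select_smoothing=config.select_smoothing).fit()
    num = GeneralizedPropensityScore(
        aset.data, z_tri, [z_pre], continuous=[z_pre],
        engine="linear").fit()
    ws = den.stabilized_weights(truncate=config.weight_truncation,
                                numerator=num)
    return den, ws


def analyze_hormone(cohort: pd.DataFrame, hormone: str,
                    config: AnalysisConfig,
                    alphas: dict[str, list] | None = None) -> HormoneAnalysis:
    """Run the full per-hormone pipeline on a cohort table.

    ``alphas`` optionally fixes the spline penalty weights per occasion
    (used by the simulation harness to reuse a selection across replicates).
    """
    all_cov = sorted(set(_occasion_covariates(config, "pre"))
                     | set(_occasion_covariates(config, "tri1")))
    aset = prepare_analysis_set(cohort, hormone, all_cov,
                                config.trim_lower_pct, config.trim_upper_pct)
    gps, weights, balance = {}, {}, {}
    for occ in schema.OCCASIONS:
        cov = _occasion_covariates(config, occ)
        zcol = aset.zcolumn(occ)
        model = GeneralizedPropensityScore(
            aset.data, zcol, cov, engine=config.engine,
            basis_df=config.basis_df,
            alpha=None if alphas is None else alphas.get(occ),
            select_smoothing=config.select_smoothing)
        res = model.fit()
        gps[occ] = res
        weights[occ] = res.stabilized_weights(truncate=config.weight_truncation)
        balance[occ] = balance_table(aset.data, zcol, cov,
                                     weights=weights[occ],
                                     threshold=config.balance_threshold)
    gps["tri1_seq"], weights["tri1_seq"] = _sequential_tri1_weights(
        aset, config, alphas)
    zcols = [aset.zcolumn(occ) for occ in schema.OCCASIONS]
    sw = combine_weights(weights["pre"], weights["tri1_seq"])
    msm = MarginalStructuralPoisson(
        aset.data, schema.OUTCOME_COLUMN, zcols, weights=sw,
        label=f"{hormone} SIPW").fit()
    msm_uw = MarginalStructuralPoisson(
        aset.data, schema.OUTCOME_COLUMN, zcols,
        label=f"{hormone} unweighted").fit()
    return HormoneAnalysis(hormone=hormone, analysis=aset, gps=gps,
                           weights=weights, balance=balance, msm=msm,
                           msm_unweighted=msm_uw)


def _load_or_simulate(config: AnalysisConfig,
                      cohort: pd.DataFrame | None) -> pd.DataFrame:
    if cohort is not None:
        return cohort
    if config.cohort_path is not None:
        return schema.read_cohort(config.cohort_path)
    if config.simulation is not None:
        sim = config.simulation
        return simulate_cohort(sim)
    raise ConfigurationError(
        "config must provide cohort_path, simulation, or an in-memory cohort")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(results: dict, config: AnalysisConfig, stem: str) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    jpath = outdir / f"{stem}_results.json"
    jpath.write_text(json.dumps(results, indent=2, sort_keys=True,
                                default=float))
    files.append(jpath)
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "outputs": {},
    }
    for f in files:
        manifest["outputs"][f.name] = _sha256(f)
    (outdir / f"{stem}_manifest.json").write_text(
        json.dumps(manifest, indent=2))


def run_primary(config: AnalysisConfig, cohort: pd.DataFrame | None = None,
                ) -> dict[str, HormoneAnalysis]:
    """Primary analysis for every configured hormone; writes result tables,
    balance plots and a manifest when an output directory is configured."""
    config.validate()
    cohort = _load_or_simulate(config, cohort)
    out = {h: analyze_hormone(cohort, h, config) for h in config.hormones}
    if config.output_dir is not None:
        results = {h: a.to_dict() for h, a in out.items()}
        _write_outputs(results, config, "primary")
        outdir = Path(config.output_dir)
        for h, a in out.items():
            for occ, rep in a.balance.items():
                plot_balance(rep, outdir / f"balance_{h}_{occ}.png")
            (outdir / f"msm_{h}.txt").write_text(a.msm.summary() + "\n")
    return out


def run_secondary(config: AnalysisConfig, cohort: pd.DataFrame | None = None,
                  primary: dict[str, HormoneAnalysis] | None = None) -> dict:
    """Secondary analyses: cumulative RR, interaction test, curvilinearity."""
    config.validate()
    if primary is None:
        primary = run_primary(config, cohort)
    out = {}
    for h, a in primary.items():
        zcols = [a.analysis.zcolumn(occ) for occ in schema.OCCASIONS]
        sw = a.joint_weights
        inter = interaction_test(a.analysis.data, schema.OUTCOME_COLUMN,
                                 zcols, weights=sw)
        curv = curvilinearity_test(a.analysis.data, schema.OUTCOME_COLUMN,
                                   zcols, weights=sw,
                                   basis_df=config.basis_df,
                                   select_smoothing=config.select_smoothing)
        out[h] = {
            "cumulative_rr": a.msm.cumulative_rr(),
            "interaction": {"b": inter.coefficient,
                            "lrt_statistic": inter.lrt_statistic,
                            "p": inter.p_value,
                            "risk_ratios":
                                inter.full.risk_ratios().to_dict("index")},
            "curvilinearity": {"lrt_statistic": curv.lrt_statistic,
                               "df": curv.df, "p": curv.p_value,
                               "spline_edf": curv.spline_edf},
        }
    if config.output_dir is not None:
        _write_outputs(out, config, "secondary")
    return out


@dataclass
class SimulationStudyReport:
    """Monte-Carlo evaluation of the weighted vs unweighted estimators."""

    n_replicates: int
    truth: dict[str, float]            # occasion -> true RR per SD
    estimates: pd.DataFrame            # one row per replicate x occasion
    interaction_p: list[float]
    balance_pass_rate: float
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n_replicates": self.n_replicates, "truth": self.truth,
                "balance_pass_rate": self.balance_pass_rate,
                "summary": self.summary}

    def text_table(self) -> str:
        rows = [f"Simulation study, R={self.n_replicates}"]
        for occ, s in self.summary.items():
            rows.append(
                f"  {occ}: truth={self.truth[occ]:.3f}  "
                f"weighted RR={s['mean_rr_weighted']:.3f} "
                f"(bias {s['bias_weighted']:+.3f}, RMSE {s['rmse_weighted']:.3f}, "
                f"coverage {s['coverage']:.1%}, reject {s['rejection_rate']:.1%})  "
                f"unweighted RR={s['mean_rr_unweighted']:.3f} "
                f"(bias {s['bias_unweighted']:+.3f})")
        rows.append(f"  balance pass rate: {self.balance_pass_rate:.1%}")
        return "\n".join(rows)


def run_simulation_study(config: AnalysisConfig,
                         progress: bool = False) -> SimulationStudyReport:
    """Replicate the full generate -> preprocess -> weight -> fit pipeline
    R times and score the estimators against the generator's truth.

    Per-replicate seeds are spawned from the master seed with numpy's
    SeedSequence (child i = spawn index i).  Spline penalty weights are
    selected by GCV on the first replicate and reused afterwards so every
    replicate analyses data under identical smoothing settings.
    """
    config.validate()
    if config.simulation is None:
        raise ConfigurationError("run_simulation_study requires a simulation "
                                 "config with known truth")
    sim = config.simulation
    R = config.n_replicates
    if R == 1:
        warnings.warn("R=1: Monte-Carlo error is undefined for a single "
                      "replicate", stacklevel=2)
    hormone = sim.causal_hormone
    truth = {occ: sim.true_rr_per_sd[occ] for occ in schema.OCCASIONS}
    children = np.random.SeedSequence(config.seed).spawn(R)

    rows, inter_p, balance_pass = [], [], []
    alphas: dict[str, list] | None = None
    for r in range(R):
        rng = np.random.default_rng(children[r])
        cohort = simulate_cohort(sim, rng=rng)
        if config.engine == "gam" and alphas is None and config.select_smoothing:
            a = analyze_hormone(cohort, hormone, config)
            alphas = {key: g.smoothing["alpha"]
                      for key, g in a.gps.items()
                      if g.smoothing.get("alpha") is not None}
        else:
            a = analyze_hormone(cohort, hormone, config, alphas=alphas)
        zcols = [a.analysis.zcolumn(occ) for occ in schema.OCCASIONS]
        rr_w = a.msm.risk_ratios()
        rr_u = a.msm_unweighted.risk_ratios()
        for occ, z in zip(schema.OCCASIONS, zcols):
            rows.append({
                "replicate": r, "occasion": occ,
                "rr_weighted": rr_w.loc[z, "rr"],
                "ci_low": rr_w.loc[z, "ci_low"],
                "ci_high": rr_w.loc[z, "ci_high"],
                "p_wald": rr_w.loc[z, "p_wald"],
                "rr_unweighted": rr_u.loc[z, "rr"],
                "covered": (rr_w.loc[z, "ci_low"] <= truth[occ]
                            <= rr_w.loc[z, "ci_high"]),
            })
        balance_pass.append(all(a.balance[occ].passed
                                for occ in schema.OCCASIONS))
        inter = interaction_test(a.analysis.data, schema.OUTCOME_COLUMN,
                                 zcols, weights=a.joint_weights)
        inter_p.append(inter.p_value)
        if progress and (r + 1) % 50 == 0:
            print(f"  replicate {r + 1}/{R}")

    est = pd.DataFrame(rows)
    summary = {}
    for occ in schema.OCCASIONS:
        e = est[est["occasion"] == occ]
        summary[occ] = {
            "mean_rr_weighted": float(e["rr_weighted"].mean()),
            "bias_weighted": float(e["rr_weighted"].mean() - truth[occ]),
            "rmse_weighted": float(np.sqrt(((e["rr_weighted"] - truth[occ]) ** 2
                                            ).mean())),
            "mean_rr_unweighted": float(e["rr_unweighted"].mean()),
            "bias_unweighted": float(e["rr_unweighted"].mean() - truth[occ]),
            "coverage": float(e["covered"].mean()),
            "rejection_rate": float((e["p_wald"] < 0.05).mean()),
        }
    report = SimulationStudyReport(
        n_replicates=R, truth=truth, estimates=est,
        interaction_p=inter_p,
        balance_pass_rate=float(np.mean(balance_pass)),
        summary=summary)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "simulation_study.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        (outdir / "simulation_study.txt").write_text(
            report.text_table() + "\n")
    return report
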