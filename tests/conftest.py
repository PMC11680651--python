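import numpy as np
import pytest

from gpsmsm import AnalysisConfig, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The default confounded study conditions (n=1807)."""
    return SimulationConfig(seed=20240901)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def null_config() -> SimulationConfig:
    """No confounding, both true RRs = 1."""
    return SimulationConfig(
        seed=20240902,
        true_rr_per_sd={"pre": 1.0, "tri1": 1.0},
        confounder_strength={},
        missingness_rate=0.0,
    )


@pytest.fixture(scope="session")
def hcc_analysis(default_cohort, default_config):
    """Full per-hormone pipeline output on the default cohort (GCV-selected
    smoothing); shared across tests because selection is the slow step."""
    from gpsmsm.pipeline import analyze_hormone
    cfg = AnalysisConfig(simulation=default_config, hormones=["hcc"])
    return analyze_hormone(default_cohort, "hcc", cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
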