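import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytomem.peaks import classify_peaks
from cytomem.sim import SimConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_peak_sim():
    """A small peak-mode simulation shared across read-only tests."""
    cfg = SimConfig.peaks_default(n_features=400, seed=7)
    matrix, design, truth = simulate(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def small_gene_sim():
    cfg = SimConfig.genes_default(n_features=400, seed=7)
    matrix, design, truth = simulate(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def peak_pipeline_runs():
    """Full simulate -> classify runs at default settings, three seeds."""
    runs = {}
    for seed in (1, 2, 3):
        cfg = SimConfig.peaks_default(n_features=2000, seed=seed)
        matrix, design, truth = simulate(cfg)
        runs[seed] = (classify_peaks(matrix, design), truth)
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
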