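import numpy as np
import pytest

from adjnorm.synth import SimulationConfig, simulate_paired_study


@pytest.fixture(scope="session")
def small_study():
    """A small paired study with signal planted only via normal tissue."""
    cfg = SimulationConfig(n_patients=120, n_genes=60, n_prog_normal=8, n_prog_tumor=0,
                           beta_normal=0.8, beta_tumor=0.0, n_deg=10, seed=42)
    return simulate_paired_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_survival(rng, n, censor=0.3, risk_coef=0.0, x=None):
    """Simple exponential survival draw used across tests."""
    if x is None:
        x = rng.standard_normal(n)
    t = rng.exponential(1.0, n) / np.exp(risk_coef * x)
    if censor > 0:
        c = rng.exponential(1.0 / censor * (1 - censor), n)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    else:
        event = np.ones(n, dtype=int)
    return x, np.maximum(t, 1e-9), event
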