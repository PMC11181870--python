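import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nephropep import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-effect cohort small enough for fast end-to-end tests."""
    cfg = SimulationConfig(
        n_patients=60,
        n_peptides=120,
        n_differential=15,
        effect_size=1.5,
        decline_frac=0.5,
        seed=42,
    )
    visits, matrix, truth = simulate_cohort(cfg)
    return cfg, visits, matrix, truth


@pytest.fixture()
def two_group_matrix():
    """Tiny labeled peptide matrix with a clear differential peptide."""
    rng = np.random.default_rng(7)
    n = 24
    samples = [f"S{i:02d}" for i in range(n)]
    labels = pd.Series(["UNCONTROLLED"] * (n // 2) + ["CONTROLLED"] * (n // 2), index=samples)
    base = rng.lognormal(8, 1, (n, 6))
    base[: n // 2, 0] *= 8.0  # strong up-regulation in uncontrolled
    mat = pd.DataFrame(base, index=samples, columns=[f"pep{j}" for j in range(6)])
    return mat, labels
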