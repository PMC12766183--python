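import numpy as np
import pytest

from proteorisk.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Complete two-sex cohort with one informative protein per sex."""
    cfg = SimConfig(
        n_participants=600, n_proteins=8, protein_block_size=4,
        protein_block_correlation=0.2,
        informative_male={1: np.log(2.0), 2: np.log(1.8)},
        informative_female={1: np.log(2.0), 3: np.log(1.8)},
        baseline_hazard_rate=0.012, dropout_rate=0.01,
        missing_rate_range=(0.0, 0.0), lod_quantile_range=(0.0, 0.0),
        seed=42)
    return generate_cohort(cfg)


@pytest.fixture
def survival_toy():
    """Small censored survival dataset with a real signal."""
    rng = np.random.default_rng(7)
    n = 120
    x = rng.standard_normal(n)
    t = rng.exponential(np.exp(-0.8 * x) * 12.0)
    c = rng.exponential(15.0, n)
    time = np.minimum(np.minimum(t, c), 10.0)
    event = ((t <= c) & (t <= 10.0)).astype(int)
    return x, time, event
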