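import numpy as np
import pandas as pd
import pytest

from tcrpi import (
    AnalysisParams,
    SimulationConfig,
    generate_study,
    run_analysis,
)

SMALL_CONFIG = dict(samples_per_cohort=100, n_genes=300, genes_per_set=10, seed=1)


@pytest.fixture(scope="session")
def small_study():
    """A compact four-cohort study with the default planted signature."""
    return generate_study(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_nes(small_study):
    from tcrpi import normalize_enrichment, ssgsea_matrix

    cohorts, sets, _, _ = small_study
    raw = pd.concat([ssgsea_matrix(c, sets) for c in cohorts], axis=1)
    return normalize_enrichment(raw)


@pytest.fixture(scope="session")
def full_scale_runs():
    """Ten fitted studies at the reference scale (800 training samples).

    Shared by the recovery and end-to-end checks so the expensive fits run
    once per session.
    """
    out = {}
    for seed in range(1, 11):
        cohorts, sets, clinical, truth = generate_study(SimulationConfig(seed=seed))
        result = run_analysis(cohorts, sets, clinical, AnalysisParams(), seed=seed)
        out[seed] = (truth, result)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_surv(rng, n=40, frac_censored=0.3, scale=30.0):
    """Continuous survival data without ties, for Cox/KM oracle checks."""
    time = rng.exponential(scale, n)
    event = (rng.uniform(size=n) > frac_censored).astype(int)
    return time, event
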