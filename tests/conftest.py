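import numpy as np
import pandas as pd
import pytest

from hdpoly.cohort import SimulationConfig, simulate_cohort
from hdpoly.coupling import coupling_table


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic cohort (21 controls / 19 preHD, 19 networks)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_couplings(default_bundle):
    return coupling_table(default_bundle.timecourses)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small cohort for pipeline-level tests (cheap end to end)."""
    cfg = SimulationConfig(n_control=8, n_prehd=8, n_networks=6, n_timepoints=80,
                           n_hypo_edges=4, n_hyper_edges=2, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def noise_features():
    """Balanced two-class pure-noise feature matrix factory."""

    def make(n=20, p=4, seed=0, index_prefix="s"):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         index=[f"{index_prefix}{i}" for i in range(n)],
                         columns=[f"f{j}" for j in range(p)])
        y = np.array(["patient"] * (n // 2) + ["control"] * (n - n // 2))
        return X, y

    return make
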