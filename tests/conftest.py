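import numpy as np
import pandas as pd
import pytest

from methconsensus import simulate
from methconsensus.containers import BetaMatrix


@pytest.fixture(scope="session")
def small_discovery():
    """A reduced-scale discovery set shared by read-only tests."""
    cfg = simulate.DiscoveryConfig(n_probes=3000)
    beta, sheet, annot, truth = simulate.generate_discovery_set(cfg, seed=11)
    return {"beta": beta, "sheet": sheet, "annot": annot, "truth": truth,
            "config": cfg}


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = simulate.generate_validation_cohort(
        simulate.CohortGenConfig(seed=7))
    return cohort, truth


@pytest.fixture
def toy_beta():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.05, 0.95, size=(8, 6))
    return BetaMatrix(pd.DataFrame(
        vals,
        index=[f"cg{i:03d}" for i in range(8)],
        columns=[f"S{j}" for j in range(6)]))
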