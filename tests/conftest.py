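import numpy as np
import pytest

from foragesim import (
    ModelKind,
    SimulationParams,
    run_reproductive,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def repro_batch():
    """20 reproductive replicates at the small-population/small-patch cell.

    Shared by the demographic-drift, lineage-mixing and kin-structure tests;
    N=40, R=15, T_prob=0.2, 1000 steps.
    """
    results = []
    for s in range(20):
        params = SimulationParams(
            n=40,
            r=15,
            t_prob=0.2,
            n_steps=1000,
            seed=3000 + s,
            model=ModelKind.REPRODUCTIVE,
        )
        results.append(run_reproductive(params))
    return results
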