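import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from limcomp.core_model import LinkageDesign
from limcomp.sampler import MCMCConfig
from limcomp.simulator import SimulationCondition, run_recovery

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_design() -> LinkageDesign:
    """Two items, three dimensions, one fresh statement per slot."""
    return LinkageDesign(
        item_ids=("i1", "i2"),
        dim_names=("a", "b", "c"),
        slots=np.array([[0, 1, 2], [3, 4, 5]]),
        statement_ids=("s1", "s2", "s3", "s4", "s5", "s6"),
        statement_dim=np.array([0, 1, 2, 0, 1, 2]),
    )


@pytest.fixture(scope="session")
def recovery_500():
    """Shared reduced-chain recovery run: 20 items, 500 persons, r = 0.5, T = 10.

    Several properties (utility bias near zero, utility-truth correlation,
    trait shrinkage) are read off this one seeded run to keep the suite
    affordable.
    """
    cond = SimulationCondition(n_items=20, n_persons=500, correlation=0.5, sigma2=0.087)
    cfg = MCMCConfig(n_chains=2, n_burnin=400, n_draws=600, seed=1)
    return run_recovery([cond], T=10, cfg=cfg)[cond.label()]
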