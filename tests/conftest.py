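import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hsettings

import clpnet as cn

hsettings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hsettings.load_profile("ci")

LABELS10 = tuple(f"s{i}" for i in range(10))
LABELS8 = tuple(f"s{i}" for i in range(8))


@pytest.fixture(scope="session")
def truth10():
    """Sparse 10-node truth: 8 directed edges of |0.3|, autoregression 0.3."""
    return cn.make_truth(
        node_labels=LABELS10, edge_density=8 / 90, effect_size=0.3,
        autoregression=0.3, seed=7,
    )


@pytest.fixture(scope="session")
def demo10(truth10):
    """Screened + imputed analysis dataset simulated from truth10 (n=2000)."""
    data = cn.simulate_panel(truth10, cn.GeneratorConfig(n=2000, seed=7))
    screened, _ = cn.apply_screening(data)
    return cn.impute_missing(screened)


@pytest.fixture(scope="session")
def network10(demo10):
    return cn.estimate_network(demo10)


@pytest.fixture(scope="session")
def strong10():
    """Hub generator: s0 -> s1,s2,s3 at 0.4 plus one strong edge fixture."""
    B = np.zeros((10, 10))
    B[0, 1] = B[0, 2] = B[0, 3] = 0.4
    truth = cn.TruthNetwork(LABELS10, B, np.full(10, 0.3), 0.3, np.full((2, 10), 0.1))
    data = cn.simulate_panel(truth, cn.GeneratorConfig(n=2000, seed=0))
    screened, _ = cn.apply_screening(data)
    return cn.impute_missing(screened)


@pytest.fixture(scope="session")
def canonical_small():
    """Raw canonical 28-node dataset (n=800) with screening fields and
    missingness, for instruments/pipeline tests."""
    truth = cn.make_truth(edge_density=0.05, seed=1)
    return cn.simulate_panel(truth, cn.GeneratorConfig(n=800, seed=1))
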