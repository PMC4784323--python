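import numpy as np
import pytest

from crvecov import SimParams, build_design, simulate_outcomes

LOG2 = float(np.log(2.0))
ALPHA0_10PCT = float(np.log(0.1 / 0.9))


@pytest.fixture(scope="session")
def base_params():
    """Conditional-model base scenario: 10% baseline prevalence, OR 2,
    household SD log 2, village SD log 2, 5x20x5 design."""
    return SimParams(
        alpha0=ALPHA0_10PCT,
        alpha=np.array([LOG2]),
        sigma_h=LOG2,
        sigma_v=LOG2,
        I=5,
        J=20,
        K=5,
    )


@pytest.fixture(scope="session")
def x1_design():
    return build_design(5, 20, 5, ("x1",), seed=42)


@pytest.fixture(scope="session")
def sim_dataset(x1_design, base_params):
    return simulate_outcomes(x1_design, base_params, seed=42)
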