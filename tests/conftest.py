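import numpy as np
import pytest

from chronopkpd.synth import (
    SynthScenario,
    generate,
    make_baseline_scenario,
    nonprodrug_archetype,
    prodrug_archetype,
)


@pytest.fixture(scope="session")
def dipper_baseline():
    return make_baseline_scenario("dipper", seed=0)


@pytest.fixture(scope="session")
def nondipper_baseline():
    return make_baseline_scenario("nondipper", seed=0)


@pytest.fixture(scope="session")
def nonprodrug_model(dipper_baseline):
    return nonprodrug_archetype(dipper_baseline)


@pytest.fixture(scope="session")
def prodrug_model(dipper_baseline):
    return prodrug_archetype(dipper_baseline)


@pytest.fixture(scope="session")
def synth_dataset(nonprodrug_model):
    """Standard two-arm study with concentrations at 2% noise."""
    scn = SynthScenario(true_model=nonprodrug_model, seed=123,
                        se_frac=0.02, include_concentrations=True)
    pre, post, truth = generate(scn)
    return pre, post, truth
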