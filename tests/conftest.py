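import numpy as np
import pytest

import premopt as po


@pytest.fixture(scope="session")
def surgical_scenario():
    return po.default_scenario("surgical", seed=7, n=5000)


@pytest.fixture(scope="session")
def surgical_data(surgical_scenario):
    return po.generate_survey(surgical_scenario)


@pytest.fixture(scope="session")
def surgical_fit(surgical_data):
    return po.fit_proportional_odds(surgical_data, stratum="surgical")


def make_toy_fit(b, kappa, item_ids=None):
    """OrdinalFit carrying chosen parameters (no estimation)."""
    b = np.asarray(b, float)
    ids = tuple(item_ids) if item_ids is not None else tuple(f"item{j}" for j in range(len(b)))
    return po.OrdinalFit(item_ids=ids, b=b, kappa=np.asarray(kappa, float))


@pytest.fixture
def toy_fit_factory():
    return make_toy_fit
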