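import numpy as np
import pytest

from campnets.synthetic import (FixtureConfig, make_expression_survival_fixture,
                                make_interactome_fixture, make_pathway_fixture)


@pytest.fixture(scope="session")
def interactome():
    return make_interactome_fixture(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def study():
    """Planted expression/survival/pathway fixture shared across tests."""
    cfg = FixtureConfig(seed=1)
    expr, surv, truth = make_expression_survival_fixture(cfg)
    pathways = make_pathway_fixture(cfg)
    return cfg, expr, surv, truth, pathways


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
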