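import numpy as np
import pytest

from nwatch.designs import design_groups
from nwatch.inference import InferenceConfig, PriorSpec, run_mcmc
from nwatch.ring import BaselineProfileParams, make_baseline


@pytest.fixture(scope="session")
def baseline_field():
    return make_baseline(BaselineProfileParams(), 600)


@pytest.fixture(scope="session")
def groups():
    return design_groups()


@pytest.fixture(scope="session")
def bead_designs(groups):
    return groups["microbead"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def bead_chains(bead_designs):
    """One full-size Model B and Model A fit on the bead-experiment set.

    Shared across the acceptance tests: 5 chains x 5000 iterations each.
    """
    config = InferenceConfig(seed=42, min_iterations=5000, n_chains=5)
    chains_B = run_mcmc(bead_designs, "B", PriorSpec.for_model("B"), config)
    chains_A = run_mcmc(bead_designs, "A", PriorSpec.for_model("A"), config)
    return {"A": chains_A, "B": chains_B, "config": config}
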