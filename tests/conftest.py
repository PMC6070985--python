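import numpy as np
import pytest

from drltiming import CohortSpec, TRParams, simulate_cohort


@pytest.fixture(scope="session")
def baseline() -> TRParams:
    """The default synthetic responder: timed 0.70 / burst 0.18 / long 0.12."""
    return TRParams(p=0.7, q=0.6, N=6.0, c=2.67, L=2.0, Lprime=0.05, delta=0.3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20180626)


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort: 2/group, prevapor + late-abstinence weeks."""
    spec = CohortSpec(n_per_group=2, weeks=(0, 11), sessions_per_week=5, seed=42)
    return spec, simulate_cohort(spec)
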