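import numpy as np
import pytest

from smartrar import (
    cancer_pain_design,
    calibrated,
    run_trial,
    sr_method,
    true_regime_values,
)


@pytest.fixture(scope="session")
def design():
    return cancer_pain_design()


@pytest.fixture(scope="session")
def params():
    return calibrated()


@pytest.fixture(scope="session")
def truth(params):
    return true_regime_values(params)


@pytest.fixture(scope="session")
def sr_ledger(params):
    """One completed uniform-randomization trial (N=1000)."""
    return run_trial(params, sr_method(), seed=np.random.SeedSequence([3, 0]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
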