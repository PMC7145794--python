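import numpy as np
import pytest

from metabound import (
    CategoryParams,
    ModelVariant,
    SyntheticObserver,
    Type1Params,
    Type2Params,
    generate_trial_bank,
)


@pytest.fixture(scope="session")
def bank():
    """Default 100-trial, 40-sample bank shared across tests."""
    return generate_trial_bank(seed=1)


@pytest.fixture(scope="session")
def small_bank():
    return generate_trial_bank(n_trials=40, seed=2)


@pytest.fixture
def type1():
    return Type1Params(sigma=0.6, alpha=1.0, a=0.15, b=0.8, lam=3.0,
                       mu_U=2.0, sigma_U=1.0)


@pytest.fixture
def type2():
    return Type2Params(sigma_c=0.5, alpha_c=1.0, a_c=0.15, b_c=0.8,
                       lam1=2.0, lam2=4.0, lam3=7.0)


@pytest.fixture
def observer(type1, type2):
    return SyntheticObserver(type1=type1, type2=type2,
                             variant=ModelVariant(), seed=42)
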