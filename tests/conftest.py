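import numpy as np
import pytest

from skewlink import (
    GroupedBinomialData,
    SyntheticSpec,
    load_poison,
    load_snail,
    simulate,
)


@pytest.fixture(scope="session")
def poison():
    return load_poison()


@pytest.fixture(scope="session")
def snail():
    data, z_tables = load_snail()
    return data, z_tables


@pytest.fixture(scope="session")
def small_weibull_data():
    """Well-conditioned synthetic Weibull-link dose-response data.

    eta spans roughly (0.3, 1.7) so fitted probabilities sweep most of
    (0, 1); 250 subjects per pattern across 20 patterns.
    """
    return simulate(
        SyntheticSpec(link="weibull", beta=(0.2, 0.75), shape=(2.0,), trials=250, seed=11)
    )


@pytest.fixture(scope="session")
def tiny_binomial():
    """Three hand-checkable covariate patterns."""
    X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
    return GroupedBinomialData(X, [2, 5, 9], [10, 10, 10])
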