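import numpy as np
import pytest

from cghawkes import HawkesModel, KernelMatrixSpec


@pytest.fixture(scope="session")
def symmetric_model():
    """Symmetric bivariate exponential model: mu=1, a_s=0.4, a_c=0.3, beta=1."""
    alpha = np.array([[0.4, 0.3], [0.3, 0.4]])
    return HawkesModel(mu=[1.0, 1.0], kernel=KernelMatrixSpec.exponential(alpha, 1.0))


@pytest.fixture(scope="session")
def asymmetric_model():
    """Asymmetric bivariate model used in the recovery studies."""
    alpha = np.array([[0.4, 0.5], [0.3, 0.2]])
    beta = np.array([[0.5, 0.7], [0.3, 1.0]])
    return HawkesModel(mu=[1.0, 1.0], kernel=KernelMatrixSpec.exponential(alpha, beta))


@pytest.fixture(scope="session")
def univariate_model():
    return HawkesModel(mu=[1.0], kernel=KernelMatrixSpec.exponential([[0.5]], 1.0))
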