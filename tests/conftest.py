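import numpy as np
import pytest

from gegdist import GEGParams

# The standard study grid for the GEG shape parameters (mu = 0, sigma = 1).
STUDY_TAUS = (0.5, 1.25)
STUDY_ALPHAS = (0.75, 1.75, 2.75)


@pytest.fixture(scope="session")
def study_params():
    """GEG parameter sets crossing the study grid of tau and alpha."""
    return [
        GEGParams(tau, 0.0, 1.0, alpha)
        for tau in STUDY_TAUS
        for alpha in STUDY_ALPHAS
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
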