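import numpy as np
import pytest

from uinhib.phase_model import PhaseModelConfig, PRCFunction, VmPhaseMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_prc():
    return PRCFunction()


@pytest.fixture(scope="session")
def canonical_vmap():
    return VmPhaseMap.canonical()


@pytest.fixture(scope="session")
def model_config():
    return PhaseModelConfig()


@pytest.fixture(scope="session")
def bin_averaged_z():
    """True PRC averaged over each of 40 regression bins (what the
    charge-regression estimator targets)."""

    def _avg(prc, n_bins=40, sub=200):
        phi = (np.arange(n_bins * sub) + 0.5) / (n_bins * sub)
        return prc(phi).reshape(n_bins, sub).mean(axis=1)

    return _avg
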