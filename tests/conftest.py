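import numpy as np
import pytest

from wfrsurv import WFrParams, load_gastric_data, load_simulated_example


@pytest.fixture(scope="session")
def table8_mle() -> WFrParams:
    """Published point estimates for the 15-point censored example."""
    return WFrParams(0.1440, 2.8097, 0.3817, 0.6267)


@pytest.fixture(scope="session")
def sim_truth() -> WFrParams:
    """Generating parameters of the packaged censored example."""
    return WFrParams(0.5, 2.5, 0.96, 0.6)


@pytest.fixture(scope="session")
def study_truth() -> WFrParams:
    """True parameters used throughout the Monte-Carlo study designs."""
    return WFrParams(0.5, 0.5, 2.0, 3.5)


@pytest.fixture(scope="session")
def censored_example():
    return load_simulated_example()


@pytest.fixture(scope="session")
def gastric():
    return load_gastric_data()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
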