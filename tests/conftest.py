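import warnings

import numpy as np
import pytest

from mvmeta_mf import builtin_table1, test_profile


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def fast_cfg():
    """Short MCMC protocol for unit tests."""
    return test_profile(seed=11)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Short-protocol fits legitimately trip the convergence gate."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*did not meet the convergence gate.*"
        )
        warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")
        yield
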