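import numpy as np
import pytest

from insightbench import builtin_battery, builtin_profile, run_full_analysis


@pytest.fixture(scope="session")
def practice_battery():
    return builtin_battery("practice")


@pytest.fixture(scope="session")
def transfer_battery():
    return builtin_battery("transfer")


@pytest.fixture(scope="session")
def pooled_battery():
    return builtin_battery("pooled")


@pytest.fixture(scope="session")
def practice_profile():
    return builtin_profile("practice")


@pytest.fixture(scope="session")
def transfer_profile():
    return builtin_profile("transfer")


@pytest.fixture(scope="session")
def pooled_profile():
    return builtin_profile("pooled")


@pytest.fixture(scope="session")
def default_report():
    """Full default analysis (includes the pooled MITM placement); computed
    once per session because the pooled set takes a few seconds."""
    return run_full_analysis()


def random_rates(rng: np.random.Generator, n: int, margin: float = 0.02) -> np.ndarray:
    """Random rates kept away from 0/1 so log-space paths stay finite."""
    return rng.uniform(margin, 1.0 - margin, size=n)
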