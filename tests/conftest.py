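import pytest

from lacticycle.pipeline import run_bundle, reference_calibrated_factors
from lacticycle.scenario import baseline_bundle


@pytest.fixture(scope="session")
def baseline():
    return baseline_bundle()


@pytest.fixture()
def bundle():
    """A fresh, mutable copy of the baseline bundle."""
    return baseline_bundle()


@pytest.fixture(scope="session")
def baseline_run(baseline):
    """Full pipeline result for the baseline scenario (shared, read-only)."""
    return run_bundle(baseline)


@pytest.fixture(scope="session")
def calibrated_factors():
    return reference_calibrated_factors()
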