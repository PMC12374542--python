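import pytest

from evkinetics import (
    default_rates,
    default_tumor_spec,
    reference_panel,
    tumor_to_population,
)


@pytest.fixture(scope="session")
def baseline_rates():
    return default_rates()


@pytest.fixture(scope="session")
def tumor_1cm(baseline_rates):
    """1-cm breast tumor at default density, secretion, and clearance."""
    return tumor_to_population(default_tumor_spec(1.0), baseline_rates)


@pytest.fixture(scope="session")
def calibrated_panel(baseline_rates):
    """Calibrated synthetic blood panel (sums to 1e10 EVs/ml x 3000 ml)."""
    return reference_panel(seed=0, rates=baseline_rates)
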