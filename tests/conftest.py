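import pytest

from mppsim import ModelParameters


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Shipped default parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def simple_cost_params() -> ModelParameters:
    """Parameters with round cost shares (10% production, 20% marketing for
    both makers) for hand-checkable profit arithmetic."""
    return ModelParameters(
        c_prod=0.10, c_mkt=0.20, c_prod_gen=0.10, c_mkt_gen=0.20
    )
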