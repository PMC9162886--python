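import pytest

from vbpricer import datasets


@pytest.fixture(scope="session")
def reference_rates():
    return datasets.load_reference_rates()


@pytest.fixture(scope="session")
def reference_portfolio():
    return datasets.load_reference_portfolio()


@pytest.fixture(scope="session")
def screening_portfolio():
    return datasets.load_screening_portfolio()
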