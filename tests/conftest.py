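import pytest

from bitterspace import core_library, generate, generate_worked_examples
from bitterspace.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def lib():
    return core_library()


@pytest.fixture(scope="session")
def worked_examples():
    return generate_worked_examples()


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared across tests."""
    return generate(GeneratorConfig(seed=1))
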