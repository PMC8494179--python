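import pytest
from hypothesis import settings

import thyrocea as t

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_spec() -> t.ModelSpec:
    """The bundled default parameterization (shared, treated as read-only)."""
    return t.default_model()


@pytest.fixture(scope="session")
def base_case(paper_spec):
    """Base-case comparison of the two strategies under the bundled config."""
    result, sg, nsg = t.compare_strategies(paper_spec)
    return result, sg, nsg
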