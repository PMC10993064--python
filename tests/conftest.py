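import pytest

from dietshift import GeneratorConfig, generate, make_toy
from dietshift.optimise import random_problem as random_feasible_problem  # noqa: F401


@pytest.fixture(scope="session")
def toy_bundle():
    return make_toy()


@pytest.fixture(scope="session")
def synth_bundle():
    """Default synthetic survey (fixed seed, 14 groups, 74 foods)."""
    return generate(GeneratorConfig(seed=0))
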