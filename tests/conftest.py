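import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nickscan import GuideRNA, SimConfig, generate_reference  # noqa: E402


@pytest.fixture(scope="session")
def twenty_mer_guides():
    """Guides with 20-nt protospacers and an A inside the 4-8 window."""
    from nickscan import MULTIPLEX_GUIDES

    return [g for g in MULTIPLEX_GUIDES if len(g.protospacer) == 20]


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(genome_length=100_000, depth=35.0, seed=11)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture
def toy_guide():
    return GuideRNA("toy", "GAACACAAAGCATAGACTGC", "NGG")
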