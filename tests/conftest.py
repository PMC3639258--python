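import numpy as np
import pytest
from hypothesis import settings

from gcbias import CompositionSpec, GenomeSequence, synth_genome

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSequence:
    """10 kb two-block genome: AT-rich left half, GC-rich right half."""
    spec = CompositionSpec(blocks=((5000, 0.30), (5000, 0.70)))
    return synth_genome(spec, seed=42, name="toy")


@pytest.fixture(scope="session")
def flat_genome() -> GenomeSequence:
    """100 kb genome of uniform 50% GC (no block structure)."""
    spec = CompositionSpec(blocks=((100_000, 0.5),))
    return synth_genome(spec, seed=7, name="flat")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
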