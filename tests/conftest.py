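import numpy as np
import pytest

from shapefeat import synthetic


@pytest.fixture(scope="session")
def default_samples():
    """The default two-class synthetic set: 100 + 100, seed 7."""
    return synthetic.generate_samples(
        synthetic.ELONGATED_SPEC, synthetic.ROUNDED_SPEC, 100, seed=7
    )


@pytest.fixture(scope="session")
def small_samples():
    """A small two-class set for fast structural checks: 20 + 20, seed 3."""
    return synthetic.generate_samples(
        synthetic.ELONGATED_SPEC, synthetic.ROUNDED_SPEC, 20, seed=3
    )


@pytest.fixture(scope="session")
def fragmented_samples():
    """100 fragmented silhouettes (fragment_prob = 1, seed 11)."""
    return synthetic.generate_samples(
        synthetic.fragmented(synthetic.ELONGATED_SPEC),
        synthetic.fragmented(synthetic.ROUNDED_SPEC),
        50,
        seed=11,
    )


@pytest.fixture(scope="session")
def disk80():
    return synthetic.make_disk(80, (200, 200))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
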