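import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from kidseg.phantom import PhantomError, generate_phantom, sample_spec


def collect_phantoms(n: int, start_seed: int, image_size=(96, 96)):
    """Deterministically draw n valid phantom samples starting at a seed."""
    samples, s = [], start_seed
    while len(samples) < n:
        try:
            spec = sample_spec(s, image_size=image_size)
            image, mask, contour = generate_phantom(spec)
            samples.append({"image": image, "mask": mask, "contour": contour, "spec": spec})
        except PhantomError:
            pass
        s += 1
    return samples


@pytest.fixture(scope="session")
def phantom_batch():
    """A handful of default-size phantoms shared across tests."""
    return collect_phantoms(4, start_seed=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
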