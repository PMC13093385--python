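import numpy as np
import pytest

from pedaccum.simulate import OffspringSample


def make_sample(parent_pairs):
    """Build an OffspringSample from a list of (mother_id, father_id) tuples."""
    n = len(parent_pairs)
    return OffspringSample(
        np.array([f"o{i}" for i in range(n)], dtype=object),
        np.array([m for m, _ in parent_pairs], dtype=object),
        np.array([f for _, f in parent_pairs], dtype=object),
    )


@pytest.fixture
def triad_sample():
    """Three maternal half-siblings: one shared mother, three distinct fathers."""
    return make_sample([("F0", "M0"), ("F0", "M1"), ("F0", "M2")])


@pytest.fixture
def fullsib_pair():
    return make_sample([("F0", "M0"), ("F0", "M0")])
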