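import logging

import numpy as np
import pytest

from handkin import HandGeometry

logging.getLogger("handkin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geometry():
    return HandGeometry.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_angle_set(rng, lo=2.0, hi=100.0):
    """A random valid full angle set in well-conditioned ranges."""
    from handkin.hand import ANGLE_KEYS, THUMB_ABDUCTION

    angles = {}
    for key in ANGLE_KEYS:
        upper = min(hi, 80.0) if key == THUMB_ABDUCTION else hi
        angles[key] = float(rng.uniform(lo, upper))
    return angles
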