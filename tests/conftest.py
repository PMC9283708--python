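import numpy as np
import pytest

from tumornet import CellConfiguration, build_contact_network, fixture_hexagonal


@pytest.fixture
def rng():
    return np.random.default_rng(20260301)


@pytest.fixture
def hex_patch():
    """7-cell hexagonal kissing configuration: center plus 6 ring cells at spacing 1."""
    return fixture_hexagonal(1)


@pytest.fixture
def hex_net(hex_patch):
    return build_contact_network(hex_patch)


@pytest.fixture
def triangle():
    """Three cells at mutual distance 0.9 (an admissible contact triangle)."""
    d = 0.9
    pos = np.array(
        [[0.0, 0.0], [d, 0.0], [d / 2, d * np.sqrt(3) / 2]]
    )
    return CellConfiguration(time=0.0, positions=pos, ids=np.arange(3))


def random_admissible_positions(rng, n, box, min_dist=0.85):
    """Rejection-sampled positions with pairwise distances >= min_dist."""
    pts = []
    while len(pts) < n:
        cand = rng.random(2) * box
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_dist**2 for p in pts):
            pts.append(cand)
    return np.array(pts)
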