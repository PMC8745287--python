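import numpy as np
import pytest

import optodrum as od


@pytest.fixture(scope="session")
def arena_config() -> od.ArenaConfig:
    return od.ArenaConfig()


@pytest.fixture(scope="session")
def geometry() -> od.ArenaGeometry:
    return od.default_geometry()


@pytest.fixture(scope="session")
def small_geometry() -> od.ArenaGeometry:
    """A 201x201-frame geometry for fast mask-level tests."""
    return od.ArenaGeometry(center=(100, 100), mask_radius=90, stripe_roi=(80, 1, 40, 4))


@pytest.fixture(scope="session")
def short_trial(arena_config, geometry):
    """5 s noiseless gain-1 synthetic trial (frames + ground truth)."""
    behavior = od.BehaviorParams(following_gain=1.0, seed=0)
    return od.render_trial(arena_config, geometry, behavior, 5.0)


def blob_mask(shape, cx, cy, radius=6):
    """Filled disc mask used as a simple symmetric blob."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius * radius
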