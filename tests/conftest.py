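import numpy as np
import pytest

from ivuscal import AcquisitionMeta, CalciumDeposit, PhantomConfig, Pullback


@pytest.fixture
def tiny_meta():
    return AcquisitionMeta(n_alines=32, n_samples=128)


@pytest.fixture
def tiny_geometry():
    """Small phantom grid used throughout the unit tests."""
    return PhantomConfig(n_frames=12, n_alines=32, n_samples=128,
                         lumen_radius_samples=40, wall_thickness_samples=30)


@pytest.fixture
def noise_free_geometry(tiny_geometry):
    from dataclasses import replace
    return replace(tiny_geometry, speckle_scale=0.0)


@pytest.fixture
def one_deposit(tiny_geometry):
    return CalciumDeposit(frame_start=2, frame_end=7, aline_start=5,
                          arc_width=10, depth_sample=50)


@pytest.fixture
def random_pullback(tiny_meta):
    rng = np.random.default_rng(42)
    frames = rng.integers(0, 256, size=(8, 32, 128), dtype=np.uint8)
    return Pullback(frames=frames, meta=tiny_meta)
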