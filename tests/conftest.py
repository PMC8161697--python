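import numpy as np
import pytest

import enfaceoct as eo


@pytest.fixture(scope="session")
def default_grid() -> eo.SectorGrid:
    """Untilted OD grid centered in the default 512x512 image."""
    return eo.SectorGrid(
        center_px=(255.5, 255.5), fovea_disc_angle_deg=0.0, laterality="OD"
    )


@pytest.fixture(scope="session")
def noiseless_eye(default_grid):
    """One noiseless synthetic eye with its circle profile (shared: rendering
    a 50-slab stack is the expensive part of these tests)."""
    stack, truth = eo.generate_eye(noise_sd=0.0, seed=42)
    profile = eo.sample_circle(stack, default_grid)
    return stack, truth, profile


@pytest.fixture(scope="session")
def flat_eye_100(default_grid):
    """Noiseless eye with uniform 100 µm bundle extent (the worked slab-grid
    example: last visible 96.75 µm, first gap 100.62 µm)."""
    anchors = {s: 100.0 for s in eo.SECTOR_NAMES}
    stack, truth = eo.generate_eye(
        extent_anchors_um=anchors, noise_sd=0.0, seed=0
    )
    profile = eo.sample_circle(stack, default_grid)
    return stack, truth, profile


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
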