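import numpy as np
import pytest

from cellmech.synthetic import Disk, elliptical_cell_mask, generate_particle_image


@pytest.fixture
def disk_image():
    """A single rendered disk, radius 40 px, 0.5 µm/px, noiseless."""
    return generate_particle_image([Disk((60, 60), 40.0)], (120, 120), 0.5)


@pytest.fixture
def cell_mask():
    """A 256x256 elliptical cell footprint at 0.2 µm/px."""
    return elliptical_cell_mask((256, 256), 0.2)


def shoelace_area(vertices: np.ndarray) -> float:
    """Independent polygon-area oracle (plain shoelace formula)."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
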