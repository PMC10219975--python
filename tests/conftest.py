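import numpy as np
import pytest

from duvtomo.optics import OpticalConfig
from duvtomo.phantom import CellSpec, TissuePhantom


@pytest.fixture
def clean_config() -> OpticalConfig:
    """Noiseless, shading-free small-field configuration."""
    return OpticalConfig(
        pixel_size_um=1.0,
        fov_px=(64, 64),
        illumination_ramp=0.0,
        vignette=0.0,
        photon_scale=0.0,
        read_noise=0.0,
        offset=0.0,
    )


@pytest.fixture
def single_cell_phantom() -> TissuePhantom:
    return TissuePhantom(
        bounding_box=(64.0, 64.0, 300.0),
        cells=[CellSpec(center=(32.0, 32.0, 6.0), nucleus_radius=3.0, soma_radius=5.0, dye_amplitudes=(1.0,))],
        n_dyes=1,
    )


def make_cell_field(n, box, depth_range, seed, amp=1.0):
    """Scatter identical-amplitude cells uniformly (helper for render tests)."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform([6, 6], [box[0] - 6, box[1] - 6], size=(n, 2))
    z = rng.uniform(*depth_range, size=n)
    cells = [
        CellSpec(center=(xy[i, 0], xy[i, 1], z[i]), nucleus_radius=3.0, soma_radius=5.0, dye_amplitudes=(amp,))
        for i in range(n)
    ]
    return TissuePhantom(bounding_box=box, cells=cells, n_dyes=1)
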