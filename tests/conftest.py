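import numpy as np
import pytest

from kerafil import simulate
from kerafil.core import Image2D, PipelineConfig

PIXEL_SIZE_A = 2.206   # the acquisition pixel size used throughout


@pytest.fixture
def config():
    return PipelineConfig(pixel_size_A=PIXEL_SIZE_A)


@pytest.fixture
def helical_class():
    """Noise-free 163 Å-pitch class average, 250 px box."""
    spec = simulate.FilamentSpec(pitch_A=163.0)
    return simulate.generate_filament_image(spec, 250, PIXEL_SIZE_A)


@pytest.fixture
def cosine_image():
    """Pure axial cosine of period 163 Å (no lateral structure)."""
    ny = nx = 250
    z = np.arange(ny) * PIXEL_SIZE_A
    img = np.tile(np.cos(2 * np.pi * z / 163.0)[:, None], (1, nx))
    return Image2D(img, PIXEL_SIZE_A)
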