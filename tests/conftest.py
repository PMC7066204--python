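import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def gaussian_blob(shape, spacing, sigma_um, amplitude=100.0):
    """Smooth radially symmetric test field centred on the grid."""
    ny, nx = shape
    y = np.arange(ny) * spacing
    x = np.arange(nx) * spacing
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cy, cx = y[-1] / 2.0, x[-1] / 2.0
    return amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_um**2))
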