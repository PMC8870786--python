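import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from trabkit.core_io import GrayImage, Modality
from trabkit.phantom import PhantomSpec, generate_phantom
from trabkit.segmentation import Phase, PhaseMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bar_mask(shape, width, axis="rows", start=10):
    """Mask with one straight bar of the given width, spanning the image."""
    mask = np.zeros(shape, dtype=bool)
    if axis == "rows":
        mask[start:start + width, :] = True
    else:
        mask[:, start:start + width] = True
    return mask


def phase_mask_from_bool(mask, spacing=1.0, slice_thickness=0.0):
    labels = np.where(mask, int(Phase.BONE), int(Phase.MARROW))
    return PhaseMask(labels, spacing, spacing, slice_thickness)


def random_blob_mask(shape, seed, density=0.5):
    """Random smooth blob mask; reproducible; never empty or full."""
    from scipy.ndimage import gaussian_filter

    r = np.random.default_rng(seed)
    field = gaussian_filter(r.normal(size=shape), 2.0)
    mask = field > np.quantile(field, 1.0 - density)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    if mask.all():
        mask[0, 0] = False
    return mask


@pytest.fixture
def bar_phantom():
    """Noise-free horizontal-bar phantom: w=4 px struts, 12 px gaps."""
    spec = PhantomSpec(
        width=128, height=128, spacing=1.0, theta_p=0.0, sigma_p=0.0,
        strut_thickness=4.0, strut_spacing=12.0, seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture
def noisy_ct_phantom():
    spec = PhantomSpec(
        width=160, height=160, spacing=0.051, theta_p=67.0, sigma_p=10.0,
        strut_thickness=0.2, strut_spacing=0.6, noise_sd=15.0,
        psf_sigma=0.03, modality=Modality.CT_LIKE, seed=7,
    )
    return generate_phantom(spec)
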