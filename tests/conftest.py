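import numpy as np
import pytest

from fracdose import (
    DoseGrid,
    StructureMask,
    make_phantom,
    make_plan_dose,
    small_phantom_config,
)


@pytest.fixture(scope="session")
def small_phantom():
    """Scaled-down pelvic phantom (64x64x48 at 3 mm) shared across tests."""
    return make_phantom(small_phantom_config())


@pytest.fixture(scope="session")
def small_plan(small_phantom):
    return make_plan_dose(small_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_dose(rng):
    """Smooth random dose on a small grid with zero boundary shell."""
    shape = (24, 24, 24)
    bump = np.zeros(shape)
    bump[6:18, 6:18, 6:18] = rng.uniform(10.0, 50.0, (12, 12, 12))
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(bump, sigma=2.0)
    # truncate the (tiny) Gaussian tails so the dose support is strictly interior
    shell = np.zeros(shape, dtype=bool)
    shell[3:-3, 3:-3, 3:-3] = True
    smooth[~shell] = 0.0
    return DoseGrid(smooth, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def band_limited_dose():
    """Compact, slowly varying cos^2 bump: smooth enough for trilinear round trips."""
    shape = (48, 48, 48)
    sp = 2.0
    center = (np.array(shape) - 1) / 2.0 * sp
    ax = [np.arange(s) * sp for s in shape]
    r = np.sqrt(
        (ax[0] - center[0])[:, None, None] ** 2
        + (ax[1] - center[1])[None, :, None] ** 2
        + (ax[2] - center[2])[None, None, :] ** 2
    )
    R = 42.0
    dose = np.where(r < R, 50.0 * np.cos(np.pi * r / (2 * R)) ** 2, 0.0)
    return DoseGrid(dose, (sp, sp, sp), (0.0, 0.0, 0.0))


def make_box_mask(shape, spacing, origin, lo, hi, name="roi"):
    """Axis-aligned box mask helper in index coordinates."""
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return StructureMask(name, mask, spacing, origin)
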