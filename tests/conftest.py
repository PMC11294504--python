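import numpy as np
import pytest

from cardioreorient.phantom import PhantomSpec, generate_phantom
from cardioreorient.region_division import lvg_ced_divide
from cardioreorient.segmentation import pso_fcm_segment


@pytest.fixture(scope="session")
def clean_phantom():
    """Realistic clean phantom (blur + noise) at a two-axis tilt, with truth."""
    spec = PhantomSpec(alpha_true=15.0, beta_true=-10.0, seed=3)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Tilted phantom with no blur and no noise: exact geometry."""
    spec = PhantomSpec(alpha_true=15.0, beta_true=-10.0, psf_fwhm_mm=0.0, noise_scale=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def aligned_phantom():
    """Axis-aligned clean phantom (blur, no noise) for polar-map uniformity."""
    spec = PhantomSpec(alpha_true=0.0, beta_true=0.0, noise_scale=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def divided_clean(clean_phantom):
    vol, truth = clean_phantom
    result = lvg_ced_divide(vol)
    assert result.success
    return result, truth


@pytest.fixture(scope="session")
def segmented_clean(divided_clean):
    result, truth = divided_clean
    mask = pso_fcm_segment(result.cropped, seed=3)
    return result, mask, truth


def resample_truth_mask(truth_mask, box, cropped_shape):
    """Nearest-neighbour transfer of a truth mask into a divided volume's grid."""
    from cardioreorient.core_volume import Volume3D, crop_volume, resample_volume, BoundingBox

    vol = Volume3D(truth_mask.astype(np.float64) + 0.0, (2.0, 2.0, 2.0))
    sub = crop_volume(vol, box)
    res = resample_volume(sub, cropped_shape, interp="nearest")
    return res.data > 0.5
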