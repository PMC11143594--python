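import numpy as np
import pytest

from vesselseg import (
    BinaryMask,
    CalibrationParams,
    EnhancementParams,
    PhantomSpec,
    VolumeImage,
    build_feature_stack,
    clip_and_normalize,
    enhance_vessels,
    generate_phantom,
)


# small phantom template for fast unit tests (the default desk-scale
# template is exercised by the end-to-end acceptance tests)
SMALL_SPEC = PhantomSpec(
    shape=(24, 40, 40),
    organ_radii=(9.0, 15.0, 15.0),
    n_tubes=2,
    radius_range=(1.0, 2.0),
    walk_steps=25,
    seed=7,
)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_stack(small_phantom):
    volume, vessel, organ = small_phantom
    vals = volume.data[vessel.data.astype(bool)]
    calib = CalibrationParams(mu=float(vals.mean()), sigma=float(vals.std()))
    enhanced = enhance_vessels(clip_and_normalize(volume, calib), EnhancementParams())
    return build_feature_stack(enhanced)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_volume(data, spacing=None):
    return VolumeImage(data=np.asarray(data, dtype=float), spacing=spacing)


def make_mask(data):
    return BinaryMask(data=np.asarray(data))
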