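import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spiraltomo import (
    OpticsParams,
    PhantomSpec,
    Primitive,
    SpiralParams,
    make_phantom,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

VOX = 2.0


@pytest.fixture(scope="session")
def two_sphere_spec():
    """Two attenuating + fluorescent spheres inside a 192 um cube."""
    return PhantomSpec(
        [
            Primitive.sphere((70, 80, 96), 20, attenuation=0.01, fluorescence=1.0,
                             label="a"),
            Primitive.sphere((120, 110, 96), 14, attenuation=0.015, fluorescence=0.6,
                             label="b"),
        ],
        (192, 192, 192),
    )


@pytest.fixture(scope="session")
def two_sphere_volumes(two_sphere_spec):
    return make_phantom(two_sphere_spec, VOX)


@pytest.fixture(scope="session")
def head_spec():
    """Two equal 'eye' spheres plus an asymmetric 'body' ellipsoid, the
    landmark-registration workhorse."""
    return PhantomSpec(
        [
            Primitive.sphere((66, 96, 96), 14, attenuation=0.02, fluorescence=1.0,
                             label="eye_l"),
            Primitive.sphere((126, 96, 96), 14, attenuation=0.02, fluorescence=1.0,
                             label="eye_r"),
            Primitive("ellipsoid", (96, 120, 120), (40, 30, 24), attenuation=0.006,
                      fluorescence=0.3, label="body"),
        ],
        (192, 192, 192),
    )


@pytest.fixture(scope="session")
def ideal_optics():
    return OpticsParams(depth_of_field_um=np.inf, pixel_size_um=VOX, noise_sd=0.0)


@pytest.fixture(scope="session")
def defocus_optics():
    return OpticsParams(depth_of_field_um=15.0, pixel_size_um=VOX, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_spiral():
    """2 rotations x 8 angles covering the volume's depth."""
    return SpiralParams(
        n_rotations=2, angular_step_deg=45.0, frames_per_rotation=8,
        z_start_um=0.0, z_end_um=192.0,
    )
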