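import numpy as np
import pytest

from pectus.phantom import PhantomParams, make_phantom_slice


@pytest.fixture(scope="session")
def reference_params() -> PhantomParams:
    """A moderate centered depression: the worked-example phantom."""
    return PhantomParams(
        transverse_semiaxis=10.0, ap_semiaxis=6.0, dent_depth=4.0,
        dent_center_offset=0.0, dent_width=3.0, spine_radius=1.5,
        wall_thickness=1.5, pixel_spacing=1.2, image_size=256,
        noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def reference_slice(reference_params):
    return make_phantom_slice(reference_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
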