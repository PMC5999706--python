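import numpy as np
import pytest

from taupet.images import DynamicImage, LabelAtlas
from taupet.synthetic.phantom import PhantomSpec, build_atlas


@pytest.fixture(scope="session")
def default_atlas() -> LabelAtlas:
    return build_atlas()


@pytest.fixture(scope="session")
def coarse_atlas() -> LabelAtlas:
    """Same geometry on a 0.5 mm grid; cheap enough for per-test use."""
    return build_atlas((32, 40, 32), (0.5, 0.5, 0.5))


def make_dynamic(values_per_frame, schedule=None, shape=(2, 2, 2)) -> DynamicImage:
    """Spatially uniform dynamic image with given per-frame values."""
    values = np.asarray(values_per_frame, dtype=float)
    if schedule is None:
        schedule = [(5.0 * i, 5.0 * (i + 1)) for i in range(values.size)]
    schedule = np.asarray(schedule, dtype=float)
    data = np.ones(shape + (values.size,)) * values
    return DynamicImage(data, schedule[:, 0], schedule[:, 1], (1.0, 1.0, 1.0))


@pytest.fixture
def two_label_atlas() -> LabelAtlas:
    """Tiny atlas with two single-label VOIs on a 2x2x2 grid."""
    labels = np.zeros((2, 2, 2), dtype=np.int16)
    labels[0, 0, 0] = 1
    labels[1, 1, 1] = 2
    labels[0, 1, 1] = 2
    return LabelAtlas(labels, {1: "a", 2: "b"}, (1.0, 1.0, 1.0), {"both": (1, 2)})


@pytest.fixture(scope="session")
def noise_free_phantom():
    from taupet.synthetic.phantom import generate_pet_phantom

    spec = PhantomSpec.default("t807", psf_sigma_mm=0.0, noise_sd_frac=0.0)
    return generate_pet_phantom(spec)
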