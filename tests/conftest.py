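import numpy as np
import pytest

import cartiq as cq

CORONAL_AXES = {"row": "sup-inf", "col": "med-lat", "slice": "ant-post"}
SAGITTAL_AXES = {"row": "sup-inf", "col": "ant-post", "slice": "med-lat"}


def make_volume(vox, spacing=(1.0, 1.0, 1.0), plane="coronal", axes=None):
    return cq.LabelVolume(np.asarray(vox, dtype=np.int16), spacing, plane,
                          dict(axes or CORONAL_AXES))


@pytest.fixture(scope="session")
def flash_phantom():
    return cq.generate_phantom(cq.PhantomConfig(preset="flash", seed=1))


@pytest.fixture(scope="session")
def dess_phantom():
    return cq.generate_phantom(cq.PhantomConfig(preset="dess", seed=1))


@pytest.fixture(scope="session")
def flash_processed(flash_phantom):
    return cq.run_postprocessing(flash_phantom.labels, flash_phantom.meta)


@pytest.fixture(scope="session")
def dess_processed(dess_phantom):
    return cq.run_postprocessing(dess_phantom.labels, dess_phantom.meta)


def random_blob_masks(rng, shape=(16, 16, 8)):
    """Pair of random non-empty ellipsoid-union masks on a small grid."""
    out = []
    for _ in range(2):
        m = np.zeros(shape, bool)
        while not m.any():
            for _ in range(rng.integers(1, 4)):
                c = rng.integers(2, np.array(shape) - 3)
                r = rng.integers(2, 5)
                ii, jj, kk = np.ogrid[:shape[0], :shape[1], :shape[2]]
                m |= ((ii - c[0]) ** 2 + (jj - c[1]) ** 2
                      + ((kk - c[2]) * 2) ** 2) <= r * r
        out.append(m)
    return out
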