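import logging

import numpy as np
import pytest

from cavseg.phantom import CamCorruption, PhantomConfig, corrupt_cam, generate_phantom
from cavseg.volume import CAMVolume, VolumeImage

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_phantom():
    """One 32^3 phantom with two cavities, its mask and image-level class."""
    cfg = PhantomConfig(shape=(32, 32, 32), n_cavities=2,
                        cavity_radius_range=(4, 6), seed=3)
    vol, mask, cls = generate_phantom(cfg)
    return vol, mask, cls


@pytest.fixture(scope="session")
def undersegmented_cam(small_phantom):
    _, mask, _ = small_phantom
    return corrupt_cam(mask, CamCorruption(keep_fraction=0.5, blur_sigma=1.0,
                                           leak_sigma=0.02, seed=0), n_classes=2)


@pytest.fixture()
def random_cam():
    rng = np.random.default_rng(11)
    vals = rng.random((12, 12, 12, 2))
    return CAMVolume(vals)


@pytest.fixture(scope="session")
def phantom_suite(tmp_path_factory):
    """Five-case NIfTI fixture suite with manifest, 32^3 volumes."""
    from cavseg.phantom import make_fixture_suite

    out = tmp_path_factory.mktemp("suite")
    cfg = PhantomConfig(shape=(32, 32, 32), n_cavities=2, cavity_radius_range=(4, 6))
    cor = CamCorruption(keep_fraction=0.5, blur_sigma=1.0, leak_sigma=0.02)
    make_fixture_suite(5, out, seed=7, config=cfg, corruption=cor)
    return out / "manifest.json"
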