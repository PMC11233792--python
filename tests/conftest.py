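import numpy as np
import pytest

from scshsi.hsi_io import HyperspectralCube, LabelMask
from scshsi.preprocessing import PatchSet
from scshsi.synthetic import SceneSpec, generate_scene, make_spectral_library


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_scene():
    """One 64x64x30 four-class scene shared by read-only tests."""
    spec = SceneSpec(seed=7)
    library = make_spectral_library(C=4, B=30, separation=10.0, seed=7)
    cube, mask = generate_scene(spec, library)
    return cube, mask, spec, library


@pytest.fixture
def small_cube(rng):
    return HyperspectralCube(data=rng.uniform(0, 1, (8, 9, 12)),
                             band_centers=list(np.linspace(400, 900, 12)),
                             name="unit-8x9x12")


@pytest.fixture
def separable_patchset(rng):
    """Two-class 3x3x3 patches with class means ~10 noise-sigmas apart."""
    n_per = 600
    c = 10.0 / np.sqrt(2)  # ||mu1 - mu0|| = 10 sigma with sigma = 1
    means = np.array([[c, 0.0, 0.0], [0.0, 0.0, c]])
    patches = np.empty((2 * n_per, 3, 3, 3))
    labels = np.repeat([0, 1], n_per)
    for i, lab in enumerate(labels):
        patches[i] = means[lab] + rng.standard_normal((3, 3, 3))
    coords = np.zeros((2 * n_per, 2), dtype=int)
    return PatchSet(patches=patches, coords=coords, labels=labels, s=3,
                    class_names=["a", "b"])


def make_mask(labels, class_names, unlabeled=0):
    return LabelMask(labels=np.asarray(labels), class_names=class_names,
                     unlabeled_value=unlabeled)
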