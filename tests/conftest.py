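import numpy as np
import pytest

from mcthick import PhantomSpec, generate_phantom
from mcthick.segmentation import NestedLabels


def concentric_sphere_labels(shape=(48, 48, 48), radii=(10.0, 8.0, 6.0)):
    """Nested labels for concentric spheres centered on the grid."""
    axes = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    labels = np.zeros(shape, dtype=np.int8)
    labels[r < radii[0]] = 1
    labels[r < radii[1]] = 2
    labels[r < radii[2]] = 3
    return NestedLabels(labels, np.eye(4))


@pytest.fixture(scope="session")
def sphere_labels():
    return concentric_sphere_labels()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless spherical-shell phantom with exact class intensities."""
    spec = PhantomSpec(r_pial=12.0, r_gm_mgm=9.5, r_wm_inner=7.0,
                       shape=(34, 34, 34), noise_sd=0.0, seed=0)
    ratio, truth = generate_phantom(spec)
    return spec, ratio, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small phantom with 5%-of-contrast additive noise."""
    spec = PhantomSpec(r_pial=12.0, r_gm_mgm=9.5, r_wm_inner=7.0,
                       shape=(34, 34, 34), noise_sd=0.05, seed=11)
    ratio, truth = generate_phantom(spec)
    return spec, ratio, truth
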