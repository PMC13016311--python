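import numpy as np
import pytest

from fodparc import PhantomSpec, generate_phantom
from fodparc.volumes import FodVolume, LabeledVolume


def as_volumes(out):
    """PhantomOutput -> (FodVolume, LabeledVolume mask, LabeledVolume truth)."""
    fod = FodVolume(out.fod, out.affine, out.spec.sh_order)
    mask = LabeledVolume(out.mask.astype(np.int16), out.affine)
    truth = LabeledVolume(out.truth_labels.astype(np.int16), out.affine)
    return fod, mask, truth


@pytest.fixture(scope="session")
def small_phantom():
    """20^3 three-region phantom (~1.4k voxels) shared across fast tests."""
    spec = PhantomSpec(grid_shape=(20, 20, 20), n_regions=3, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_volumes(small_phantom):
    return as_volumes(small_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
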