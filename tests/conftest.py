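import numpy as np
import pytest

from qt1bbb import PhantomSpec, QT1Volume, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Label map + noiseless baseline of the default 64^3 phantom."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_spec():
    """A 32^3 phantom spec for fast volumetric tests."""
    return PhantomSpec(shape=(32, 32, 32))


def noisify(vol: QT1Volume, sd: float, rng: np.random.Generator) -> QT1Volume:
    """Multiplicative Gaussian voxel noise on a T1 volume."""
    d = np.where(vol.mask, vol.t1_map * (1 + rng.normal(0, sd, vol.t1_map.shape)), np.nan)
    return QT1Volume(d, vol.affine, vol.session, vol.mask)
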