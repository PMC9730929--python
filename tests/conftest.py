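import numpy as np
import pytest

from petmip.phantom import Ellipsoid, PhantomSpec, generate_cohort, generate_phantom
from petmip.projection import make_mip_pair
from petmip.volume_io import LesionMask3D, PetVolume


@pytest.fixture(scope="session")
def small_cohort():
    """12 reproducible phantom patients used across test modules."""
    return generate_cohort(12, seed=11)


@pytest.fixture(scope="session")
def one_case(small_cohort):
    """A multi-lesion case with its MIP pair."""
    case = next(c for c in small_cohort if len(c.spec.lesion_specs) >= 2)
    return case, make_mip_pair(case.volume, case.mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_volume(rng, shape=(16, 16, 16), spacing=(2.0, 3.0, 4.0)) -> PetVolume:
    return PetVolume(data=rng.uniform(0, 10, size=shape), spacing=spacing)


def random_mask(rng, shape=(16, 16, 16), spacing=(2.0, 3.0, 4.0), p=0.1) -> LesionMask3D:
    return LesionMask3D(data=(rng.uniform(size=shape) < p).astype(np.uint8), spacing=spacing)


def sphere_phantom(radius_mm=10.0, spacing=(2.0, 2.0, 2.0), uptake=5.0, noise=0.0):
    """Single-sphere phantom without organs, for analytic-volume checks."""
    extent = 8 * radius_mm
    shape = tuple(int(np.ceil(extent / s)) for s in spacing)
    center = tuple(n * s / 2 for n, s in zip(shape, spacing))
    spec = PhantomSpec(
        grid_shape=shape,
        spacing=spacing,
        organ_specs=[],
        lesion_specs=[Ellipsoid(center, (radius_mm,) * 3, uptake)],
        noise_sigma=noise,
        seed=0,
    )
    return generate_phantom(spec)
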