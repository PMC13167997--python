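import numpy as np
import pytest

from dualgat import CorneaGeometry, CorneaMechanics, EyeState, TearFilm


@pytest.fixture
def reference_geom() -> CorneaGeometry:
    """The zero-error reference cornea: a = 7.15 mm, h = 0.536 mm."""
    return CorneaGeometry.from_mid_surface(7.15, 0.536)


@pytest.fixture
def reference_mech() -> CorneaMechanics:
    """Reference shell material: E = 0.16 MPa, nu = 0.485."""
    return CorneaMechanics(e_mpa=0.16, nu=0.485)


@pytest.fixture
def reference_eye(reference_geom, reference_mech) -> EyeState:
    return EyeState(iopt=20.0, geom=reference_geom, mech=reference_mech,
                    tear=TearFilm.normal())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def random_eyes(rng: np.random.Generator, n: int) -> list[EyeState]:
    """Noise-free eyes sampled over the physiologic grid."""
    eyes = []
    for _ in range(n):
        eyes.append(
            EyeState(
                iopt=float(rng.uniform(5.0, 40.0)),
                geom=CorneaGeometry.from_mid_surface(
                    float(rng.uniform(6.5, 8.0)), float(rng.uniform(0.45, 0.65))
                ),
                mech=CorneaMechanics(e_mpa=float(rng.uniform(0.10, 0.35))),
            )
        )
    return eyes
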