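import numpy as np
import pytest

from phsi import SpectralAxis


@pytest.fixture(scope="session")
def axis21() -> SpectralAxis:
    """Coarse 21-band simulation axis, 470-750 nm step 14."""
    return SpectralAxis.test_scale()


@pytest.fixture(scope="session")
def axis5() -> SpectralAxis:
    """Tiny 5-band axis for fast unit tests."""
    return SpectralAxis((470.0, 540.0, 610.0, 680.0, 750.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def reference_polarizer(theta_deg: float) -> np.ndarray:
    """Textbook linear-polarizer Mueller matrix, written out independently."""
    c = np.cos(2 * np.radians(theta_deg))
    s = np.sin(2 * np.radians(theta_deg))
    return 0.5 * np.array(
        [
            [1, c, s, 0],
            [c, c * c, c * s, 0],
            [s, c * s, s * s, 0],
            [0, 0, 0, 0],
        ]
    )


def reference_retarder(theta_deg: float, delta_rad: float) -> np.ndarray:
    """Textbook linear-retarder Mueller matrix (standard sign convention)."""
    c = np.cos(2 * np.radians(theta_deg))
    s = np.sin(2 * np.radians(theta_deg))
    cd, sd = np.cos(delta_rad), np.sin(delta_rad)
    return np.array(
        [
            [1, 0, 0, 0],
            [0, c * c + s * s * cd, c * s * (1 - cd), -s * sd],
            [0, c * s * (1 - cd), s * s + c * c * cd, c * sd],
            [0, s * sd, -c * sd, cd],
        ]
    )


def random_physical_stokes(rng: np.random.Generator, n: int) -> np.ndarray:
    """n random Stokes vectors with s0 in (0, 2] and DOP in [0, 1]."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    dop = rng.uniform(0, 1, size=(n, 1))
    s0 = rng.uniform(0.1, 2.0, size=(n, 1))
    return np.concatenate([s0, s0 * dop * v], axis=1)
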