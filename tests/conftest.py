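import numpy as np
import pytest

from stereocol import EllipsoidCell, Window3D


@pytest.fixture
def cube100() -> Window3D:
    return Window3D(100.0, 100.0, 100.0)


@pytest.fixture
def cube200() -> Window3D:
    return Window3D(200.0, 200.0, 200.0)


@pytest.fixture
def prolate_cell() -> EllipsoidCell:
    """Axis-aligned (10, 5, 5) µm ellipsoid offset 2 µm in x from its nucleolus."""
    return EllipsoidCell(semi_axes=(10.0, 5.0, 5.0), center=(2.0, 0.0, 0.0),
                         nucleolus=(0.0, 0.0, 0.0))


@pytest.fixture
def ball10() -> EllipsoidCell:
    return EllipsoidCell(semi_axes=(10.0, 10.0, 10.0), center=(0.0, 0.0, 0.0))


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([
        [np.cos(a), -np.sin(a), 0.0],
        [np.sin(a), np.cos(a), 0.0],
        [0.0, 0.0, 1.0],
    ])
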