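import logging

import numpy as np
import pytest

from shpart import build_molecular_grid, make_promolecular_system

# Grid exclusions and clamped voxels are logged by design; keep test output
# readable.
logging.getLogger("shpart").setLevel(logging.ERROR)
logging.getLogger("shpart.partition").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def hf_system():
    """HF-like diatomic whose density is an exact scaled promolecule."""
    return make_promolecular_system(
        ["H", "F"], [[0.0, 0.0, 0.0], [0.0, 0.0, 1.7]], [0.9, 1.1]
    )


@pytest.fixture(scope="session")
def hf_grid(hf_system):
    """Moderate grid: accurate to ~1e-5 e, fast enough for many tests."""
    return build_molecular_grid(
        hf_system.positions, hf_system.atomic_numbers,
        n_radial=50, angular_order=11,
    )


@pytest.fixture(scope="session")
def water_like_system():
    """Bent 3-center toy (O + 2 H at ~1.8 bohr, 104 deg)."""
    r, half_angle = 1.81, np.deg2rad(52.0)
    pos = np.array([
        [0.0, 0.0, 0.0],
        [r * np.sin(half_angle), 0.0, r * np.cos(half_angle)],
        [-r * np.sin(half_angle), 0.0, r * np.cos(half_angle)],
    ])
    return make_promolecular_system(["O", "H", "H"], pos, [1.05, 0.85, 0.85])
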