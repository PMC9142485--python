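import numpy as np
import pytest

from orfi_eeg.forward import SourceGrid, build_leadfield
from orfi_eeg.montage import default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def coarse_leadfield(montage):
    """20-mm grid lead field — cheap but structurally identical to the 10-mm one."""
    from orfi_eeg.forward import default_grid

    grid10 = default_grid(spacing_mm=20.0, montage=montage)
    return build_leadfield(grid10, montage)


@pytest.fixture(scope="session")
def tiny_grid(montage):
    """A handful of interior voxels for shape/contract tests."""
    pts = np.array(
        [
            [0.0, 0.0, 40.0],
            [30.0, 0.0, 40.0],
            [-30.0, 0.0, 40.0],
            [0.0, 40.0, 40.0],
            [0.0, 0.0, 80.0],
        ]
    )
    return SourceGrid(pts, spacing_mm=10.0)
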