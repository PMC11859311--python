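import numpy as np
import pytest

from skinperm import DiffusionCellProtocol, MembraneModel


@pytest.fixture
def protocol() -> DiffusionCellProtocol:
    """Default cell: 1.77 cm², 4 mL receptor, 2 mL draws at 1..8 h."""
    return DiffusionCellProtocol()


@pytest.fixture
def membrane() -> MembraneModel:
    """A membrane with T_lag ≈ 1 min and J_ss = 100 µg/cm²/h."""
    return MembraneModel(
        partition_k=1.0, diffusivity=0.001, thickness=0.01, donor_concentration=1000.0
    )


@pytest.fixture
def lagged_membrane() -> MembraneModel:
    """A membrane with T_lag = 1.5 h, in the range typical of excised skin."""
    h = float(np.sqrt(6 * 1e-4 * 1.5))
    return MembraneModel(
        partition_k=1.0, diffusivity=1e-4, thickness=h, donor_concentration=1000.0
    )
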