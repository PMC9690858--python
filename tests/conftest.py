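import numpy as np
import pytest

from isodamage import (
    GeometryConfig,
    StoppingPowerTable,
    reference_proton_table,
)


@pytest.fixture(scope="session")
def table():
    """Packaged proton-water reference table."""
    return reference_proton_table("packaged")


@pytest.fixture(scope="session")
def analytic_table():
    return reference_proton_table("analytic")


@pytest.fixture(scope="session")
def geom():
    return GeometryConfig()


def make_constant_table(s0: float, e_min: float = 1e-9, e_max: float = 512.0):
    """Mock table with constant stopping; log-log interpolation is exact."""
    grid = np.geomspace(e_min, e_max, 64)
    return StoppingPowerTable(grid, np.full_like(grid, s0), metadata=f"const {s0}")


@pytest.fixture(scope="session")
def const_table():
    return make_constant_table(10.0)  # 10 keV/um


def euler_residual(iso, e0, path_um, table, step_um=1e-3):
    """Brute-force fixed-step integration of dE/dx = -S_ion/A.

    Independent oracle for residual_energy_after_path: explicit Euler at
    1 nm steps, stopping when the energy falls below the table floor.
    """
    from isodamage import ion_stopping

    e = float(e0)
    n = int(round(path_um / step_um))
    for _ in range(n):
        if e <= table.e_min:
            return 0.0
        s = float(ion_stopping(iso, e, table)) / 1000.0  # MeV/um
        e -= s * step_um / iso.A
    return max(e, 0.0) if e > table.e_min else 0.0
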