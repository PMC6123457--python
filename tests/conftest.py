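import pytest

from deptrap.dielectrics import DielectricMedium, DriveSignal, ShelledCell
from deptrap.field_solver import DeviceGeometry, GridSpec, solve_potential
from deptrap.pipeline import load_config


@pytest.fixture(scope="session")
def default_config():
    return load_config(None)


@pytest.fixture(scope="session")
def default_medium():
    return DielectricMedium(permittivity=7.1e-10, conductivity=1.5)


@pytest.fixture(scope="session")
def default_cell():
    return ShelledCell(
        radius=5e-6,
        membrane_thickness=5e-9,
        membrane_permittivity=1.8e-12,
        membrane_conductivity=1e-7,
        cytoplasm_permittivity=7.1e-10,
        cytoplasm_conductivity=0.75,
    )


@pytest.fixture(scope="session")
def coarse_field():
    """Ring-trap field on a 2 um grid: fast, topology-faithful."""
    return solve_potential(
        DeviceGeometry(), DriveSignal(vpp=8.0, frequency=1e7), GridSpec(spacing=2e-6)
    )
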