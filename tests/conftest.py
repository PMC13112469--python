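import numpy as np
import pytest

from pgalbind.molecules import (
    Atom,
    Molecule,
    assign_charges_radii,
    default_charge_table,
)
from pgalbind.structures import build_histidine, build_pgal_oligomer


@pytest.fixture(scope="session")
def charge_table():
    return default_charge_table()


@pytest.fixture(scope="session")
def pgal9(charge_table):
    return assign_charges_radii(build_pgal_oligomer(9), charge_table)


@pytest.fixture(scope="session")
def pgal3(charge_table):
    """Small oligomer for tests where the nonamer would be needlessly slow."""
    return assign_charges_radii(build_pgal_oligomer(3), charge_table)


@pytest.fixture(scope="session")
def his_zwitterion(charge_table):
    return assign_charges_radii(build_histidine("zwitterionic"), charge_table)


@pytest.fixture(scope="session")
def his_protonated(charge_table):
    return assign_charges_radii(build_histidine("protonated"), charge_table)


def make_ion(charge=1.0, radius=2.0, position=(0.0, 0.0, 0.0), name="X"):
    return Molecule(
        f"ion_{name}",
        [Atom(name, "C", np.asarray(position, float), charge=charge, radius=radius)],
    )


@pytest.fixture
def born_ion():
    return make_ion()
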