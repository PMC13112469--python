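import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pgalbind.constants import COULOMB_KJ_MOL_ANG
from pgalbind.molecules import Atom, Molecule
from pgalbind.pb import (
    DielectricModel,
    ElecComponents,
    GridSpec,
    coulomb_energy,
    elec_binding_components,
    inter_coulomb,
    solvation_energy,
    solve_poisson,
)

from conftest import make_ion

KE = COULOMB_KJ_MOL_ANG


def born(a, eps_in, eps_out, q=1.0):
    return -KE * q * q / (2.0 * a) * (1.0 / eps_in - 1.0 / eps_out)


def test_gridspec_invariants():
    with pytest.raises(ValueError):
        GridSpec((0, 0, 0), 0.0, (33, 33, 33))
    with pytest.raises(ValueError):
        GridSpec((0, 0, 0), 0.5, (16, 33, 33))
    with pytest.raises(ValueError):
        GridSpec((0, 0, 0), 0.5, (33, 33, 33), padding=2.0)


def test_dielectric_model_ordering():
    with pytest.raises(ValueError):
        DielectricModel(eps_solvent=3.0, eps_solute=78.0)
    assert DielectricModel().kappa == 0.0
    assert DielectricModel(ionic_strength=0.15).kappa == pytest.approx(
        1.0 / 7.83, rel=0.02)  # physiological Debye length ~7.8 Å


def test_zero_charge_molecule_zero_potential(born_ion):
    mol = make_ion(charge=0.0)
    grid = GridSpec.for_molecule(mol, 0.5)
    res = solve_poisson(mol, grid, DielectricModel(), eps_out=78.0)
    assert res.converged
    np.testing.assert_allclose(res.potential, 0.0, atol=1e-12)
    assert res.grid_energy == 0.0


def test_homogeneous_medium_zero_solvation(born_ion):
    diel = DielectricModel(78.0, 3.0)
    grid = GridSpec.for_molecule(born_ion, 0.5)
    # differencing two identical eps_out runs must cancel exactly
    e = (solve_poisson(born_ion, grid, diel, eps_out=3.0).grid_energy
         - solve_poisson(born_ion, grid, diel, eps_out=3.0).grid_energy)
    assert e == 0.0


def test_born_ion_moderate_grid(born_ion):
    """eps 3 -> 78 generalized Born value at an unfocused 0.4 Å grid."""
    diel = DielectricModel(78.0, 3.0)
    grid = GridSpec.for_molecule(born_ion, 0.4, padding=6.0)
    e = solvation_energy(born_ion, grid, diel)
    assert e == pytest.approx(born(2.0, 3.0, 78.0), rel=0.05)


def test_grid_halving_error_decreases(born_ion):
    diel = DielectricModel(78.0, 3.0)
    exact = born(2.0, 3.0, 78.0)
    errs = []
    for h in (1.0, 0.5, 0.25):
        grid = GridSpec.for_molecule(born_ion, h, padding=6.0)
        errs.append(abs(solvation_energy(born_ion, grid, diel) - exact))
    assert errs[0] > errs[1] > errs[2]


def test_superposition_in_homogeneous_medium():
    """Linearity: potential of two charges = sum of single-charge solves."""
    diel = DielectricModel(78.0, 1.0)
    a = make_ion(1.0, 1.5, (-2.0, 0.0, 0.0), "A")
    b = make_ion(1.0, 1.5, (2.0, 0.0, 0.0), "B")
    pair = a.merged_with(b)
    grid = GridSpec.for_molecule(pair, 0.5)
    # homogeneous: eps_out equals the solute dielectric everywhere
    phi_pair = solve_poisson(pair, grid, diel, eps_out=1.0).potential
    phi_a = solve_poisson(a, grid, diel, eps_out=1.0).potential
    phi_b = solve_poisson(b, grid, diel, eps_out=1.0).potential
    scale = np.abs(phi_pair).max()
    np.testing.assert_allclose(phi_pair, phi_a + phi_b, atol=1e-6 * scale)


@pytest.mark.parametrize("eps,expected", [
    (1.0, KE),          # two +1 e at 1 Å in vacuum: +1389.35 kJ/mol
    (3.0, KE / 3.0),    # +463.12 kJ/mol
])
def test_coulomb_closed_form(eps, expected):
    pair = Molecule("pair", [
        Atom("A", "C", [0.0, 0.0, 0.0], charge=1.0, radius=1.0),
        Atom("B", "C", [1.0, 0.0, 0.0], charge=1.0, radius=1.0),
    ])
    assert coulomb_energy(pair, eps) == pytest.approx(expected, rel=1e-12)


def test_coulomb_single_atom_zero():
    assert coulomb_energy(make_ion(), eps=1.0) == 0.0


def test_coulomb_coincident_charges_singularity():
    bad_a = make_ion(1.0, 1.0, (0, 0, 0), "A")
    bad_b = make_ion(1.0, 1.0, (0, 0, 0), "B")
    with pytest.raises(ZeroDivisionError):
        inter_coulomb(bad_a, bad_b, eps=1.0)


def test_opposite_charges_at_5A_closed_form():
    a = make_ion(+1.0, 2.0, (0.0, 0.0, 0.0), "A")
    b = make_ion(-1.0, 2.0, (5.0, 0.0, 0.0), "B")
    assert inter_coulomb(a, b, eps=1.0) == pytest.approx(-KE / 5.0, rel=1e-12)
    assert inter_coulomb(a, b, eps=1.0) == pytest.approx(-277.87, abs=0.01)


def test_opposite_contact_pair_has_desolvation_penalty():
    """dG_solv of binding > 0 for an oppositely charged contact pair."""
    a = make_ion(+1.0, 2.0, (0.0, 0.0, 0.0), "A")
    b = make_ion(-1.0, 2.0, (5.0, 0.0, 0.0), "B")
    diel = DielectricModel(78.0, 3.0)
    comp = elec_binding_components(a, b, diel, spacing=0.5)
    assert comp.dG_solv > 0.0
    assert comp.dG_coul == pytest.approx(-KE / (3.0 * 5.0), rel=1e-12)
    # screened-interaction closed form: k_e q1 q2 (1/78 - 1/3) / r
    expected = KE * (-1.0) * (1.0 / 78.0 - 1.0 / 3.0) / 5.0
    assert comp.dG_solv == pytest.approx(expected, rel=0.15)


def test_noninteracting_limit_components_vanish(charge_table):
    from pgalbind.molecules import assign_charges_radii
    from pgalbind.structures import build_gallic_unit, build_histidine

    rec = assign_charges_radii(build_gallic_unit(), charge_table)
    lig = assign_charges_radii(build_histidine("zwitterionic"), charge_table)
    far = lig.transformed(np.eye(3), np.array([60.0, 0.0, 0.0]))
    comp = elec_binding_components(rec, far, DielectricModel(), spacing=2.0)
    assert abs(comp.dG_coul) < 0.5
    assert abs(comp.dG_solv) < 0.5


def test_receptor_ligand_swap_symmetry():
    a = make_ion(+1.0, 2.0, (0.0, 0.0, 0.0), "A")
    b = make_ion(-0.5, 1.5, (4.5, 0.0, 0.0), "B")
    diel = DielectricModel(78.0, 3.0)
    ab = elec_binding_components(a, b, diel, spacing=0.6)
    ba = elec_binding_components(b, a, diel, spacing=0.6)
    assert ab.dG_coul == pytest.approx(ba.dG_coul, rel=1e-10)
    assert ab.dG_solv == pytest.approx(ba.dG_solv, rel=1e-6, abs=1e-6)


def test_energies_invariant_under_lattice_rigid_motion(charge_table):
    """A 90° rotation plus a translation maps the discretization onto itself."""
    from pgalbind.molecules import assign_charges_radii
    from pgalbind.structures import build_gallic_unit

    mol = assign_charges_radii(build_gallic_unit(), charge_table)
    diel = DielectricModel(78.0, 3.0)
    e1 = solvation_energy(mol, GridSpec.for_molecule(mol, 0.6), diel)
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = mol.transformed(R, np.array([7.0, -3.0, 11.0]))
    e2 = solvation_energy(moved, GridSpec.for_molecule(moved, 0.6), diel)
    assert e2 == pytest.approx(e1, rel=1e-4)


def test_elec_components_must_be_finite():
    with pytest.raises(ValueError):
        ElecComponents(np.inf, 0.0)
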