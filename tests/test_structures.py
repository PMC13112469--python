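import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from pgalbind.molecules import assign_charges_radii
from pgalbind.sasa import sasa
from pgalbind.structures import (
    ComplexPose,
    SamplingExhaustedError,
    build_gallic_unit,
    build_histidine,
    build_pgal_oligomer,
    sample_poses,
)


def test_gallic_unit_oxygens_hbond_capable(charge_table):
    unit = assign_charges_radii(build_gallic_unit(), charge_table)
    capable = [a for a in unit.atoms
               if a.element == "O" and a.hbond_role in ("donor", "acceptor", "both")]
    assert len(capable) >= 4
    assert abs(unit.charges.sum()) < 1e-6  # fully protonated, net 0


def test_gallic_unit_deterministic():
    a, b = build_gallic_unit(), build_gallic_unit()
    np.testing.assert_array_equal(a.coords, b.coords)


def test_oligomer_atom_count_and_sanity():
    unit = build_gallic_unit()
    nonamer = build_pgal_oligomer(9)
    assert len(nonamer) == 9 * len(unit)
    assert pdist(nonamer.coords).min() >= 0.7
    assert nonamer.protonation_label == "fully_protonated_polymer"


def test_oligomer_n1_is_the_unit():
    np.testing.assert_allclose(build_pgal_oligomer(1).coords,
                               build_gallic_unit().coords, atol=1e-12)


def test_oligomer_requires_positive_units():
    with pytest.raises(ValueError):
        build_pgal_oligomer(0)


def test_dimer_buries_interface_area(charge_table):
    one = assign_charges_radii(build_pgal_oligomer(1), charge_table)
    two = assign_charges_radii(build_pgal_oligomer(2), charge_table)
    assert sasa(two).total < 2.0 * sasa(one).total


def test_histidine_states_share_heavy_skeleton():
    z = build_histidine("zwitterionic")
    p = build_histidine("protonated")
    assert len(p) == len(z) + 1  # extra ring proton
    heavy_z = {a.name for a in z.atoms if not a.is_hydrogen}
    heavy_p = {a.name for a in p.atoms if not a.is_hydrogen}
    assert heavy_z == heavy_p


def test_histidine_ring_nitrogen_roles(charge_table):
    z = assign_charges_radii(build_histidine("zwitterionic"), charge_table)
    p = assign_charges_radii(build_histidine("protonated"), charge_table)
    roles_z = {a.name: a.hbond_role for a in z.atoms}
    roles_p = {a.name: a.hbond_role for a in p.atoms}
    assert roles_z["ND1"] == "acceptor" and roles_z["NE2"] == "donor"
    assert roles_p["ND1"] == "donor" and roles_p["NE2"] == "donor"


def test_unknown_state_rejected():
    with pytest.raises(ValueError, match="unknown"):
        build_histidine("anionic")


@pytest.mark.parametrize("seed", [0, 7, 123])
def test_sampled_poses_respect_clash_and_contact_shell(pgal3, his_zwitterion, seed):
    ps = sample_poses(pgal3, his_zwitterion, n_poses=8, replicates=2, seed=seed)
    assert len(ps) == 16
    for pose in ps.poses:
        d = ps.min_distance(pose)
        assert ps.clash_min <= d <= ps.contact_max


def test_pose_sampling_seeded_determinism(pgal3, his_zwitterion):
    a = sample_poses(pgal3, his_zwitterion, 5, 2, seed=11)
    b = sample_poses(pgal3, his_zwitterion, 5, 2, seed=11)
    for pa, pb in zip(a.poses, b.poses):
        np.testing.assert_array_equal(pa.rotation, pb.rotation)
        np.testing.assert_array_equal(pa.translation, pb.translation)


def test_triplicate_campaign_size(pgal3, his_protonated):
    ps = sample_poses(pgal3, his_protonated, n_poses=50, replicates=3, seed=7)
    assert len(ps) == 150


def test_impossible_constraint_errors(pgal3, his_zwitterion):
    with pytest.raises(ValueError):
        sample_poses(pgal3, his_zwitterion, 1, 1, seed=0, clash_min=50.0)
    with pytest.raises(SamplingExhaustedError, match="attempts"):
        sample_poses(pgal3, his_zwitterion, 1, 1, seed=0,
                     clash_min=4.4999, contact_max=4.5, max_attempts=1)


def test_orientation_sampling_is_rotation_uniform():
    """Mean of sampled rotation matrices tends to zero (3 sigma at n=10000)."""
    rng = np.random.default_rng(2024)
    n = 10_000
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    mats = Rotation.from_quat(q, scalar_first=True).as_matrix()
    mean = mats.mean(axis=0)
    # each matrix entry has mean 0, variance 1/3 under the uniform measure
    assert np.all(np.abs(mean) < 3.0 * np.sqrt(1.0 / 3.0 / n))


def test_pose_versor_norm_enforced():
    with pytest.raises(ValueError, match="unit norm"):
        ComplexPose(0, np.array([1.0, 1.0, 0.0, 0.0]), np.zeros(3), 0)


def test_pose_transform_is_rigid(his_zwitterion):
    q = np.array([0.5, 0.5, 0.5, 0.5])
    pose = ComplexPose(0, q, np.array([10.0, -3.0, 2.0]), 0)
    posed = pose.apply(his_zwitterion)
    np.testing.assert_allclose(pdist(posed.coords), pdist(his_zwitterion.coords),
                               atol=1e-9)
    np.testing.assert_allclose(posed.coords.mean(axis=0), [10.0, -3.0, 2.0],
                               atol=1e-9)


def test_transform_table_round_trip(tmp_path, pgal3, his_zwitterion):
    ps = sample_poses(pgal3, his_zwitterion, 3, 1, seed=5)
    path = tmp_path / "transforms.tsv"
    ps.write_transforms(path)
    rows = path.read_text().strip().splitlines()
    assert rows[0].startswith("pose_id")
    assert len(rows) == 1 + len(ps)
    vals = rows[1].split("\t")
    np.testing.assert_allclose([float(v) for v in vals[2:6]],
                               ps.poses[0].rotation, atol=1e-9)
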