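"""Synthetic structural inputs: PGAL oligomer, histidine, rigid-body poses.

The experimental complexes behind the binding-energy decomposition are not
deposited anywhere, so this module generates idealized stand-ins:

* a planar gallic-acid unit and a helical fully protonated oligomer built by
  stacking units with a fixed rise and twist (the polymer is reported to adopt
  a stable helical structure);
* L-histidine in its two physiological protonation states — the zwitterion
  (NH3+/COO-, neutral imidazole, net 0) and the imidazolium-protonated cation
  (net +1) — sharing one heavy-atom skeleton;
* seeded rigid-body complex poses in a contact shell around the receptor,
  emulating a docking campaign of >= 50 poses in triplicate.

All geometry is idealized (fixed bond lengths and angles); every quantity the
pipeline derives from it is validated against closed-form oracles, not against
the unpublished quantum-chemically optimized structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .molecules import Atom, Molecule, MoleculeError

__all__ = [
    "ComplexPose",
    "PoseSet",
    "SamplingExhaustedError",
    "build_gallic_unit",
    "build_pgal_oligomer",
    "build_histidine",
    "sample_poses",
]

# helical stacking of gallic units, Å / degrees
HELIX_RISE = 3.5
HELIX_TWIST_DEG = 40.0

RING_RADIUS = 1.395        # benzene C-C 1.395 Å hexagon
C_CARBOXYL = 1.48
C_O_DOUBLE = 1.23
C_O_SINGLE = 1.36
O_H = 0.97
PENTAGON_BOND = 1.37
PENTAGON_RADIUS = PENTAGON_BOND / (2.0 * math.sin(math.pi / 5.0))

DEFAULT_CLASH_MIN = 2.2    # Å, minimum inter-molecular approach
DEFAULT_CONTACT_MAX = 4.5  # Å, contact-shell outer bound
DEFAULT_MAX_ATTEMPTS = 10_000


class SamplingExhaustedError(RuntimeError):
    """No clash-free in-shell pose found within the attempt budget."""


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def build_gallic_unit() -> Molecule:
    """One idealized planar gallic-acid unit (net charge 0, fully protonated).

    Benzene ring in the xy-plane with a carboxyl group at C1 and hydroxyls at
    C3/C4/C5; carbonyl oxygen is an acceptor, all OH oxygens donor+acceptor.
    Nonpolar ring hydrogens are folded into the carbon radii.
    """
    def ring_pos(k: int, r: float = RING_RADIUS) -> np.ndarray:
        a = math.radians(60.0 * k)
        return np.array([r * math.cos(a), r * math.sin(a), 0.0])

    def planar(angle_deg: float, dist: float) -> np.ndarray:
        a = math.radians(angle_deg)
        return np.array([dist * math.cos(a), dist * math.sin(a), 0.0])

    atoms = [Atom(f"C{k + 1}", "C", ring_pos(k), res_name="GAL") for k in range(6)]
    # carboxyl on C1 (radial angle 0 deg)
    c7 = ring_pos(0) + planar(0.0, C_CARBOXYL)
    atoms.append(Atom("C7", "C", c7, res_name="GAL"))
    atoms.append(Atom("O1", "O", c7 + planar(55.0, C_O_DOUBLE), res_name="GAL"))
    o2 = c7 + planar(-55.0, C_O_SINGLE)
    atoms.append(Atom("O2", "O", o2, res_name="GAL"))
    atoms.append(Atom("HO2", "H", o2 + planar(0.0, O_H), res_name="GAL"))
    # ring hydroxyls on C3 (120 deg), C4 (180 deg), C5 (240 deg)
    for idx, ang in ((3, 120.0), (4, 180.0), (5, 240.0)):
        o = ring_pos(idx - 1) + planar(ang, C_O_SINGLE)
        atoms.append(Atom(f"O{idx}", "O", o, res_name="GAL"))
        atoms.append(Atom(f"HO{idx}", "H", o + planar(ang + 65.0, O_H), res_name="GAL"))
    mol = Molecule("GAL", atoms, net_charge=0, protonation_label="other")
    mol.validate(check_charge=False)
    return mol


def build_pgal_oligomer(n_units: int) -> Molecule:
    """Stack *n_units* gallic units on an idealized helix (rise 3.5 Å,
    twist 40°/unit); net charge 0, fully protonated."""
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    unit = build_gallic_unit()
    atoms: list[Atom] = []
    for k in range(n_units):
        rot = Rotation.from_euler("z", k * HELIX_TWIST_DEG, degrees=True).as_matrix()
        shift = np.array([0.0, 0.0, k * HELIX_RISE])
        for a in unit.atoms:
            atoms.append(Atom(a.name, a.element, rot @ a.position + shift,
                              res_name="GAL", res_seq=k + 1))
    mol = Molecule(f"PGAL{n_units}", atoms, net_charge=0,
                   protonation_label="fully_protonated_polymer")
    mol.validate(check_charge=False)
    return mol


def build_histidine(state: str) -> Molecule:
    """Idealized L-histidine.

    ``state='zwitterionic'``: NH3+ / COO-, neutral imidazole (NE2-H donor,
    ND1 acceptor), net 0.  ``state='protonated'``: additionally carries HD1 on
    the imidazolium ring (both ring nitrogens donors), net +1.  Both states
    share the same heavy-atom skeleton.
    """
    if state not in ("protonated", "zwitterionic"):
        raise ValueError(f"unknown protonation state {state!r}")
    res = "HIP" if state == "protonated" else "HIE"

    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = np.array([2.010, 1.400, 0.0])
    O = np.array([1.150, 2.350, 0.0])
    OXT = np.array([3.250, 1.750, 0.0])
    H1 = np.array([-0.333, 0.943, 0.0])
    H2 = np.array([-0.333, -0.471, 0.816])
    H3 = np.array([-0.333, -0.471, -0.816])
    CB = CA + np.array([0.540, -0.780, 1.210])
    u = _unit(np.array([0.10, -0.62, 0.78]))
    CG = CB + 1.50 * u

    # imidazole: planar pentagon with CG a vertex, extending away from CB
    a1 = _unit(CG - CB)
    a2 = _unit(np.cross(a1, np.array([0.0, 0.0, 1.0])))
    center = CG + PENTAGON_RADIUS * a1
    ring = {}
    for k, name in enumerate(["CG", "ND1", "CE1", "NE2", "CD2"]):
        ang = math.radians(180.0 - 72.0 * k)
        ring[name] = center + PENTAGON_RADIUS * (math.cos(ang) * a1 + math.sin(ang) * a2)
    HD1 = ring["ND1"] + 1.01 * _unit(ring["ND1"] - center)
    HE2 = ring["NE2"] + 1.01 * _unit(ring["NE2"] - center)

    coords = {"N": N, "H1": H1, "H2": H2, "H3": H3, "CA": CA, "C": C, "O": O,
              "OXT": OXT, "CB": CB, "CG": ring["CG"], "ND1": ring["ND1"],
              "CE1": ring["CE1"], "NE2": ring["NE2"], "HE2": HE2, "CD2": ring["CD2"]}
    if state == "protonated":
        coords["HD1"] = HD1
    atoms = [Atom(n, ("H" if n.startswith("H") else n[0]), p, res_name=res)
             for n, p in coords.items()]
    mol = Molecule(f"HIS_{state}", atoms,
                   net_charge=1 if state == "protonated" else 0,
                   protonation_label=state)
    mol.validate(check_charge=False)
    return mol


@dataclass(frozen=True)
class ComplexPose:
    """Rigid-body placement of the ligand: x -> R(versor) (x - centroid) + t."""

    pose_id: int
    rotation: np.ndarray   # unit quaternion, scalar-first (w, x, y, z)
    translation: np.ndarray  # new ligand-centroid position, Å
    replicate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        if abs(np.linalg.norm(self.rotation) - 1.0) > 1e-9:
            raise ValueError("pose rotation versor must have unit norm")

    def matrix(self) -> np.ndarray:
        return Rotation.from_quat(self.rotation, scalar_first=True).as_matrix()

    def apply(self, ligand: Molecule) -> Molecule:
        centroid = ligand.coords.mean(axis=0)
        R = self.matrix()
        posed = ligand.transformed(R, self.translation - R @ centroid)
        posed.id = f"{ligand.id}_pose{self.pose_id}r{self.replicate}"
        return posed


@dataclass
class PoseSet:
    """A seeded ensemble of rigid-body complex poses."""

    receptor: Molecule
    ligand: Molecule
    poses: list[ComplexPose]
    seed: int
    replicates: int
    clash_min: float = DEFAULT_CLASH_MIN
    contact_max: float = DEFAULT_CONTACT_MAX

    def __len__(self) -> int:
        return len(self.poses)

    def posed_ligand(self, pose: ComplexPose) -> Molecule:
        return pose.apply(self.ligand)

    def min_distance(self, pose: ComplexPose) -> float:
        """Closest inter-molecular atom-center approach, Å."""
        return float(cdist(self.receptor.coords, self.posed_ligand(pose).coords).min())

    def write_transforms(self, path: str | Path) -> None:
        lines = ["pose_id\treplicate\tqw\tqx\tqy\tqz\ttx\tty\ttz"]
        for p in self.poses:
            q, t = p.rotation, p.translation
            lines.append(
                f"{p.pose_id}\t{p.replicate}\t"
                + "\t".join(f"{v:.9f}" for v in (*q, *t))
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_models(self, path: str | Path) -> None:
        """Multi-model PDB of the posed complexes."""
        from .molecules import write_pdb  # noqa: F401  (formatting helper below)

        blocks = []
        for m, pose in enumerate(self.poses, start=1):
            complex_mol = self.receptor.merged_with(self.posed_ligand(pose))
            body = []
            for i, a in enumerate(complex_mol.atoms, start=1):
                body.append(
                    f"ATOM  {i:5d} {a.name:<4.4s}{a.res_name:>4.3s}  {a.res_seq:4d}    "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
                )
            blocks.append(f"MODEL     {m:4d}\n" + "\n".join(body) + "\nENDMDL")
        Path(path).write_text("\n".join(blocks) + "\nEND\n")


def _random_versor(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def sample_poses(
    receptor: Molecule,
    ligand: Molecule,
    n_poses: int,
    replicates: int = 3,
    seed: int = 0,
    clash_min: float = DEFAULT_CLASH_MIN,
    contact_max: float = DEFAULT_CONTACT_MAX,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> PoseSet:
    """Seeded rigid-body pose sampling in a contact shell.

    Each pose draws a uniform random orientation (normalized 4-normal versor)
    and a surface-biased translation: the ligand is slid along a random ray
    anchored at a random receptor atom until its closest atom-center approach
    to the receptor falls in ``[clash_min, contact_max]``.  Replicate ``r``
    uses seed ``seed + r``, mirroring a triplicated docking campaign.
    """
    if n_poses < 1 or replicates < 1:
        raise ValueError("n_poses and replicates must be >= 1")
    if clash_min <= 0 or contact_max <= clash_min:
        raise ValueError("require 0 < clash_min < contact_max")

    rec = receptor.coords
    lig = ligand.coords
    lig_centered = lig - lig.mean(axis=0)
    diam = np.ptp(rec, axis=0).max() + np.ptp(lig, axis=0).max() + 10.0
    t_grid = np.linspace(-diam, diam, 641)

    poses: list[ComplexPose] = []
    for rep in range(replicates):
        rng = np.random.default_rng(seed + rep)
        for pid in range(n_poses):
            placed = False
            for attempt in range(max_attempts):
                q = _random_versor(rng)
                R = Rotation.from_quat(q, scalar_first=True).as_matrix()
                B = lig_centered @ R.T
                p = rec[rng.integers(len(rec))]
                u = _unit(rng.normal(size=3))
                # pair separations as a function of slide distance t:
                # |a_i - (b_j + p + t u)|^2 = perp2_ij + (proj_ij - t)^2
                w = (rec[:, None, :] - B[None, :, :]).reshape(-1, 3) - p
                proj = w @ u
                perp2 = np.einsum("ij,ij->i", w, w) - proj**2
                d2 = perp2[:, None] + (proj[:, None] - t_grid[None, :]) ** 2
                fmin = np.sqrt(d2.min(axis=0))
                ok = np.flatnonzero((fmin >= clash_min) & (fmin <= contact_max))
                if ok.size:
                    t = t_grid[ok[rng.integers(ok.size)]]
                    poses.append(ComplexPose(pid, q, p + t * u, rep))
                    placed = True
                    break
            if not placed:
                raise SamplingExhaustedError(
                    f"pose {pid} replicate {rep}: no clash-free pose in "
                    f"[{clash_min}, {contact_max}] Å after {max_attempts} attempts"
                )
    return PoseSet(receptor, ligand, poses, seed, replicates, clash_min, contact_max)
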