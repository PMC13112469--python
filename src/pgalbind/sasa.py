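"""Shrake-Rupley solvent-accessible surface area and the non-polar term.

Per-atom accessible area is computed by spherical point quadrature on the
probe-expanded sphere, testing each quadrature point against all neighboring
expanded spheres.  The point set is a deterministic golden-spiral lattice
applied in a canonical molecular frame, so SASA is bit-reproducible and
invariant under rigid motion (the point set effectively moves with the
molecule).

The hydrophobic binding contribution is gamma * (SASA of complex - SASA of
receptor - SASA of ligand), with gamma in cal mol^-1 Å^-2 converted to kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import cdist

from .constants import CAL_TO_KJ, DEFAULT_GAMMA_CAL, DEFAULT_PROBE_RADIUS
from .molecules import Molecule, MoleculeError

__all__ = ["SasaResult", "sasa", "delta_sasa", "nonpolar_energy", "sphere_points"]


@lru_cache(maxsize=8)
def _sphere_points_cached(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    # golden-spiral lattice: quasi-uniform, deterministic
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one quadrature point")
    return _sphere_points_cached(int(n))


def _canonical_coords(xyz: np.ndarray) -> np.ndarray:
    """Express coordinates in a canonical molecular frame.

    Axes are the principal axes of the centered coordinate cloud, with signs
    fixed by the third moment of the projections (falling back to the first
    off-axis atom), and a right-handed third axis.  Rigid motions of the
    molecule then leave the returned coordinates unchanged (up to eigensolver
    roundoff), which makes SASA invariant under rigid motion.  Clouds with
    degenerate principal moments (e.g. perfectly spherical arrangements) have
    no unique frame; for such inputs invariance is only approximate.
    """
    center = xyz.mean(axis=0)
    p = xyz - center
    if len(p) == 1:
        return p
    cov = p.T @ p
    _, vecs = np.linalg.eigh(cov)
    axes = []
    for k in (2, 1):  # largest two principal axes
        v = vecs[:, k]
        proj = p @ v
        s = float((proj**3).sum())
        if abs(s) < 1e-8:
            nz = proj[np.abs(proj) > 1e-8]
            s = float(nz[0]) if nz.size else 1.0
        axes.append(v if s > 0 else -v)
    axes.append(np.cross(axes[0], axes[1]))
    return p @ np.column_stack(axes)


@dataclass(frozen=True)
class SasaResult:
    """Total and per-atom solvent-accessible surface area, Å²."""

    total: float
    per_atom: np.ndarray
    probe_radius: float
    n_points: int


def sasa(mol: Molecule, probe: float = DEFAULT_PROBE_RADIUS,
         n_points: int = 960) -> SasaResult:
    """Shrake-Rupley SASA of *mol* with the given probe radius.

    Neighbors are culled at center distance r_i + r_j + 2*probe; each atom's
    quadrature points are tested against its neighbors' expanded spheres only.
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    radii = mol.radii
    if np.any(radii <= 0):
        raise MoleculeError(
            f"molecule {mol.id}: SASA requires positive radii on all atoms"
        )
    xyz = _canonical_coords(mol.coords)
    n = len(mol)
    expanded = radii + probe
    pts = sphere_points(n_points)

    dist = cdist(xyz, xyz)
    cutoff = radii[:, None] + radii[None, :] + 2.0 * probe
    np.fill_diagonal(dist, np.inf)
    neighbor_lists = [np.flatnonzero(dist[i] < cutoff[i]) for i in range(n)]

    per_atom = np.empty(n)
    for i in range(n):
        surf = xyz[i] + expanded[i] * pts
        nbrs = neighbor_lists[i]
        if nbrs.size:
            d2 = cdist(surf, xyz[nbrs], metric="sqeuclidean")
            buried = (d2 < (expanded[nbrs] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return SasaResult(float(per_atom.sum()), per_atom, probe, n_points)


def delta_sasa(receptor: Molecule, posed_ligand: Molecule,
               probe: float = DEFAULT_PROBE_RADIUS, n_points: int = 960) -> float:
    """Buried area on binding: SASA(complex) - SASA(receptor) - SASA(ligand).

    Non-positive for any contacting pose; tends to 0 for separated species.
    """
    complex_mol = receptor.merged_with(posed_ligand)
    return (
        sasa(complex_mol, probe, n_points).total
        - sasa(receptor, probe, n_points).total
        - sasa(posed_ligand, probe, n_points).total
    )


def nonpolar_energy(delta_area: float, gamma: float = DEFAULT_GAMMA_CAL) -> float:
    """gamma * delta_area with gamma in cal mol^-1 Å^-2, returned in kJ/mol."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return gamma * delta_area * CAL_TO_KJ
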