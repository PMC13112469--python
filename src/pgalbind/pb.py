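"""Finite-difference Poisson electrostatics for implicit-solvent binding.

The electrostatic part of the binding free energy is split into a solvation
term and a Coulomb term.  Solvation energies come from a two-dielectric
Poisson model: the solute interior (union of atom spheres) has a low
dielectric (default 3.0, the polyimide/polypropylene range appropriate for
the polyphenolic solute) and the exterior has the solvent dielectric
(default 78, water).  The equation

    div( eps(r) grad phi ) = -4 pi k_e rho

is discretized on a regular grid with a 7-point stencil, harmonic averaging
of the node dielectric on edges, trilinear charge assignment, and analytic
Coulomb/Debye-Hückel Dirichlet values on the box faces.  The SPD interior
system is solved by Jacobi-preconditioned conjugate gradients, optionally in
a two-level focusing pass (coarse box -> fine box boundary conditions).

The grid "self-energy" of the point charges is removed strictly by
same-grid differencing: the solvation energy is the charge-potential energy
with solvent outside minus the identical calculation with the solute
dielectric outside (a homogeneous reference), never by analytic subtraction.
Units: Å, elementary charges, kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.constants as sc
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist, pdist

from .constants import (
    COULOMB_KJ_MOL_ANG,
    DEFAULT_EPS_SOLUTE,
    DEFAULT_EPS_SOLVENT,
    TEMPERATURE_K,
)
from .molecules import Molecule, MoleculeError

__all__ = [
    "GridSpec",
    "DielectricModel",
    "PBResult",
    "ElecComponents",
    "NonConvergedError",
    "solve_poisson",
    "solvation_energy",
    "coulomb_energy",
    "inter_coulomb",
    "elec_binding_components",
    "write_dx",
]

MIN_DIM = 33
MIN_PADDING = 5.0


class NonConvergedError(RuntimeError):
    """Poisson solve did not reach the residual tolerance."""


@dataclass(frozen=True)
class GridSpec:
    """Regular finite-difference grid: origin (Å), spacing (Å), node counts."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]
    padding: float = MIN_PADDING

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < MIN_DIM for d in self.dims):
            raise ValueError(f"grid dims must be >= {MIN_DIM} per axis")
        if self.padding < MIN_PADDING:
            raise ValueError(f"grid padding must be >= {MIN_PADDING} Å")

    @classmethod
    def for_molecule(cls, mol: Molecule, spacing: float,
                     padding: float = MIN_PADDING) -> "GridSpec":
        """Smallest grid (>=33 nodes/axis) enclosing atom spheres + padding."""
        xyz, r = mol.coords, mol.radii
        lo = (xyz - r[:, None]).min(axis=0) - padding
        hi = (xyz + r[:, None]).max(axis=0) + padding
        dims, origin = [], []
        for a in range(3):
            n = max(MIN_DIM, int(np.ceil((hi[a] - lo[a]) / spacing)) + 1)
            extra = ((n - 1) * spacing - (hi[a] - lo[a])) / 2.0
            dims.append(n)
            origin.append(lo[a] - extra)
        return cls(tuple(origin), spacing, tuple(dims), padding)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o, h = self.origin, self.spacing
        return tuple(o[a] + h * np.arange(self.dims[a]) for a in range(3))

    def encloses(self, mol: Molecule, margin: float = 0.0) -> bool:
        xyz = mol.coords
        lo = np.array(self.origin) + margin
        hi = np.array(self.origin) + self.spacing * (np.array(self.dims) - 1) - margin
        return bool(np.all(xyz >= lo) and np.all(xyz <= hi))


@dataclass(frozen=True)
class DielectricModel:
    """Two-dielectric implicit-solvent model (zero salt by default)."""

    eps_solvent: float = DEFAULT_EPS_SOLVENT
    eps_solute: float = DEFAULT_EPS_SOLUTE
    temperature: float = TEMPERATURE_K
    ionic_strength: float = 0.0  # mol/L

    def __post_init__(self) -> None:
        if not self.eps_solvent > self.eps_solute >= 1.0:
            raise ValueError("require eps_solvent > eps_solute >= 1")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def kappa(self) -> float:
        """Inverse Debye length, Å^-1 (0 at zero salt)."""
        if self.ionic_strength == 0:
            return 0.0
        k2 = (2.0 * self.ionic_strength * 1000.0 * sc.Avogadro * sc.e**2
              / (sc.epsilon_0 * self.eps_solvent * sc.k * self.temperature))
        return float(np.sqrt(k2) * 1e-10)


@dataclass
class PBResult:
    """Grid charge-potential energy (kJ/mol) and the potential field."""

    grid_energy: float
    potential: np.ndarray
    converged: bool
    iterations: int
    residual: float
    grid: GridSpec = None


@dataclass(frozen=True)
class ElecComponents:
    """Electrostatic binding components, kJ/mol."""

    dG_solv: float
    dG_coul: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dG_solv) and np.isfinite(self.dG_coul)):
            raise ValueError("electrostatic components must be finite")


# ---------------------------------------------------------------------------
# field construction
# ---------------------------------------------------------------------------

def _node_dielectric(grid: GridSpec, xyz: np.ndarray, radii: np.ndarray,
                     eps_in: float, eps_out: float) -> np.ndarray:
    eps = np.full(grid.dims, float(eps_out))
    o = np.array(grid.origin)
    h = grid.spacing
    dims = np.array(grid.dims)
    for pos, r in zip(xyz, radii):
        lo = np.maximum(np.floor((pos - r - o) / h).astype(int), 0)
        hi = np.minimum(np.ceil((pos + r - o) / h).astype(int) + 1, dims)
        if np.any(lo >= hi):
            continue
        ax = [o[a] + h * np.arange(lo[a], hi[a]) - pos[a] for a in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = eps[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[d2 <= r * r] = eps_in
    return eps


def _spread_charges(grid: GridSpec, xyz: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Trilinear assignment of point charges to the 8 surrounding nodes."""
    qg = np.zeros(grid.dims)
    frac = (xyz - np.array(grid.origin)) / grid.spacing
    base = np.floor(frac).astype(int)
    w = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                weight = (
                    (w[:, 0] if dx else 1 - w[:, 0])
                    * (w[:, 1] if dy else 1 - w[:, 1])
                    * (w[:, 2] if dz else 1 - w[:, 2])
                )
                np.add.at(qg, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                          q * weight)
    return qg


def _analytic_potential(grid: GridSpec, xyz: np.ndarray, q: np.ndarray,
                        eps: float, kappa: float) -> np.ndarray:
    """Coulomb / Debye-Hückel superposition on all grid nodes (kJ/mol/e)."""
    gx, gy, gz = grid.axes()
    nodes = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
    d = cdist(nodes, xyz)
    np.maximum(d, 0.5 * grid.spacing, out=d)  # regularize near charge centers
    if kappa > 0:
        pot = (np.exp(-kappa * d) / d) @ q
    else:
        pot = (1.0 / d) @ q
    return (COULOMB_KJ_MOL_ANG / eps) * pot.reshape(grid.dims)


def _interp(field: np.ndarray, grid: GridSpec, points: np.ndarray) -> np.ndarray:
    frac = (points - np.array(grid.origin)) / grid.spacing
    return map_coordinates(field, frac.T, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def solve_poisson(
    mol: Molecule,
    grid: GridSpec,
    diel: DielectricModel,
    eps_out: float,
    boundary: np.ndarray | None = None,
    rtol: float = 1e-6,
    maxiter: int = 20_000,
) -> PBResult:
    """Solve the (linearized, zero-salt by default) Poisson problem.

    ``eps_out`` is the dielectric outside the atom spheres; the interior is
    ``diel.eps_solute``.  ``boundary`` optionally supplies a full-grid field
    whose face values serve as Dirichlet data (focusing); otherwise the faces
    carry the analytic Coulomb/Debye-Hückel superposition in ``eps_out``.
    Returns the charge-potential energy 1/2 sum_i q_i phi(r_i).
    """
    if not mol.charges_assigned or not mol.radii_assigned:
        raise MoleculeError(f"molecule {mol.id}: charges/radii must be assigned")
    if not grid.encloses(mol, margin=1.0):
        raise ValueError(f"grid does not enclose molecule {mol.id}")
    xyz, q, radii = mol.coords, mol.charges, mol.radii
    h = grid.spacing
    nx, ny, nz = grid.dims

    eps = _node_dielectric(grid, xyz, radii, diel.eps_solute, eps_out)
    ex = 2.0 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:])
    ey = 2.0 * eps[:, :-1] * eps[:, 1:] / (eps[:, :-1] + eps[:, 1:])
    ez = 2.0 * eps[:, :, :-1] * eps[:, :, 1:] / (eps[:, :, :-1] + eps[:, :, 1:])

    guess = _analytic_potential(grid, xyz, q, eps_out, diel.kappa)
    phi = guess.copy() if boundary is None else boundary.copy()

    b = 4.0 * np.pi * COULOMB_KJ_MOL_ANG * _spread_charges(grid, xyz, q) / h
    # boundary (Dirichlet) contributions folded into the rhs
    b[1, :, :] += ex[0] * phi[0]
    b[-2, :, :] += ex[-1] * phi[-1]
    b[:, 1, :] += ey[:, 0] * phi[:, 0]
    b[:, -2, :] += ey[:, -1] * phi[:, -1]
    b[:, :, 1] += ez[:, :, 0] * phi[:, :, 0]
    b[:, :, -2] += ez[:, :, -1] * phi[:, :, -1]

    diag = np.zeros(grid.dims)
    diag[:-1] += ex
    diag[1:] += ex
    diag[:, :-1] += ey
    diag[:, 1:] += ey
    diag[:, :, :-1] += ez
    diag[:, :, 1:] += ez
    if diel.kappa > 0:
        diag += eps * (diel.kappa * h) ** 2  # linearized screening term

    idx = np.arange(nx * ny * nz).reshape(grid.dims)
    interior = np.zeros(grid.dims, bool)
    interior[1:-1, 1:-1, 1:-1] = True
    comp = np.full(idx.size, -1, dtype=np.int64)
    int_flat = idx[interior]
    comp[int_flat] = np.arange(int_flat.size)

    rows = [comp[int_flat]]
    cols = [comp[int_flat]]
    vals = [diag[interior]]
    for r_sl, c_sl, e_sl in (
        (np.s_[1:-2, 1:-1, 1:-1], np.s_[2:-1, 1:-1, 1:-1], ex[1:-1, 1:-1, 1:-1]),
        (np.s_[1:-1, 1:-2, 1:-1], np.s_[1:-1, 2:-1, 1:-1], ey[1:-1, 1:-1, 1:-1]),
        (np.s_[1:-1, 1:-1, 1:-2], np.s_[1:-1, 1:-1, 2:-1], ez[1:-1, 1:-1, 1:-1]),
    ):
        r = comp[idx[r_sl].ravel()]
        c = comp[idx[c_sl].ravel()]
        v = -e_sl.ravel()
        rows += [r, c]
        cols += [c, r]
        vals += [v, v]
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(int_flat.size, int_flat.size),
    ).tocsr()

    b_int = b[interior]
    M = sp.diags(1.0 / diag[interior])
    n_iter = 0

    def _count(_):
        nonlocal n_iter
        n_iter += 1

    x, info = spla.cg(A, b_int, x0=phi[interior], rtol=rtol, maxiter=maxiter,
                      M=M, callback=_count)
    bnorm = np.linalg.norm(b_int)
    residual = float(np.linalg.norm(A @ x - b_int) / bnorm) if bnorm > 0 else 0.0
    converged = info == 0

    phi_full = phi.copy()
    phi_full[interior] = x
    energy = 0.5 * float(q @ _interp(phi_full, grid, xyz))
    return PBResult(energy, phi_full, converged, n_iter, residual, grid)


def solvation_energy(
    mol: Molecule,
    grid: GridSpec,
    diel: DielectricModel,
    coarse_grid: GridSpec | None = None,
    rtol: float = 1e-6,
    maxiter: int = 20_000,
) -> float:
    """Electrostatic solvation energy by same-grid differencing, kJ/mol.

    G(eps_out = eps_solvent) - G(eps_out = eps_solute), both on *grid*; the
    second run is the homogeneous reference that cancels the grid self-energy.
    With ``coarse_grid``, each run is focused: solve the coarse box with
    analytic boundary data, then use the interpolated coarse potential as
    Dirichlet data for *grid*.
    """
    energies = []
    for eps_out in (diel.eps_solvent, diel.eps_solute):
        boundary = None
        if coarse_grid is not None:
            coarse = solve_poisson(mol, coarse_grid, diel, eps_out,
                                   rtol=rtol, maxiter=maxiter)
            if not coarse.converged:
                raise NonConvergedError(
                    f"coarse Poisson solve not converged (residual "
                    f"{coarse.residual:.2e})"
                )
            gx, gy, gz = grid.axes()
            pts = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"),
                           axis=-1).reshape(-1, 3)
            boundary = _interp(coarse.potential, coarse_grid, pts).reshape(grid.dims)
        res = solve_poisson(mol, grid, diel, eps_out, boundary=boundary,
                            rtol=rtol, maxiter=maxiter)
        if not res.converged:
            raise NonConvergedError(
                f"Poisson solve (eps_out={eps_out}) not converged "
                f"(residual {res.residual:.2e})"
            )
        energies.append(res.grid_energy)
    return energies[0] - energies[1]


# ---------------------------------------------------------------------------
# Coulomb terms
# ---------------------------------------------------------------------------

def coulomb_energy(mol: Molecule, eps: float) -> float:
    """Pairwise intra-molecular Coulomb energy sum_{i<j} k_e q_i q_j / (eps r_ij)."""
    if eps < 1.0:
        raise ValueError("dielectric must be >= 1")
    if len(mol) < 2:
        return 0.0
    q = mol.charges
    d = pdist(mol.coords)
    iu, ju = np.triu_indices(len(mol), k=1)
    qq = q[iu] * q[ju]  # pdist order matches the row-major upper triangle
    if np.any((d < 1e-6) & (np.abs(qq) > 0)):
        raise ZeroDivisionError(f"molecule {mol.id}: coincident charged atoms")
    return float(COULOMB_KJ_MOL_ANG / eps * (qq / d).sum())


def inter_coulomb(a: Molecule, b: Molecule, eps: float) -> float:
    """Inter-molecular Coulomb energy between two rigid species, kJ/mol.

    Under rigid binding the intra-molecular sums cancel, so this pair sum is
    the Coulombic contribution to binding.
    """
    if eps < 1.0:
        raise ValueError("dielectric must be >= 1")
    d = cdist(a.coords, b.coords)
    if np.any((d < 1e-6) & (np.outer(np.abs(a.charges), np.abs(b.charges)) > 0)):
        raise ZeroDivisionError("coincident charged atoms across species")
    return float(COULOMB_KJ_MOL_ANG / eps
                 * (np.outer(a.charges, b.charges) / np.maximum(d, 1e-12)).sum())


def elec_binding_components(
    receptor: Molecule,
    posed_ligand: Molecule,
    diel: DielectricModel,
    grid: GridSpec | None = None,
    spacing: float = 0.6,
    padding: float = MIN_PADDING,
    coarse_grid: GridSpec | None = None,
    receptor_solvation: float | None = None,
    rtol: float = 1e-6,
) -> ElecComponents:
    """Electrostatic binding components of one pose.

    dG_solv = Gsolv(complex) - Gsolv(receptor) - Gsolv(ligand), all three on
    the identical grid (default: built from the complex); dG_coul is the
    inter-molecular pair sum in the uniform solute dielectric.  A precomputed
    ``receptor_solvation`` on the same grid may be supplied for caching.
    """
    complex_mol = receptor.merged_with(posed_ligand)
    if grid is None:
        grid = GridSpec.for_molecule(complex_mol, spacing, padding)
    for species in (receptor, posed_ligand):
        if not grid.encloses(species, margin=1.0):
            raise ValueError(
                "species grids inconsistent: shared grid does not enclose "
                f"{species.id}"
            )
    g_complex = solvation_energy(complex_mol, grid, diel, coarse_grid, rtol=rtol)
    g_rec = (receptor_solvation if receptor_solvation is not None
             else solvation_energy(receptor, grid, diel, coarse_grid, rtol=rtol))
    g_lig = solvation_energy(posed_ligand, grid, diel, coarse_grid, rtol=rtol)
    return ElecComponents(
        dG_solv=g_complex - g_rec - g_lig,
        dG_coul=inter_coulomb(receptor, posed_ligand, diel.eps_solute),
    )


def write_dx(result: PBResult, path) -> None:
    """Dump the potential field in OpenDX scalar-grid format."""
    g = result.grid
    nx, ny, nz = g.dims
    vals = result.potential.ravel()
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6e} {:.6e} {:.6e}".format(*g.origin),
        f"delta {g.spacing:.6e} 0.0 0.0",
        f"delta 0.0 {g.spacing:.6e} 0.0",
        f"delta 0.0 0.0 {g.spacing:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {vals.size} data follows",
    ]
    for i in range(0, vals.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
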