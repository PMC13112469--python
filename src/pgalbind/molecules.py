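"""Point-atom molecular model with PDB/PQR input and output.

A :class:`Molecule` is an ordered list of :class:`Atom` records carrying
Cartesian coordinates (Å), an optional partial charge (elementary charges)
and an optional hard-sphere radius (Å).  Charges and radii are assigned from
a :class:`ChargeRadiusTable`, a per-residue template whose partial charges
sum exactly to the residue's formal integer charge; the assigned molecule is
then written to the whitespace-delimited PQR dialect consumed by the
electrostatics and surface-area stages.

Hydrogen-bond capability is tracked per heavy atom via ``hbond_role``
(``donor`` / ``acceptor`` / ``both`` / ``none``); templates carry polar
hydrogens only, with nonpolar hydrogens folded into heavy-atom radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.spatial.distance import pdist

__all__ = [
    "Atom",
    "Molecule",
    "ChargeRadiusTable",
    "MoleculeError",
    "ParseError",
    "read_pdb",
    "read_pqr",
    "write_pdb",
    "write_pqr",
    "assign_charges_radii",
    "default_charge_table",
]

HBOND_ROLES = ("donor", "acceptor", "both", "none")
PROTONATION_LABELS = ("protonated", "zwitterionic", "fully_protonated_polymer", "other")

#: minimum credible separation between two atoms, Å (covalent sanity)
MIN_ATOM_SEPARATION = 0.7


class MoleculeError(ValueError):
    """Invariant violation in a molecular object."""


class ParseError(MoleculeError):
    """Malformed structure-file record; message names the offending line."""


@dataclass
class Atom:
    """A point atom: label, element, position (Å), charge (e), radius (Å)."""

    name: str
    element: str
    position: np.ndarray
    charge: float | None = None
    radius: float | None = None
    hbond_role: str = "none"
    res_name: str = "UNK"
    res_seq: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise MoleculeError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise MoleculeError(f"atom {self.name}: non-finite coordinates")
        if self.hbond_role not in HBOND_ROLES:
            raise MoleculeError(
                f"atom {self.name}: hbond_role {self.hbond_role!r} not in {HBOND_ROLES}"
            )
        if self.charge is not None and not -2.0 <= self.charge <= 2.0:
            raise MoleculeError(
                f"atom {self.name}: partial charge {self.charge} outside [-2, +2]"
            )
        if self.radius is not None and self.radius <= 0:
            raise MoleculeError(f"atom {self.name}: radius must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Molecule:
    """An ordered collection of atoms with a declared integer net charge."""

    id: str
    atoms: list[Atom]
    net_charge: int | None = None
    protonation_label: str = "other"

    def __post_init__(self) -> None:
        if self.protonation_label not in PROTONATION_LABELS:
            raise MoleculeError(
                f"unknown protonation label {self.protonation_label!r}"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([0.0 if a.charge is None else a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([0.0 if a.radius is None else a.radius for a in self.atoms])

    @property
    def charges_assigned(self) -> bool:
        return bool(self.atoms) and all(a.charge is not None for a in self.atoms)

    @property
    def radii_assigned(self) -> bool:
        return bool(self.atoms) and all(a.radius is not None for a in self.atoms)

    def validate(self, check_charge: bool = True) -> None:
        """Raise :class:`MoleculeError` on any structural invariant violation."""
        if not self.atoms:
            raise MoleculeError(f"molecule {self.id}: no atoms")
        xyz = self.coords
        if not np.all(np.isfinite(xyz)):
            raise MoleculeError(f"molecule {self.id}: non-finite coordinates")
        if len(self.atoms) > 1:
            dmin = pdist(xyz).min()
            if dmin < MIN_ATOM_SEPARATION:
                raise MoleculeError(
                    f"molecule {self.id}: atoms closer than "
                    f"{MIN_ATOM_SEPARATION} Å (min {dmin:.3f} Å)"
                )
        if check_charge and self.charges_assigned and self.net_charge is not None:
            total = float(self.charges.sum())
            if abs(total - self.net_charge) > 1e-6:
                raise MoleculeError(
                    f"molecule {self.id}: partial charges sum to {total:.6f}, "
                    f"declared net charge {self.net_charge}"
                )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a rigidly moved copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return Molecule(self.id, atoms, self.net_charge, self.protonation_label)

    def merged_with(self, other: "Molecule", new_id: str | None = None) -> "Molecule":
        """Concatenate two species into one complex (atom order preserved)."""
        nq = None
        if self.net_charge is not None and other.net_charge is not None:
            nq = self.net_charge + other.net_charge
        return Molecule(
            new_id or f"{self.id}+{other.id}",
            list(self.atoms) + list(other.atoms),
            nq,
            "other",
        )


@dataclass
class ChargeRadiusTable:
    """Per-residue template of (charge, radius, hbond_role) keyed by atom name.

    ``entries[res_name][atom_name] = (charge, radius, role)``; every residue's
    charges must sum to its declared formal integer charge within 1e-6.
    """

    entries: dict[str, dict[str, tuple[float, float, str]]]
    formal_charges: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res, atoms in self.entries.items():
            total = sum(v[0] for v in atoms.values())
            formal = self.formal_charges.get(res, round(total))
            if abs(total - formal) > 1e-6:
                raise MoleculeError(
                    f"template {res}: charges sum to {total:.6f}, "
                    f"formal charge {formal}"
                )
            self.formal_charges[res] = formal

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChargeRadiusTable":
        """Load a template table from the documented YAML schema.

        Schema::

            residues:
              <RES>:
                formal_charge: <int>
                atoms:
                  <NAME>: {charge: <e>, radius: <Å>, role: donor|acceptor|both|none}
        """
        raw = yaml.safe_load(Path(path).read_text())
        entries: dict[str, dict[str, tuple[float, float, str]]] = {}
        formal: dict[str, int] = {}
        for res, spec in raw["residues"].items():
            formal[res] = int(spec["formal_charge"])
            entries[res] = {
                name: (float(a["charge"]), float(a["radius"]), a.get("role", "none"))
                for name, a in spec["atoms"].items()
            }
        return cls(entries, formal)

    def lookup(self, res_name: str, atom_name: str) -> tuple[float, float, str]:
        try:
            return self.entries[res_name][atom_name]
        except KeyError:
            raise LookupError(
                f"no template entry for atom {atom_name!r} in residue {res_name!r}"
            ) from None


def default_charge_table() -> ChargeRadiusTable:
    """The bundled template table (gallic unit, histidine in two states)."""
    from importlib.resources import files

    path = files("pgalbind.data").joinpath("charges.yaml")
    return ChargeRadiusTable.from_yaml(str(path))


def assign_charges_radii(mol: Molecule, table: ChargeRadiusTable) -> Molecule:
    """Return a copy of *mol* with template charges, radii and H-bond roles.

    Assignment is idempotent.  Raises :class:`LookupError` listing every atom
    missing from the table.
    """
    missing = []
    new_atoms = []
    for a in mol.atoms:
        try:
            q, r, role = table.lookup(a.res_name, a.name)
        except LookupError:
            missing.append(f"{a.res_name}:{a.name}")
            continue
        new_atoms.append(replace(a, charge=q, radius=r, hbond_role=role))
    if missing:
        raise LookupError(
            "missing template entries for: " + ", ".join(sorted(set(missing)))
        )
    out = Molecule(mol.id, new_atoms, mol.net_charge, mol.protonation_label)
    if out.atoms:
        out.validate()
    return out


# ---------------------------------------------------------------------------
# File I/O.  PDB: fixed-column ATOM/HETATM records.  PQR: the permissive
# whitespace-delimited dialect, per-atom charge then radius as the last two
# numeric fields, 4-decimal fixed formatting.
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def read_pdb(path: str | Path) -> Molecule:
    """Read ATOM/HETATM records; charges and radii are left unassigned."""
    path = Path(path)
    atoms: list[Atom] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            name = line[12:16].strip()
            res_name = line[17:20].strip() or "UNK"
            res_seq = int(line[22:26].strip() or "1")
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            element = line[76:78].strip() or _element_from_name(name)
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path.name}:{lineno}: malformed record: {exc}") from exc
        atoms.append(Atom(name, element, np.array([x, y, z]),
                          res_name=res_name, res_seq=res_seq))
    if not atoms:
        raise ParseError(f"{path.name}: no ATOM/HETATM records")
    mol = Molecule(path.stem, atoms)
    mol.validate(check_charge=False)
    return mol


def read_pqr(path: str | Path) -> Molecule:
    """Read whitespace-delimited PQR (… x y z charge radius)."""
    path = Path(path)
    atoms: list[Atom] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        if len(fields) < 10:
            raise ParseError(
                f"{path.name}:{lineno}: expected >=10 whitespace fields, "
                f"got {len(fields)}"
            )
        try:
            name = fields[2]
            res_name = fields[3]
            res_seq = int(fields[4])
            x, y, z = (float(v) for v in fields[5:8])
            charge = float(fields[8])
            radius = float(fields[9])
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: malformed record: {exc}") from exc
        atoms.append(
            Atom(name, _element_from_name(name), np.array([x, y, z]),
                 charge=charge, radius=radius, res_name=res_name, res_seq=res_seq)
        )
    if not atoms:
        raise ParseError(f"{path.name}: no ATOM/HETATM records")
    mol = Molecule(path.stem, atoms)
    mol.validate(check_charge=False)
    return mol


def write_pdb(mol: Molecule, path: str | Path) -> None:
    """Write fixed-column PDB ATOM records."""
    lines = []
    for i, a in enumerate(mol.atoms, start=1):
        lines.append(
            f"ATOM  {i:5d} {a.name:<4.4s}{a.res_name:>4.3s}  {a.res_seq:4d}    "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pqr(mol: Molecule, path: str | Path) -> None:
    """Write the whitespace PQR dialect; refuses unassigned charges/radii."""
    for a in mol.atoms:
        if a.charge is None or a.radius is None or a.radius <= 0:
            raise MoleculeError(
                f"molecule {mol.id}: atom {a.name} lacks charge/radius; "
                "assign_charges_radii before write_pqr"
            )
    lines = [f"REMARK net charge {mol.net_charge}"] if mol.net_charge is not None else []
    for i, a in enumerate(mol.atoms, start=1):
        lines.append(
            f"ATOM {i} {a.name} {a.res_name} {a.res_seq} "
            f"{a.position[0]:.4f} {a.position[1]:.4f} {a.position[2]:.4f} "
            f"{a.charge:.4f} {a.radius:.4f}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
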