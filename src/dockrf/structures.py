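"""Shared 3-D structure model: typed atoms, molecules, complexes and pose sets.

Every featurizer in the package consumes only what these containers hold:
element symbols, SYBYL atom types, Cartesian coordinates (Å) and the bonded
neighbour relation.  Atom indices are 0-based in memory; file writers emit
1-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np


class StructureError(ValueError):
    """Raised for malformed or physically inconsistent structures."""


class EmptyStructureError(StructureError):
    """Raised when a structure contains no heavy atoms (e.g. water-only file)."""


#: Biometal elements treated as metal ions when present as isolated atoms.
METAL_ELEMENTS = frozenset(
    {"Na", "K", "Mg", "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Cd", "Hg"}
)

#: Residue names stripped as solvent by default.
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "SOL", "TIP3", "TIP4", "SPC"})


@dataclass
class Atom:
    """A single typed atom.

    ``sybyl_type`` is the mol2 chemical type (``C.ar``, ``N.4`` ...); for atoms
    read from PDB/PDBQT it is derived by the typing fallback in
    :mod:`dockrf.io`.  ``neighbor_indices`` lists bonded atoms by index within
    the owning molecule; the relation is kept symmetric by
    :meth:`Molecule.add_bond`.
    """

    index: int
    element: str
    sybyl_type: str
    coords: np.ndarray
    is_hydrogen: bool = False
    neighbor_indices: list[int] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (3,):
            raise StructureError(f"atom {self.index}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.index}: non-finite coordinates")


@dataclass
class Molecule:
    """A protein or ligand: a list of atoms plus bonds.

    ``torsdof`` carries the PDBQT torsional-degrees-of-freedom record for
    ligands.  ``pharmacophores`` is filled by
    :func:`dockrf.pharmacophore.assign_molecule` (one label per atom, ``None``
    for hydrogens) and is required by the contact and Vina featurizers.
    """

    atoms: list[Atom]
    role: str = "ligand"
    torsdof: Optional[int] = None
    pharmacophores: Optional[list[Optional[str]]] = None
    name: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    # -- construction -----------------------------------------------------
    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise StructureError(f"self-bond on atom {i}")
        for a, b in ((i, j), (j, i)):
            if b not in self.atoms[a].neighbor_indices:
                self.atoms[a].neighbor_indices.append(b)

    def validate(self) -> None:
        n = len(self.atoms)
        if self.role not in ("protein", "ligand"):
            raise StructureError(f"unknown role {self.role!r}")
        if self.torsdof is not None and self.torsdof < 0:
            raise StructureError("torsdof must be >= 0")
        for a in self.atoms:
            for j in a.neighbor_indices:
                if not 0 <= j < n:
                    raise StructureError(f"atom {a.index}: neighbor {j} out of range")
                if a.index not in self.atoms[j].neighbor_indices:
                    raise StructureError(
                        f"asymmetric bond {a.index}-{j}"
                    )
        if not any(not a.is_hydrogen for a in self.atoms):
            raise EmptyStructureError("molecule has no heavy atoms")

    # -- views ------------------------------------------------------------
    @property
    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if not a.is_hydrogen]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        if not atoms:
            return np.zeros((0, 3))
        return np.vstack([a.coords for a in atoms])

    @property
    def has_explicit_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)

    def neighbors(self, atom: Atom) -> list[Atom]:
        return [self.atoms[j] for j in atom.neighbor_indices]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] | None = None) -> "Molecule":
        """Return a rigidly transformed copy (used for invariance checks)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
        tr = np.zeros(3) if translation is None else np.asarray(translation, float)
        atoms = [
            Atom(a.index, a.element, a.sybyl_type, rot @ a.coords + tr,
                 a.is_hydrogen, list(a.neighbor_indices), a.name)
            for a in self.atoms
        ]
        return Molecule(atoms, self.role, self.torsdof,
                        None if self.pharmacophores is None
                        else list(self.pharmacophores), self.name)


@dataclass
class Complex:
    """One receptor together with one ligand pose, in a shared Å frame."""

    protein: Molecule
    ligand: Molecule

    def __post_init__(self) -> None:
        if self.protein.role != "protein":
            raise StructureError("Complex.protein must have role 'protein'")
        if self.ligand.role != "ligand":
            raise StructureError("Complex.ligand must have role 'ligand'")


@dataclass
class PoseSet:
    """A receptor with an ordered list of docked ligand poses.

    ``reported_scores`` holds the docking engine's energies (kcal/mol, from
    ``REMARK VINA RESULT`` records) when present, aligned with ``poses``.
    """

    receptor: Molecule
    poses: list[Molecule]
    reported_scores: Optional[list[Optional[float]]] = None

    def __post_init__(self) -> None:
        counts = {len(p) for p in self.poses}
        if len(counts) > 1:
            raise StructureError(
                f"poses have inconsistent atom counts: {sorted(counts)}"
            )
        if self.reported_scores is not None and len(self.reported_scores) != len(self.poses):
            raise StructureError("reported_scores misaligned with poses")

    def complexes(self) -> list[Complex]:
        return [Complex(self.receptor, p) for p in self.poses]
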