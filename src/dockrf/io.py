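"""Readers and writers for mol2, PDB and PDBQT (AutoDock dialect) files.

mol2 SYBYL atom types are trusted as given; PDB/PDBQT atoms receive a SYBYL
type from a documented fallback (AutoDock-type map for PDBQT, element +
connectivity heuristics for PDB).  Bonds come from the mol2 bond block or,
for PDB/PDBQT, from distance-based perception against covalent radii.

Multi-pose AutoDock Vina output (MODEL/ENDMDL blocks with ``REMARK VINA
RESULT`` energies) is parsed by :func:`read_pose_set`.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structures import (
    Atom,
    Complex,
    EmptyStructureError,
    METAL_ELEMENTS,
    Molecule,
    PoseSet,
    StructureError,
    WATER_RESNAMES,
)


class ParseError(StructureError):
    """Raised when a structure file cannot be parsed; names the offending line."""


# Covalent radii (Å) for distance-based bond perception (Cordero et al. set,
# rounded); generous defaults keep perception conservative for rare elements.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
}
_BOND_TOLERANCE = 1.25  # multiplicative slack on the radius sum

# AutoDock atom types -> (element, SYBYL type).  AD types distinguish
# aromatic carbon (A), H-bond acceptors (NA/OA/SA) and polar hydrogens (HD).
_AD_TYPES = {
    "C": ("C", "C.3"), "A": ("C", "C.ar"), "N": ("N", "N.am"),
    "NA": ("N", "N.3"), "NS": ("N", "N.3"), "OA": ("O", "O.3"),
    "OS": ("O", "O.3"), "O": ("O", "O.3"), "S": ("S", "S.3"),
    "SA": ("S", "S.3"), "P": ("P", "P.3"), "H": ("H", "H"),
    "HD": ("H", "H"), "HS": ("H", "H"), "F": ("F", "F"), "CL": ("Cl", "Cl"),
    "BR": ("Br", "Br"), "I": ("I", "I"), "SI": ("Si", "Si"),
    "MG": ("Mg", "Mg"), "MN": ("Mn", "Mn"), "ZN": ("Zn", "Zn"),
    "CA": ("Ca", "Ca"), "FE": ("Fe", "Fe"), "NI": ("Ni", "Ni"),
    "CO": ("Co", "Co"), "CU": ("Cu", "Cu"), "CD": ("Cd", "Cd"),
    "HG": ("Hg", "Hg"), "NA+": ("Na", "Na"), "K": ("K", "K"),
}

_ELEMENT_RE = re.compile(r"^([A-Z][a-z]?)")


def _element_from_name(name: str, resname: str = "") -> str:
    """Deduce an element symbol from a PDB atom name (e.g. ' CA ', '1HB2').

    Two-letter halogens are taken at face value; metal symbols only when the
    residue name matches the atom name (the convention for ions), so an
    alpha-carbon 'CA' in residue 'ALA' never becomes calcium.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot deduce element from atom name {name!r}")
    two = stripped[:2].capitalize()
    if two in ("Cl", "Br"):
        return two
    if two in METAL_ELEMENTS and resname.strip().upper() == stripped.upper():
        return two
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# mol2
# ---------------------------------------------------------------------------

def _read_mol2(lines: list[str], role: str) -> Molecule:
    section = None
    raw_atoms: list[tuple] = []
    raw_bonds: list[tuple[int, int]] = []
    mol_name = ""
    mol_line = 0
    for ln, line in enumerate(lines, start=1):
        s = line.strip()
        if s.startswith("@<TRIPOS>"):
            section = s[len("@<TRIPOS>"):].upper()
            mol_line = 0
            continue
        if not s or s.startswith("#"):
            continue
        if section == "MOLECULE":
            mol_line += 1
            if mol_line == 1:
                mol_name = s
        elif section == "ATOM":
            parts = s.split()
            if len(parts) < 6:
                raise ParseError(f"mol2 atom record too short at line {ln}")
            try:
                x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise ParseError(f"bad coordinates at line {ln}") from exc
            raw_atoms.append((parts[1], (x, y, z), parts[5]))
        elif section == "BOND":
            parts = s.split()
            if len(parts) < 3:
                raise ParseError(f"mol2 bond record too short at line {ln}")
            try:
                raw_bonds.append((int(parts[1]) - 1, int(parts[2]) - 1))
            except ValueError as exc:
                raise ParseError(f"bad bond indices at line {ln}") from exc

    atoms = []
    for i, (name, xyz, sybyl) in enumerate(raw_atoms):
        element = sybyl.split(".")[0].capitalize()
        atoms.append(Atom(i, element, sybyl, np.array(xyz),
                          is_hydrogen=(element == "H"), name=name))
    mol = Molecule(atoms, role=role, name=mol_name)
    for i, j in raw_bonds:
        if not (0 <= i < len(atoms) and 0 <= j < len(atoms)):
            raise ParseError(f"mol2 bond references missing atom {i + 1}-{j + 1}")
        mol.add_bond(i, j)
    mol.validate()
    return mol


def write_mol2(mol: Molecule, path: str | Path) -> None:
    """Write a molecule as TRIPOS mol2 (1-based indices, 4-decimal coords)."""
    bonds = sorted({tuple(sorted((a.index, j)))
                    for a in mol.atoms for j in a.neighbor_indices})
    out = ["@<TRIPOS>MOLECULE", mol.name or "dockrf",
           f"{len(mol.atoms)} {len(bonds)} 0 0 0", "SMALL", "NO_CHARGES", "",
           "@<TRIPOS>ATOM"]
    for a in mol.atoms:
        nm = a.name or a.element
        out.append(
            f"{a.index + 1:>7} {nm:<8} {a.coords[0]:>10.4f} {a.coords[1]:>10.4f}"
            f" {a.coords[2]:>10.4f} {a.sybyl_type:<8} 1 MOL 0.0000"
        )
    out.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(bonds, start=1):
        out.append(f"{k:>6} {i + 1:>5} {j + 1:>5} 1")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PDB / PDBQT
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, ln: int, pdbqt: bool) -> Optional[dict]:
    if not (line.startswith("ATOM") or line.startswith("HETATM")):
        return None
    try:
        name = line[12:16]
        altloc = line[16]
        resname = line[17:20].strip().upper()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM record at line {ln}") from exc
    element = ""
    ad_type = None
    if pdbqt:
        ad_type = line.split()[-1].upper()
        if ad_type in _AD_TYPES:
            element = _AD_TYPES[ad_type][0]
    if not element:
        field = line[76:78].strip()
        element = field.capitalize() if field else _element_from_name(name, resname)
    return {"name": name.strip(), "altloc": altloc, "resname": resname,
            "xyz": (x, y, z), "element": element, "ad_type": ad_type}


def _perceive_bonds(mol: Molecule) -> None:
    """Distance-based bond perception; metals are left unbonded (ions)."""
    idx = [a.index for a in mol.atoms if a.element not in METAL_ELEMENTS]
    if len(idx) < 2:
        return
    coords = np.vstack([mol.atoms[i].coords for i in idx])
    radii = np.array([_COVALENT_RADII.get(mol.atoms[i].element, 1.5) for i in idx])
    tree = cKDTree(coords)
    rmax = 2 * radii.max() * _BOND_TOLERANCE
    for a, b in tree.query_pairs(rmax):
        dist = float(np.linalg.norm(coords[a] - coords[b]))
        if 0.4 < dist <= (radii[a] + radii[b]) * _BOND_TOLERANCE:
            mol.add_bond(idx[a], idx[b])


def _in_small_ring(mol: Molecule, start: int, max_size: int = 6) -> bool:
    """True if the atom lies on a cycle of length <= max_size (BFS per edge)."""
    for nb in mol.atoms[start].neighbor_indices:
        # shortest path start..nb avoiding the direct edge
        seen = {start}
        frontier = [(start, 0)]
        while frontier:
            nxt = []
            for node, depth in frontier:
                if depth >= max_size - 1:
                    continue
                for k in mol.atoms[node].neighbor_indices:
                    if node == start and k == nb:
                        continue
                    if k == nb:
                        return True
                    if k not in seen and not mol.atoms[k].is_hydrogen:
                        seen.add(k)
                        nxt.append((k, depth + 1))
            frontier = nxt
    return False


def _derive_sybyl(mol: Molecule) -> None:
    """Element+connectivity fallback typing for structures without mol2 types.

    Heuristic, documented in the methods note: aromaticity is approximated by
    membership in a 5/6-ring whose members all have <= 3 heavy neighbours;
    carbonyl oxygens by a single sp2-carbon neighbour; carboxylate-like
    oxygens by terminal O on a C/P/S that bears >= 2 terminal oxygens.
    """
    for a in mol.atoms:
        if a.sybyl_type:
            continue
        el = a.element
        heavy_nb = [mol.atoms[j] for j in a.neighbor_indices
                    if not mol.atoms[j].is_hydrogen]
        deg = len(a.neighbor_indices)
        if a.is_hydrogen:
            a.sybyl_type = "H"
        elif el in METAL_ELEMENTS:
            a.sybyl_type = el
        elif el == "C":
            if len(heavy_nb) <= 3 and _in_small_ring(mol, a.index):
                a.sybyl_type = "C.ar"
            elif deg >= 4:
                a.sybyl_type = "C.3"
            elif deg == 3:
                a.sybyl_type = "C.2"
            else:
                a.sybyl_type = "C.3"
        elif el == "N":
            if len(heavy_nb) <= 3 and _in_small_ring(mol, a.index):
                a.sybyl_type = "N.ar"
            elif deg >= 4:
                a.sybyl_type = "N.4"
            elif any(n.element == "C" and any(
                    mol.atoms[k].element == "O" and
                    len([m for m in mol.atoms[k].neighbor_indices
                         if not mol.atoms[m].is_hydrogen]) == 1
                    for k in n.neighbor_indices) for n in heavy_nb):
                a.sybyl_type = "N.am"
            else:
                a.sybyl_type = "N.3"
        elif el == "O":
            parent = heavy_nb[0] if len(heavy_nb) == 1 else None
            if parent is not None and parent.element in ("C", "P", "S"):
                terminal_o = [
                    k for k in parent.neighbor_indices
                    if mol.atoms[k].element == "O"
                    and len([m for m in mol.atoms[k].neighbor_indices
                             if not mol.atoms[m].is_hydrogen]) == 1
                ]
                if len(terminal_o) >= 2:
                    a.sybyl_type = "O.co2"
                elif parent.element == "C" and len(parent.neighbor_indices) == 3:
                    a.sybyl_type = "O.2"
                else:
                    a.sybyl_type = "O.3"
            else:
                a.sybyl_type = "O.3"
        elif el == "S":
            a.sybyl_type = "S.3"
        elif el == "P":
            a.sybyl_type = "P.3"
        else:
            a.sybyl_type = el


def _build_pdb_molecule(records: list[dict], role: str, keep_waters: bool,
                        torsdof: Optional[int]) -> Molecule:
    atoms = []
    for rec in records:
        if not keep_waters and rec["resname"] in WATER_RESNAMES:
            continue
        if rec["altloc"] not in (" ", "", "A"):
            continue
        el = rec["element"]
        sybyl = ""
        if rec["ad_type"] is not None and rec["ad_type"] in _AD_TYPES:
            sybyl = _AD_TYPES[rec["ad_type"]][1]
        atoms.append(Atom(len(atoms), el, sybyl, np.array(rec["xyz"]),
                          is_hydrogen=(el == "H"), name=rec["name"]))
    mol = Molecule(atoms, role=role, torsdof=torsdof)
    if not any(not a.is_hydrogen for a in atoms):
        raise EmptyStructureError("no heavy atoms left after solvent stripping")
    _perceive_bonds(mol)
    _derive_sybyl(mol)
    mol.validate()
    return mol


def _read_pdb_like(lines: list[str], role: str, keep_waters: bool,
                   pdbqt: bool) -> Molecule:
    records = []
    torsdof = None
    for ln, line in enumerate(lines, start=1):
        if line.startswith("TORSDOF"):
            try:
                torsdof = int(line.split()[1])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"bad TORSDOF record at line {ln}") from exc
            continue
        rec = _parse_pdb_atom_line(line, ln, pdbqt)
        if rec is not None:
            records.append(rec)
    return _build_pdb_molecule(records, role, keep_waters, torsdof)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, role: str, keep_waters: bool = False,
                   fmt: Optional[str] = None) -> Molecule:
    """Read a PDB, PDBQT or mol2 file into a :class:`Molecule`.

    Format is taken from the extension unless ``fmt`` is given.  Waters and
    non-'A' alternate locations are stripped by default; ions are retained as
    single-atom entries.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if fmt == "mol2":
        mol = _read_mol2(lines, role)
    elif fmt in ("pdb", "pdbqt", "ent"):
        mol = _read_pdb_like(lines, role, keep_waters, pdbqt=(fmt == "pdbqt"))
    else:
        raise ParseError(f"unsupported structure format {fmt!r} for {path}")
    mol.name = mol.name or path.stem
    return mol


_VINA_RESULT_RE = re.compile(r"REMARK VINA RESULT:\s*(-?\d+\.?\d*)")


def read_pose_set(path: str | Path, receptor: Molecule,
                  keep_waters: bool = True) -> PoseSet:
    """Parse a (possibly multi-MODEL) PDBQT docking output into a PoseSet.

    One ligand pose per MODEL block (a file without MODEL records is a single
    pose); ``REMARK VINA RESULT`` energies are captured when present.  Models
    with inconsistent atom counts raise :class:`StructureError`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    blocks: list[list[str]] = []
    current: Optional[list[str]] = None
    has_models = any(l.startswith("MODEL") for l in lines)
    if not has_models:
        blocks = [lines]
    else:
        for line in lines:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ENDMDL"):
                if current is not None:
                    blocks.append(current)
                current = None
            elif current is not None:
                current.append(line)
    poses, scores = [], []
    for block in blocks:
        mol = _read_pdb_like(block, "ligand", keep_waters, pdbqt=True)
        mol.name = path.stem
        poses.append(mol)
        m = next((_VINA_RESULT_RE.search(l) for l in block
                  if _VINA_RESULT_RE.search(l)), None)
        scores.append(float(m.group(1)) if m else None)
    if not poses:
        raise ParseError(f"no poses found in {path}")
    return PoseSet(receptor, poses,
                   scores if any(s is not None for s in scores) else None)


# SYBYL -> AutoDock type used when writing PDBQT (acceptor flavours chosen for
# N/O/S; adequate for round-tripping through the typing fallback).
def _ad_type_for(atom: Atom) -> str:
    if atom.is_hydrogen:
        return "HD"
    if atom.sybyl_type == "C.ar":
        return "A"
    el = atom.element.upper()
    return {"N": "NA", "O": "OA", "S": "SA", "CL": "CL", "BR": "BR"}.get(el, el)


def write_pdbqt(mol: Molecule, path: str | Path,
                model_scores: Optional[list[float]] = None) -> None:
    """Write a ligand as single-pose PDBQT (with TORSDOF when known)."""
    write_pose_pdbqt([mol], path, scores=None)


def write_pose_pdbqt(poses: list[Molecule], path: str | Path,
                     scores: Optional[list[Optional[float]]] = None) -> None:
    """Write one or more ligand poses as a (multi-)MODEL PDBQT file."""
    out: list[str] = []
    multi = len(poses) > 1
    for k, mol in enumerate(poses):
        if multi:
            out.append(f"MODEL {k + 1}")
        if scores is not None and scores[k] is not None:
            out.append(f"REMARK VINA RESULT: {scores[k]:>9.3f}      0.000      0.000")
        out.append("ROOT")
        for a in mol.atoms:
            nm = (a.name or a.element)[:4]
            out.append(
                f"ATOM  {a.index + 1:>5} {nm:<4} LIG A   1    "
                f"{a.coords[0]:>8.3f}{a.coords[1]:>8.3f}{a.coords[2]:>8.3f}"
                f"  1.00  0.00     0.000 {_ad_type_for(a):<2}"
            )
        out.append("ENDROOT")
        if mol.torsdof is not None:
            out.append(f"TORSDOF {mol.torsdof}")
        if multi:
            out.append("ENDMDL")
    Path(path).write_text("\n".join(out) + "\n")
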