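"""Desk-scale synthetic complexes with a planted affinity signal.

Toy "proteins" and "ligands" are unconnected typed atom clouds: every
featurizer in the package consumes only SYBYL types, bonds and coordinates,
so residue topology is unnecessary.  Bonds (and explicit hydrogens) are
added only where a typing pattern needs neighbours — hydroxyl/amide
hydrogens, quaternary amines, carboxylate triads.  Atom clouds are packed
at realistic heavy-atom density (~0.04 atoms/Å**3) with a 1.5 Å minimum
separation; the ligand cloud is centred just outside the receptor surface
so the first contact shells are populated, as for a surface-bound pose.

The affinity label of each complex is a sparse linear function of its own
feature vector plus Gaussian noise, clipped to the physical pKd range
[0, 16].  With the default weights the labels span roughly pKd 3-9, the
range that dominates experimental affinity data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .features import FeatureConfig, featurize_many
from .io import write_mol2, write_pose_pdbqt
from .structures import Atom, Complex, Molecule, StructureError

# Palette entries: (SYBYL type, number of explicit hydrogens, weight).
# Types are chosen so each labels cleanly under the packaged rule table:
# C.3 -> H, C.ar -> AR, O.3+H -> DA, O.2 -> A, N.am+H -> D, N.4+4H -> P,
# N.3 -> A, S.3+H -> DA, N.am -> PL, F -> HA, Zn -> MI; the carboxylate
# triad (C.2 with two terminal O.co2) contributes N-labelled oxygens.
DEFAULT_PROTEIN_PALETTE = (
    ("C.3", 0, 0.30), ("C.ar", 0, 0.20), ("O.3", 1, 0.10), ("O.2", 0, 0.08),
    ("N.am", 1, 0.08), ("N.am", 0, 0.05), ("N.3", 0, 0.05), ("N.4", 4, 0.03),
    ("S.3", 1, 0.02), ("COO", 0, 0.06), ("Zn", 0, 0.03),
)
DEFAULT_LIGAND_PALETTE = (
    ("C.3", 0, 0.34), ("C.ar", 0, 0.24), ("O.3", 1, 0.10), ("O.2", 0, 0.08),
    ("N.am", 1, 0.07), ("N.3", 0, 0.06), ("F", 0, 0.07), ("S.3", 0, 0.04),
)

#: Default planted signal: short/medium-range hydrophobic and aromatic
#: contact bins plus the contact surface area.  Weight scales were sized
#: from the generator's analytic feature magnitudes so labels span ~3-9 pKd.
DEFAULT_SIGNAL = {
    "PH_LH_S1": 0.50,
    "PH_LH_S2": 0.25,
    "PAR_LAR_S2": 0.30,
    "PH_LAR_S3": 0.10,
    "PDA_LDA_S1": 0.60,
    "PA_LDA_S2": 0.30,
    "csa": 0.008,
}

HEAVY_ATOM_DENSITY = 0.04  # heavy atoms per Å**3, protein-like


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for fixture generation; the seed fixes everything."""

    n_complexes: int = 500
    protein_size: tuple[int, int] = (40, 80)
    ligand_size: tuple[int, int] = (8, 16)
    pocket_distance: tuple[float, float] = (1.0, 1.0)  # offset past surface: mean, sd (Å)
    protein_palette: tuple = DEFAULT_PROTEIN_PALETTE
    ligand_palette: tuple = DEFAULT_LIGAND_PALETTE
    signal: Optional[dict] = None          # None -> DEFAULT_SIGNAL
    intercept: float = 2.5
    noise_sd: float = 0.35                 # pKd units
    min_separation: float = 1.5            # Å between heavy atoms
    seed: int = 0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_complexes < 0:
            raise ValueError("n_complexes must be >= 0")


@dataclass
class SyntheticDataset:
    complexes: list[Complex]
    labels: np.ndarray
    features: pd.DataFrame
    spec: SyntheticSpec

    def __iter__(self) -> Iterator[tuple[Complex, float]]:
        return iter(zip(self.complexes, self.labels))

    def __len__(self) -> int:
        return len(self.complexes)

    @property
    def ids(self) -> list[str]:
        return list(self.features.index)


def _sample_positions(rng: np.random.Generator, n: int, radius: float,
                      center: np.ndarray, min_sep: float,
                      obstacles: Optional[np.ndarray] = None,
                      margins: Optional[np.ndarray] = None,
                      max_tries: int = 500) -> np.ndarray:
    """Uniform positions in a sphere with pairwise and obstacle separation.

    ``margins`` adds per-site clearance (for motifs whose pendant heavy
    atoms extend beyond the site centre) on top of ``min_sep``.
    """
    if margins is None:
        margins = np.zeros(n)
    placed: list[np.ndarray] = []
    for i in range(n):
        for attempt in range(max_tries):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = center + v * radius * rng.random() ** (1.0 / 3.0)
            ok = all(np.linalg.norm(p - q) >= min_sep + margins[i] + margins[j]
                     for j, q in enumerate(placed))
            if ok and obstacles is not None and len(obstacles):
                ok = np.min(np.linalg.norm(obstacles - p, axis=1)) \
                    >= min_sep + margins[i]
            if ok:
                placed.append(p)
                break
        else:
            raise StructureError(
                f"cannot pack {n} atoms in radius {radius:.1f} Å "
                f"after {max_tries} tries")
    return np.array(placed).reshape(n, 3)


def _cloud_radius(n_atoms: int) -> float:
    return (n_atoms / HEAVY_ATOM_DENSITY * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _pick_types(rng: np.random.Generator, palette, n: int) -> list:
    weights = np.array([w for _, _, w in palette], dtype=float)
    weights /= weights.sum()
    idx = rng.choice(len(palette), size=n, p=weights)
    return [palette[i] for i in idx]


def _build_molecule(rng: np.random.Generator, role: str, entries,
                    positions: np.ndarray) -> Molecule:
    mol = Molecule([], role=role)
    for (sybyl, n_h, _), pos in zip(entries, positions):
        if sybyl == "COO":  # carboxylate triad: C.2 with two terminal O.co2
            c = Atom(len(mol.atoms), "C", "C.2", pos)
            mol.atoms.append(c)
            # planar geometry: O-C-O angle ~126 deg, C-O bond 1.25 Å
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            w = np.cross(u, rng.normal(size=3))
            w /= np.linalg.norm(w)
            half = np.deg2rad(63.0)
            for sign in (1.0, -1.0):
                direction = np.cos(half) * u + sign * np.sin(half) * w
                o = Atom(len(mol.atoms), "O", "O.co2", pos + 1.25 * direction)
                mol.atoms.append(o)
                mol.add_bond(c.index, o.index)
            continue
        element = sybyl.split(".")[0].capitalize()
        a = Atom(len(mol.atoms), element, sybyl, pos)
        mol.atoms.append(a)
        for _ in range(n_h):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            h = Atom(len(mol.atoms), "H", "H", pos + 1.0 * v, is_hydrogen=True)
            mol.atoms.append(h)
            mol.add_bond(a.index, h.index)
    mol.validate()
    return mol


def generate_complex(rng: np.random.Generator, spec: SyntheticSpec,
                     index: int = 0) -> Complex:
    """One receptor/ligand pair; geometry and typing only, no label."""
    n_p = int(rng.integers(spec.protein_size[0], spec.protein_size[1] + 1))
    n_l = int(rng.integers(spec.ligand_size[0], spec.ligand_size[1] + 1))
    r_p, r_l = _cloud_radius(n_p), _cloud_radius(n_l)
    p_entries = _pick_types(rng, spec.protein_palette, n_p)
    p_margins = np.array([1.25 if e[0] == "COO" else 0.0 for e in p_entries])
    p_pos = _sample_positions(rng, n_p, r_p, np.zeros(3),
                              spec.min_separation, margins=p_margins)
    protein = _build_molecule(rng, "protein", p_entries, p_pos)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    offset = rng.normal(spec.pocket_distance[0], spec.pocket_distance[1])
    center = direction * (r_p + offset)
    l_entries = _pick_types(rng, spec.ligand_palette, n_l)
    l_margins = np.array([1.25 if e[0] == "COO" else 0.0 for e in l_entries])
    heavy = np.array([a.coords for a in protein.atoms if not a.is_hydrogen])
    l_pos = _sample_positions(rng, n_l, r_l, center, spec.min_separation,
                              obstacles=heavy, margins=l_margins)
    ligand = _build_molecule(rng, "ligand", l_entries, l_pos)
    ligand.torsdof = int(rng.integers(0, 9))
    protein.name = f"receptor_{index:04d}"
    ligand.name = f"ligand_{index:04d}"
    return Complex(protein, ligand)


def generate(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticDataset:
    """Generate complexes, featurize them and plant the affinity signal."""
    rng = np.random.default_rng(spec.seed)
    complexes = [generate_complex(rng, spec, i) for i in range(spec.n_complexes)]
    ids = [f"cpx_{i:04d}" for i in range(spec.n_complexes)]
    features = featurize_many(complexes, spec.feature_config, ids=ids)
    signal = DEFAULT_SIGNAL if spec.signal is None else spec.signal
    missing = [k for k in signal if k not in features.columns]
    if missing:
        raise ValueError(f"signal features not in schema: {missing}")
    contribution = np.zeros(len(features))
    for name, w in signal.items():
        contribution += w * features[name].to_numpy()
    noise = rng.normal(0.0, spec.noise_sd, size=len(features)) \
        if spec.noise_sd > 0 else np.zeros(len(features))
    labels = np.clip(spec.intercept + contribution + noise, 0.0, 16.0)
    return SyntheticDataset(complexes, labels, features, spec)


def write_fixture_files(dataset: SyntheticDataset, directory: str | Path,
                        pdbqt_poses: bool = True) -> pd.DataFrame:
    """Write receptor/ligand mol2 files plus a labels TSV; returns the table.

    mol2 is the lossless interchange format (SYBYL types round-trip exactly;
    the ligand TORSDOF is recorded in the labels table).  A single-pose PDBQT
    per ligand is written too for exercising the rescoring path; its AutoDock
    typing is a lossy projection of the mol2 types.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for cid, (cplx, pkd) in zip(dataset.ids, dataset):
        rec = directory / f"{cid}_receptor.mol2"
        lig = directory / f"{cid}_ligand.mol2"
        write_mol2(cplx.protein, rec)
        write_mol2(cplx.ligand, lig)
        if pdbqt_poses:
            write_pose_pdbqt([cplx.ligand], directory / f"{cid}_ligand.pdbqt")
        rows.append({"id": cid, "receptor": rec.name, "ligand": lig.name,
                     "pkd": pkd, "torsdof": cplx.ligand.torsdof})
    table = pd.DataFrame(rows, columns=["id", "receptor", "ligand", "pkd",
                                        "torsdof"])
    table.to_csv(directory / "labels.tsv", sep="\t", index=False)
    return table
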