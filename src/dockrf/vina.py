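"""Unweighted AutoDock Vina energy terms and the rotatable-bond count.

Every term is a function of the surface distance
``d_surf = r - (r_vdw_a + r_vdw_b)`` between a protein and a ligand heavy
atom (Vina atom-type radii, see ``data/vina_radii.tsv``), summed over all
intermolecular pairs within an 8 Å cutoff:

    gauss1      = exp(-(d_surf / 0.5)^2)
    gauss2      = exp(-((d_surf - 3) / 2)^2)
    repulsion   = d_surf^2            for d_surf < 0, else 0
    hydrophobic = ramp 1 -> 0 over d_surf in [0.5, 1.5]   (hydrophobic pairs)
    hbond       = ramp 1 -> 0 over d_surf in [-0.7, 0]    (donor-acceptor pairs)

Pair eligibility comes from the pharmacophore labels: H, and AR on carbon,
are hydrophobic; D/DA donate; A/DA accept.  The sixth feature is the
ligand's rotatable-bond count (PDBQT TORSDOF record when present, else
perceived as non-ring, non-terminal, non-amide heavy-atom single bonds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .sasa import _load_radius_table
from .structures import Complex, Molecule, StructureError

DEFAULT_CUTOFF = 8.0  # Å, Vina's interaction cutoff

#: Term parameters (Å), shipped as an auditable config block.
TERM_PARAMS = {
    "gauss1_width": 0.5,
    "gauss2_offset": 3.0,
    "gauss2_width": 2.0,
    "hydrophobic_good": 0.5,
    "hydrophobic_bad": 1.5,
    "hbond_good": -0.7,
    "hbond_bad": 0.0,
}

_VINA_RADII: dict[str, float] | None = None


def vina_radii() -> dict[str, float]:
    global _VINA_RADII
    if _VINA_RADII is None:
        _VINA_RADII = _load_radius_table("vina_radii.tsv")
    return _VINA_RADII


@dataclass
class VinaFeatures:
    """Five unweighted term sums plus the rotatable-bond count."""

    gauss1: float
    gauss2: float
    repulsion: float
    hydrophobic: float
    hbond: float
    n_rot: int

    def as_tuple(self) -> tuple:
        return (self.gauss1, self.gauss2, self.repulsion,
                self.hydrophobic, self.hbond, self.n_rot)


def term_values(d_surf: float) -> tuple[float, float, float, float, float]:
    """Closed-form per-pair values (gauss1, gauss2, repulsion, hydrophobic,
    hbond) at one surface distance; the last two are the ramp factors that
    apply only to eligible pairs."""
    p = TERM_PARAMS
    d = float(d_surf)
    gauss1 = float(np.exp(-((d / p["gauss1_width"]) ** 2)))
    gauss2 = float(np.exp(-(((d - p["gauss2_offset"]) / p["gauss2_width"]) ** 2)))
    repulsion = d * d if d < 0 else 0.0
    hydrophobic = _ramp(d, p["hydrophobic_good"], p["hydrophobic_bad"])
    hbond = _ramp(d, p["hbond_good"], p["hbond_bad"])
    return gauss1, gauss2, repulsion, hydrophobic, hbond


def _ramp(d: float, good: float, bad: float) -> float:
    if d <= good:
        return 1.0
    if d >= bad:
        return 0.0
    return (bad - d) / (bad - good)


def _pair_flags(mol: Molecule):
    """Hydrophobic / donor / acceptor flags per heavy atom from labels."""
    if mol.pharmacophores is None:
        raise StructureError(
            "molecule is not pharmacophore-typed; call assign_molecule first")
    idx = [a.index for a in mol.atoms if not a.is_hydrogen]
    coords = (np.vstack([mol.atoms[i].coords for i in idx])
              if idx else np.zeros((0, 3)))
    hydro, donor, accept = [], [], []
    for i in idx:
        lab = mol.pharmacophores[i]
        el = mol.atoms[i].element
        hydro.append(lab == "H" or (lab == "AR" and el == "C"))
        donor.append(lab in ("D", "DA"))
        accept.append(lab in ("A", "DA"))
    radii_table = vina_radii()
    missing = sorted({mol.atoms[i].element for i in idx
                      if mol.atoms[i].element not in radii_table})
    if missing:
        raise StructureError(f"no Vina radius for element(s): {missing}")
    radii = np.array([radii_table[mol.atoms[i].element] for i in idx])
    return (coords, radii, np.array(hydro), np.array(donor), np.array(accept))


def vina_features(cplx: Complex, cutoff: float = DEFAULT_CUTOFF) -> VinaFeatures:
    """Sum the five terms over intermolecular heavy-atom pairs within cutoff."""
    p_xyz, p_rad, p_h, p_d, p_a = _pair_flags(cplx.protein)
    l_xyz, l_rad, l_h, l_d, l_a = _pair_flags(cplx.ligand)
    sums = np.zeros(5)
    if len(p_xyz) and len(l_xyz):
        tree = cKDTree(p_xyz)
        pm = TERM_PARAMS
        for li, plist in enumerate(tree.query_ball_point(l_xyz, cutoff)):
            if not plist:
                continue
            pi = np.asarray(plist, dtype=np.intp)
            r = np.linalg.norm(p_xyz[pi] - l_xyz[li], axis=1)
            d = r - (p_rad[pi] + l_rad[li])
            sums[0] += np.exp(-((d / pm["gauss1_width"]) ** 2)).sum()
            sums[1] += np.exp(
                -(((d - pm["gauss2_offset"]) / pm["gauss2_width"]) ** 2)).sum()
            neg = d < 0
            sums[2] += (d[neg] ** 2).sum()
            hp = p_h[pi] & l_h[li]
            if hp.any():
                sums[3] += _ramp_vec(d[hp], pm["hydrophobic_good"],
                                     pm["hydrophobic_bad"]).sum()
            hb = (p_d[pi] & l_a[li]) | (p_a[pi] & l_d[li])
            if hb.any():
                sums[4] += _ramp_vec(d[hb], pm["hbond_good"],
                                     pm["hbond_bad"]).sum()
    n_rot = (cplx.ligand.torsdof if cplx.ligand.torsdof is not None
             else count_rotatable_bonds(cplx.ligand))
    return VinaFeatures(*map(float, sums), n_rot)


def _ramp_vec(d: np.ndarray, good: float, bad: float) -> np.ndarray:
    return np.clip((bad - d) / (bad - good), 0.0, 1.0)


def _edge_in_ring(mol: Molecule, i: int, j: int) -> bool:
    """True if i-j lies on a cycle: j reachable from i without the edge."""
    seen = {i}
    stack = [k for k in mol.atoms[i].neighbor_indices if k != j]
    while stack:
        k = stack.pop()
        if k == j:
            return True
        if k in seen:
            continue
        seen.add(k)
        stack.extend(m for m in mol.atoms[k].neighbor_indices
                     if m not in seen and not (k == i and m == j))
    return False


def count_rotatable_bonds(mol: Molecule) -> int:
    """Operational rotatable-bond count: acyclic bonds between non-terminal
    heavy atoms, excluding amide C-N bonds (N.am to a carbonyl-type carbon)."""
    n_rot = 0
    for a in mol.atoms:
        if a.is_hydrogen:
            continue
        for j in a.neighbor_indices:
            if j <= a.index:
                continue
            b = mol.atoms[j]
            if b.is_hydrogen:
                continue
            heavy_a = sum(1 for k in a.neighbor_indices
                          if not mol.atoms[k].is_hydrogen)
            heavy_b = sum(1 for k in b.neighbor_indices
                          if not mol.atoms[k].is_hydrogen)
            if heavy_a < 2 or heavy_b < 2:
                continue  # terminal bond
            types = {a.sybyl_type, b.sybyl_type}
            if "N.am" in types and ("C.2" in types or "C.ar" in types):
                continue  # amide-like
            if _edge_in_ring(mol, a.index, j):
                continue
            n_rot += 1
    return n_rot
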