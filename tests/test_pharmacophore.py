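"""Typing-rule table: per-atom labels, precedence, totality, determinism."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dockrf.pharmacophore import (ALPHABET_9, DEFAULT_ALPHABET,
                                  assign_molecule, assign_pharmacophore,
                                  count_labels, default_rules)
from dockrf.structures import Atom, Molecule

from conftest import build_molecule


def _ring(sybyl="C.ar", n=6, radius=1.4):
    entries = [(sybyl, (radius * np.cos(2 * np.pi * k / n),
                        radius * np.sin(2 * np.pi * k / n), 0.0))
               for k in range(n)]
    bonds = [(k, (k + 1) % n) for k in range(n)]
    return entries, bonds


def _label_of(entries, bonds, atom_idx=0):
    mol = build_molecule(entries, bonds)
    return assign_molecule(mol)[atom_idx]


CASES = [
    # quaternary amine: N.4 with four bonded atoms -> positive
    ("N4_quaternary", [("N.4", (0, 0, 0))] + [("C.3", (1.5 * k, 1, 0))
                                              for k in range(4)],
     [(0, k) for k in range(1, 5)], 0, "P"),
    # hydroxyl oxygen with explicit hydrogen -> donor-acceptor
    ("O_with_H", [("O.3", (0, 0, 0)), ("H", (0.96, 0, 0)),
                  ("C.3", (-1.4, 0, 0))], [(0, 1), (0, 2)], 0, "DA"),
    # aromatic carbon -> aromatic
    ("C_aromatic", *(_ring()), 0, "AR"),
    # fluorine -> halogen
    ("F_halogen", [("F", (0, 0, 0)), ("C.3", (1.4, 0, 0))], [(0, 1)], 0, "HA"),
    # carbon with no N/O/F/P/S neighbour -> hydrophobic
    ("C_hydrophobic", [("C.3", (0, 0, 0)), ("C.3", (1.5, 0, 0))],
     [(0, 1)], 0, "H"),
    # carbon bonded to an oxygen -> polar
    ("C_polar", [("C.3", (0, 0, 0)), ("O.3", (1.4, 0, 0)),
                 ("H", (2.0, 0.5, 0))], [(0, 1), (1, 2)], 0, "PL"),
    # carboxylate oxygen -> negative (C bearing two terminal oxygens)
    ("O_carboxylate", [("O.co2", (1.2, 0.6, 0)), ("C.2", (0, 0, 0)),
                       ("O.co2", (1.2, -0.6, 0)), ("C.3", (-1.5, 0, 0)),
                       ("H", (-2, 1, 0))],
     [(0, 1), (1, 2), (1, 3), (3, 4)], 0, "N"),
    # amide nitrogen with hydrogen -> donor
    ("N_amide_donor", [("N.am", (0, 0, 0)), ("H", (1, 0, 0)),
                       ("C.2", (-1.3, 0, 0))], [(0, 1), (0, 2)], 0, "D"),
    # pyridine-type aromatic nitrogen (two neighbours, no H) -> acceptor
    ("N_pyridine", [("N.ar", (0, 0, 0)), ("C.ar", (1.4, 0, 0)),
                    ("C.ar", (-1.4, 0, 0)), ("H", (2.4, 0, 0)),
                    ("H", (-2.4, 0, 0))],
     [(0, 1), (0, 2), (1, 3), (2, 4)], 0, "A"),
    # carbonyl oxygen, no hydrogen anywhere relevant -> acceptor
    ("O_carbonyl", [("O.2", (0, 0, 0)), ("C.2", (1.25, 0, 0)),
                    ("H", (2, 0.8, 0))], [(0, 1), (1, 2)], 0, "A"),
    # thioether sulfur (fewer than three bonds) -> acceptor
    ("S_thioether", [("S.3", (0, 0, 0)), ("C.3", (1.8, 0, 0)),
                     ("C.3", (-1.8, 0, 0)), ("H", (2.5, 0.8, 0))],
     [(0, 1), (0, 2), (1, 3)], 0, "A"),
    # sulfoxide-like sulfur with three bonds -> polar
    ("S_three_bonds", [("S.3", (0, 0, 0)), ("C.3", (1.8, 0, 0)),
                       ("C.3", (-1.8, 0, 0)), ("O.2", (0, 1.5, 0)),
                       ("H", (2.5, 0.8, 0))],
     [(0, 1), (0, 2), (0, 3), (1, 4)], 0, "PL"),
    # thiol sulfur with explicit H -> donor-acceptor
    ("S_thiol", [("S.3", (0, 0, 0)), ("H", (1.3, 0, 0)),
                 ("C.3", (-1.8, 0, 0)), ("H", (-2.4, 0.8, 0))],
     [(0, 1), (0, 2), (2, 3)], 0, "DA"),
    # phosphorus -> polar
    ("P_polar", [("P.3", (0, 0, 0)), ("C.3", (1.8, 0, 0)),
                 ("H", (2.4, 0.8, 0))], [(0, 1), (1, 2)], 0, "PL"),
]


@pytest.mark.parametrize("name,entries,bonds,idx,expected",
                         CASES, ids=[c[0] for c in CASES])
def test_rule_table_assignments(name, entries, bonds, idx, expected):
    assert _label_of(entries, bonds, idx) == expected


def test_zinc_ion_is_metal_label():
    mol = build_molecule([("Zn", (0, 0, 0)), ("C.3", (8, 8, 8))])
    assert assign_molecule(mol)[0] == "MI"


def test_nine_type_mode_drops_metal_label():
    mol = build_molecule([("Zn", (0, 0, 0)), ("C.3", (8, 8, 8))])
    labels = assign_molecule(mol, alphabet=ALPHABET_9)
    assert labels[0] != "MI"
    assert set(l for l in labels if l) <= set(ALPHABET_9)


def test_implicit_hydrogens_when_structure_has_none():
    # hydroxyl oxygen without explicit H: valence deficit implies the proton
    mol = build_molecule([("O.3", (0, 0, 0)), ("C.3", (1.4, 0, 0))],
                         bonds=[(0, 1)])
    assert assign_molecule(mol)[0] == "DA"
    # but a molecule with explicit hydrogens elsewhere gets no implied ones
    mol2 = build_molecule([("O.3", (0, 0, 0)), ("C.3", (1.4, 0, 0)),
                           ("H", (2.0, 0.8, 0))], bonds=[(0, 1), (1, 2)])
    assert assign_molecule(mol2)[0] == "A"


def test_hydrogens_are_not_labeled():
    mol = build_molecule([("O.3", (0, 0, 0)), ("H", (0.96, 0, 0))],
                         bonds=[(0, 1)])
    labels = assign_molecule(mol)
    assert labels[1] is None


def test_unmatched_heavy_atom_falls_back_to_polar():
    mol = build_molecule([("Se", (0, 0, 0)), ("C.3", (1.9, 0, 0))],
                         bonds=[(0, 1)])
    assert assign_molecule(mol)[0] == "PL"


def test_default_alphabet_contents():
    assert DEFAULT_ALPHABET == ("P", "N", "DA", "D", "A", "AR", "H", "PL",
                                "HA", "MI")
    assert len(set(DEFAULT_ALPHABET)) == 10
    labels_in_rules = {r.label for r in default_rules()}
    assert labels_in_rules == set(ALPHABET_9)


def test_count_labels_matches_per_atom_oracle():
    entries, bonds = _ring()
    entries += [("O.3", (4, 0, 0)), ("H", (4.8, 0.4, 0)), ("F", (0, 4, 0)),
                ("N.4", (6, 6, 6)), ("C.3", (7.5, 6, 6)), ("C.3", (6, 7.5, 6)),
                ("C.3", (6, 6, 7.5)), ("C.3", (4.5, 6, 6))]
    b0 = len(entries) - 5
    bonds = bonds + [(6, 7)] + [(b0, b0 + k) for k in range(1, 5)]
    mol = build_molecule(entries, bonds)
    labels = assign_molecule(mol)
    oracle = {}
    for lab in labels:
        if lab is not None:
            oracle[lab] = oracle.get(lab, 0) + 1
    counts = count_labels(mol)
    assert {k: v for k, v in counts.items() if v} == oracle
    assert sum(counts.values()) == sum(1 for a in mol.atoms if not a.is_hydrogen)


def test_empty_heavy_label_tally_is_zero():
    mol = build_molecule([("C.3", (0, 0, 0))])
    counts = count_labels(mol)
    assert sum(counts.values()) == 1  # single heavy atom, single label


def test_labels_invariant_under_atom_reordering():
    entries = [("C.ar", (0, 0, 0)), ("O.3", (2, 0, 0)), ("N.4", (0, 2, 0)),
               ("F", (2, 2, 0)), ("H", (2.8, 0.4, 0))]
    bonds = [(1, 4)]
    mol = build_molecule(entries, bonds)
    labels = assign_molecule(mol)
    perm = [3, 1, 4, 0, 2]  # new order of old indices
    entries_p = [entries[i] for i in perm]
    inv = {old: new for new, old in enumerate(perm)}
    bonds_p = [(inv[i], inv[j]) for i, j in bonds]
    mol_p = build_molecule(entries_p, bonds_p)
    labels_p = assign_molecule(mol_p)
    for new, old in enumerate(perm):
        assert labels_p[new] == labels[old]


@given(st.lists(st.sampled_from(
    ["C.3", "C.ar", "C.2", "N.3", "N.4", "N.am", "N.ar", "O.3", "O.2",
     "O.co2", "S.3", "P.3", "F", "Cl", "Br", "I", "Zn", "Na"]),
    min_size=1, max_size=12))
def test_every_heavy_atom_gets_exactly_one_label(types):
    entries = [(t, (3.0 * k, 0.0, 0.0)) for k, t in enumerate(types)]
    mol = build_molecule(entries)
    labels = assign_molecule(mol)
    assert len(labels) == len(types)
    assert all(l in DEFAULT_ALPHABET for l in labels)
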