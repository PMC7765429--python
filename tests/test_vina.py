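"""Vina energy terms: closed forms, pair sums vs oracle, rotatable bonds."""

import numpy as np
import pytest

from dockrf.pharmacophore import DEFAULT_ALPHABET
from dockrf.structures import Complex
from dockrf.vina import (count_rotatable_bonds, term_values, vina_features,
                         vina_radii)

from conftest import build_molecule, random_labeled_complex


@pytest.mark.parametrize("d,term,expected", [
    (0.0, 0, 1.0),          # gauss1 peaks at contact
    (3.0, 1, 1.0),          # gauss2 centred at 3 Å
    (0.0, 2, 0.0),          # no repulsion at or beyond contact
    (1.0, 2, 0.0),
    (-0.5, 2, 0.25),        # quadratic clash penalty
    (1.0, 3, 0.5),          # hydrophobic ramp midpoint
    (0.4, 3, 1.0),
    (1.6, 3, 0.0),
    (-0.35, 4, 0.5),        # hbond ramp midpoint
    (-0.8, 4, 1.0),
    (0.1, 4, 0.0),
])
def test_term_closed_forms(d, term, expected):
    assert term_values(d)[term] == pytest.approx(expected, abs=1e-12)


def test_gauss_terms_anywhere():
    for d in (-1.0, 0.3, 2.0, 5.5):
        g1, g2, *_ = term_values(d)
        assert g1 == pytest.approx(np.exp(-((d / 0.5) ** 2)))
        assert g2 == pytest.approx(np.exp(-(((d - 3.0) / 2.0) ** 2)))


def brute_force_vina(cplx, cutoff=8.0):
    radii = vina_radii()
    sums = np.zeros(5)
    for pa in cplx.protein.atoms:
        if pa.is_hydrogen:
            continue
        pl = cplx.protein.pharmacophores[pa.index]
        for la in cplx.ligand.atoms:
            if la.is_hydrogen:
                continue
            ll = cplx.ligand.pharmacophores[la.index]
            r = float(np.linalg.norm(pa.coords - la.coords))
            if r > cutoff:
                continue
            d = r - (radii[pa.element] + radii[la.element])
            g1, g2, rep, hyd, hb = term_values(d)
            sums[0] += g1
            sums[1] += g2
            sums[2] += rep
            p_hyd = pl == "H" or (pl == "AR" and pa.element == "C")
            l_hyd = ll == "H" or (ll == "AR" and la.element == "C")
            if p_hyd and l_hyd:
                sums[3] += hyd
            p_don, p_acc = pl in ("D", "DA"), pl in ("A", "DA")
            l_don, l_acc = ll in ("D", "DA"), ll in ("A", "DA")
            if (p_don and l_acc) or (p_acc and l_don):
                sums[4] += hb
    return sums


def test_single_hydrophobic_pair_hand_value():
    protein = build_molecule([("C.3", (0, 0, 0))], role="protein")
    ligand = build_molecule([("C.3", (4.0, 0, 0))], role="ligand")
    protein.pharmacophores = ["H"]
    ligand.pharmacophores = ["H"]
    feats = vina_features(Complex(protein, ligand))
    d = 4.0 - 2 * vina_radii()["C"]  # = 0.2 Å surface distance
    assert feats.gauss1 == pytest.approx(np.exp(-((d / 0.5) ** 2)))
    assert feats.repulsion == 0.0
    assert feats.hydrophobic == pytest.approx(1.0)  # d < 0.5 ramp plateau
    assert feats.hbond == 0.0


def test_beyond_cutoff_all_zero():
    protein = build_molecule([("C.3", (0, 0, 0))], role="protein")
    ligand = build_molecule([("O.3", (9.5, 0, 0))], role="ligand")
    protein.pharmacophores = ["DA"]
    ligand.pharmacophores = ["A"]
    feats = vina_features(Complex(protein, ligand))
    assert (feats.gauss1, feats.gauss2, feats.repulsion,
            feats.hydrophobic, feats.hbond) == (0, 0, 0, 0, 0)


@pytest.mark.parametrize("seed", [3, 17, 99])
def test_random_complex_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    cplx = random_labeled_complex(rng, 40, 10, DEFAULT_ALPHABET, spread=7.0)
    feats = vina_features(cplx)
    want = brute_force_vina(cplx)
    got = np.array(feats.as_tuple()[:5])
    np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)


def test_rigid_transform_invariance():
    rng = np.random.default_rng(23)
    cplx = random_labeled_complex(rng, 30, 8, DEFAULT_ALPHABET, spread=6.0)
    base = np.array(vina_features(cplx).as_tuple()[:5])
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = Complex(cplx.protein.transformed(q, (1, 2, 3)),
                    cplx.ligand.transformed(q, (1, 2, 3)))
    moved.protein.pharmacophores = cplx.protein.pharmacophores
    moved.ligand.pharmacophores = cplx.ligand.pharmacophores
    np.testing.assert_allclose(
        np.array(vina_features(moved).as_tuple()[:5]), base, rtol=1e-9)


def test_feature_count_is_six():
    rng = np.random.default_rng(1)
    cplx = random_labeled_complex(rng, 10, 4, DEFAULT_ALPHABET)
    cplx.ligand.torsdof = 4
    assert len(vina_features(cplx).as_tuple()) == 6


def test_torsdof_record_preferred_over_perception():
    rng = np.random.default_rng(2)
    cplx = random_labeled_complex(rng, 10, 4, DEFAULT_ALPHABET)
    cplx.ligand.torsdof = 7
    assert vina_features(cplx).n_rot == 7


def test_rotatable_bond_perception():
    # butane-like chain: only the central C-C bond rotates
    chain = build_molecule(
        [("C.3", (0, 0, 0)), ("C.3", (1.5, 0, 0)), ("C.3", (3.0, 0, 0)),
         ("C.3", (4.5, 0, 0))], bonds=[(0, 1), (1, 2), (2, 3)])
    assert count_rotatable_bonds(chain) == 1
    # benzene ring: no rotatable bonds
    ring = build_molecule(
        [("C.ar", (np.cos(k * np.pi / 3), np.sin(k * np.pi / 3), 0))
         for k in range(6)], bonds=[(k, (k + 1) % 6) for k in range(6)])
    assert count_rotatable_bonds(ring) == 0
    # N-methylacetamide-like: the amide bond is excluded
    amide = build_molecule(
        [("C.3", (0, 0, 0)), ("C.2", (1.5, 0, 0)), ("O.2", (2.1, 1.1, 0)),
         ("N.am", (2.2, -1.2, 0)), ("C.3", (3.7, -1.3, 0))],
        bonds=[(0, 1), (1, 2), (1, 3), (3, 4)])
    assert count_rotatable_bonds(amide) == 0
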