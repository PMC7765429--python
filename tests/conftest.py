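"""Shared fixtures: molecule builders and the planted-signal dataset."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dockrf.structures import Atom, Complex, Molecule

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def build_molecule(entries, bonds=(), role="ligand", torsdof=None) -> Molecule:
    """Molecule from (sybyl_type, xyz) entries plus bond index pairs."""
    atoms = []
    for i, (sybyl, xyz) in enumerate(entries):
        element = sybyl.split(".")[0].capitalize()
        atoms.append(Atom(i, element, sybyl, np.asarray(xyz, float),
                          is_hydrogen=(element == "H")))
    mol = Molecule(atoms, role=role, torsdof=torsdof)
    for i, j in bonds:
        mol.add_bond(i, j)
    return mol


def random_labeled_complex(rng: np.random.Generator, n_protein: int,
                           n_ligand: int, alphabet, spread: float = 12.0
                           ) -> Complex:
    """Random typed point clouds with labels assigned directly (no rules)."""
    def cloud(n, role, center):
        entries = [("C.3", center + rng.uniform(-spread, spread, 3))
                   for _ in range(n)]
        mol = build_molecule(entries, role=role)
        mol.pharmacophores = list(rng.choice(alphabet, size=n))
        return mol

    return Complex(cloud(n_protein, "protein", np.zeros(3)),
                   cloud(n_ligand, "ligand", rng.uniform(-6, 6, 3)))


@pytest.fixture(scope="session")
def planted_dataset():
    """The n = 500 planted-signal study set (fixed seed), featurized once."""
    from dockrf.synthetic import SyntheticSpec, generate
    return generate(SyntheticSpec(n_complexes=500, seed=1))


@pytest.fixture(scope="session")
def planted_holdout(planted_dataset):
    """Default RF trained on a fixed 80:20 split of the planted set."""
    from dockrf.metrics import evaluate
    from dockrf.models import TrainingSet, train

    ds = planted_dataset
    rng = np.random.default_rng(2024)
    idx = rng.permutation(len(ds))
    tr, te = idx[:400], idx[400:]
    model = train(TrainingSet(ds.features.iloc[tr], ds.labels[tr]), seed=1)
    report = evaluate(model.predict_frame(ds.features.iloc[te]), ds.labels[te])
    return {"model": model, "report": report, "train_idx": tr, "test_idx": te}
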