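"""Feature assembly: contact shells + Vina terms + SASA deltas.

The raw vector concatenates the three classes in fixed order
``[phCo | Vina | SASA]`` — by default 900 + 6 + 3 = 909 entries — and the
ordered feature names are hashed into a schema identifier that trained
models refuse to mismatch.  Zero-variance filtering reproduces the training
protocol in which never-observed contact bins are dropped before fitting.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ShellConfig, count_contacts, prepare_complex
from .pharmacophore import ALPHABET_9, DEFAULT_ALPHABET
from .sasa import DEFAULT_PROBE, DEFAULT_SLICE_SPACING, sasa_features
from .structures import Complex
from .vina import DEFAULT_CUTOFF, vina_features

FEATURE_CLASSES = ("phCo", "Vina", "SASA")

VINA_FEATURE_NAMES = ("vina_gauss1", "vina_gauss2", "vina_repulsion",
                      "vina_hydrophobic", "vina_hbond", "vina_nrot")
SASA_FEATURE_NAMES = ("dsasa_protein", "dsasa_ligand", "csa")


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature classes to compute and with which parameters."""

    classes: tuple[str, ...] = FEATURE_CLASSES
    shell: ShellConfig = field(default_factory=ShellConfig)
    include_metal_label: bool = True
    probe: float = DEFAULT_PROBE
    slice_spacing: float = DEFAULT_SLICE_SPACING
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if not self.classes:
            raise ValueError("at least one feature class required")

    @property
    def alphabet(self) -> tuple[str, ...]:
        return DEFAULT_ALPHABET if self.include_metal_label else ALPHABET_9


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("schema length != value length")


@dataclass
class FeatureMask:
    """Indices kept by a feature filter, with provenance."""

    kept_indices: np.ndarray
    provenance: str = ""

    def apply_values(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values)[..., self.kept_indices]

    def apply_names(self, names: Sequence[str]) -> tuple[str, ...]:
        return tuple(names[i] for i in self.kept_indices)


def feature_names(config: FeatureConfig = FeatureConfig()) -> tuple[str, ...]:
    """Ordered schema for a configuration."""
    from .contacts import contact_feature_names
    names: list[str] = []
    if "phCo" in config.classes:
        names.extend(contact_feature_names(config.alphabet,
                                           config.shell.n_shells))
    if "Vina" in config.classes:
        names.extend(VINA_FEATURE_NAMES)
    if "SASA" in config.classes:
        names.extend(SASA_FEATURE_NAMES)
    return tuple(names)


def schema_hash(names: Sequence[str]) -> str:
    """Stable identifier of an ordered feature schema."""
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


def featurize_complex(cplx: Complex,
                      config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Compute the full feature vector for one protein–ligand pose."""
    prepare_complex(cplx, alphabet=config.alphabet)
    parts: list[np.ndarray] = []
    if "phCo" in config.classes:
        parts.append(count_contacts(cplx, config.shell, config.alphabet)
                     .counts.astype(np.float64))
    if "Vina" in config.classes:
        parts.append(np.array(vina_features(cplx, config.cutoff).as_tuple(),
                              dtype=np.float64))
    if "SASA" in config.classes:
        sf = sasa_features(cplx, config.probe, config.slice_spacing)
        parts.append(np.array([sf.dsasa_protein, sf.dsasa_ligand, sf.csa]))
    return FeatureVector(np.concatenate(parts), feature_names(config))


def featurize_many(complexes: Sequence[Complex],
                   config: FeatureConfig = FeatureConfig(),
                   ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Feature matrix for a list of complexes (rows in input order)."""
    names = feature_names(config)
    rows = [featurize_complex(c, config).values for c in complexes]
    idx = list(ids) if ids is not None else list(range(len(complexes)))
    return pd.DataFrame(np.vstack(rows) if rows else
                        np.zeros((0, len(names))), index=idx, columns=names)


def variance_filter(matrix: np.ndarray | pd.DataFrame,
                    dataset_id: str = "training set") -> FeatureMask:
    """Drop zero-variance columns; errors if every column is constant."""
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("variance filter needs a 2-D matrix with >= 2 rows")
    keep = np.flatnonzero(X.var(axis=0) > 0.0)
    if keep.size == 0:
        raise ValueError("all feature columns are constant")
    return FeatureMask(keep, provenance=f"zero-variance filter on {dataset_id}")
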