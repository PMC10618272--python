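"""Molecular featurization: count fingerprints + 2D descriptors, normalized.

The model input is a 2048-dimensional count-based extended-connectivity
fingerprint (radius 2) concatenated with a fixed panel of 2D descriptors.
The default panel is the toolkit's full 2D descriptor catalogue minus the
substructure-fragment counters (``fr_*``), frozen as an explicit name list
so a spec is reproducible across runs.  Features are standardized
(per-feature mean/scale) with statistics fitted on training molecules only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .errors import NotFittedError, ParseError

logger = logging.getLogger(__name__)

_DESC_FUNCS = dict(Descriptors.descList)

#: Default descriptor panel: every 2D descriptor except fragment counters.
DEFAULT_DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    name for name, _ in Descriptors.descList if not name.startswith("fr_"))


@dataclass
class FeaturizerSpec:
    """Featurization parameters plus (after fit) normalization statistics."""

    fp_radius: int = 2
    fp_size: int = 2048
    descriptor_names: tuple[str, ...] = DEFAULT_DESCRIPTOR_NAMES
    center: np.ndarray | None = None   # per-feature mean, length n_features
    scale: np.ndarray | None = None    # per-feature std; 1.0 where constant

    def __post_init__(self) -> None:
        self.descriptor_names = tuple(self.descriptor_names)
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor_names contains duplicates")
        unknown = [n for n in self.descriptor_names if n not in _DESC_FUNCS]
        if unknown:
            raise ValueError(f"unknown descriptors: {unknown}")

    @property
    def n_features(self) -> int:
        return self.fp_size + len(self.descriptor_names)

    @property
    def fitted(self) -> bool:
        return self.center is not None

    def to_json(self) -> str:
        return json.dumps({
            "fp_radius": self.fp_radius, "fp_size": self.fp_size,
            "descriptor_names": list(self.descriptor_names),
            "center": None if self.center is None else self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
        })

    @classmethod
    def from_json(cls, payload: str) -> "FeaturizerSpec":
        d = json.loads(payload)
        return cls(
            fp_radius=d["fp_radius"], fp_size=d["fp_size"],
            descriptor_names=tuple(d["descriptor_names"]),
            center=None if d["center"] is None else np.asarray(d["center"]),
            scale=None if d["scale"] is None else np.asarray(d["scale"]))


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles:
        raise ParseError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def fingerprint_counts(smiles: str, spec: FeaturizerSpec | None = None) -> np.ndarray:
    """Hashed circular-environment counts folded to ``fp_size`` dimensions.

    Invariant to SMILES atom ordering (fingerprints hash canonical atom
    environments, not the input string).
    """
    spec = spec or FeaturizerSpec()
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=spec.fp_radius, fpSize=spec.fp_size)
    return gen.GetCountFingerprintAsNumPy(mol).astype(np.float64)


def descriptors_2d(smiles: str, spec: FeaturizerSpec | None = None) -> np.ndarray:
    """Descriptor panel values in spec order.

    A descriptor that fails or returns a non-finite value is imputed to 0
    with a logged warning; featurization never crashes on one bad descriptor.
    """
    spec = spec or FeaturizerSpec()
    mol = _mol_from_smiles(smiles)
    out = np.zeros(len(spec.descriptor_names))
    for i, name in enumerate(spec.descriptor_names):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = float(_DESC_FUNCS[name](mol))
        except Exception:
            logger.warning("descriptor %s failed on %s; imputed 0", name, smiles)
            continue
        if np.isfinite(val):
            out[i] = val
        else:
            logger.warning("descriptor %s non-finite on %s; imputed 0", name, smiles)
    return out


def raw_features(smiles_list: Sequence[str],
                 spec: FeaturizerSpec | None = None) -> np.ndarray:
    """Unnormalized (fingerprint, descriptor) matrix, one row per molecule."""
    spec = spec or FeaturizerSpec()
    rows = [np.concatenate([fingerprint_counts(s, spec), descriptors_2d(s, spec)])
            for s in smiles_list]
    return np.vstack(rows)


class Featurizer:
    """Fits normalization statistics on training molecules and transforms.

    Transformed training features have per-feature mean ~0 and unit scale;
    constant features map to exactly 0.  Fit before transform, and reuse the
    same fitted instance at inference to avoid leakage.
    """

    def __init__(self, spec: FeaturizerSpec | None = None):
        self.spec = spec or FeaturizerSpec()

    @property
    def fitted(self) -> bool:
        return self.spec.fitted

    def fit(self, smiles_list: Sequence[str]) -> "Featurizer":
        if len(smiles_list) < 2:
            raise ValueError("fit requires at least 2 molecules")
        X = raw_features(smiles_list, self.spec)
        self.spec.center = X.mean(axis=0)
        std = X.std(axis=0)
        self.spec.scale = np.where(std > 0, std, 1.0)
        return self

    def transform(self, smiles_or_matrix) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("transform called before fit")
        if isinstance(smiles_or_matrix, np.ndarray):
            X = np.atleast_2d(smiles_or_matrix)
        else:
            X = raw_features(list(smiles_or_matrix), self.spec)
        Z = (X - self.spec.center) / self.spec.scale
        bad = ~np.isfinite(Z)
        if bad.any():
            logger.warning("%d non-finite feature values imputed to 0", bad.sum())
            Z = np.where(bad, 0.0, Z)
        return Z

    def fit_transform(self, smiles_list: Sequence[str]) -> np.ndarray:
        return self.fit(smiles_list).transform(smiles_list)
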