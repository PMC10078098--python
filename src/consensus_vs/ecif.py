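"""Extended-connectivity interaction features and affinity regression.

Each heavy atom is typed by (element, valence, heavy degree, attached H,
aromaticity, ring membership); the feature vector of a complex counts typed
protein-atom/ligand-atom pairs within a distance cutoff (default 6.0 Å,
inclusive).  A pluggable regressor (ridge or gradient boosting) maps feature
vectors to predicted pKi.  No pre-trained weights ship with the package —
the mechanism, not a particular model, is the deliverable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.distance import cdist
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import Ridge

from .chem_core import Atom, Molecule
from .errors import ContractViolationError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 6.0  # Å, inclusive


@dataclass(frozen=True)
class EcifAtomType:
    element: str
    explicit_valence: int
    heavy_degree: int
    attached_h: int
    is_aromatic: bool
    in_ring: bool

    def __str__(self) -> str:
        return (
            f"{self.element};{self.explicit_valence};{self.heavy_degree};"
            f"{self.attached_h};{str(self.is_aromatic).lower()};"
            f"{str(self.in_ring).lower()}"
        )


@dataclass(frozen=True)
class EcifVector:
    counts: dict[str, int] = field(default_factory=dict)  # "p_type|l_type" -> n
    cutoff: float = DEFAULT_CUTOFF

    def total(self) -> int:
        return sum(self.counts.values())


def ecif_atom_type(atom: Atom) -> EcifAtomType:
    """Type tuple for one heavy atom; hydrogens are never typed."""
    if atom.element == "H":
        raise ContractViolationError("hydrogens are not typed")
    return EcifAtomType(
        element=atom.element,
        explicit_valence=atom.explicit_valence,
        heavy_degree=atom.heavy_degree,
        attached_h=atom.attached_h,
        is_aromatic=atom.is_aromatic,
        in_ring=atom.in_ring,
    )


def _typed_heavy_atoms(mol: Molecule) -> tuple[list[str], np.ndarray]:
    coords = mol.coords
    if coords is None:
        raise ContractViolationError(f"molecule {mol.id!r} has no coordinates")
    types, points = [], []
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H":
            continue
        types.append(str(ecif_atom_type(atom)))
        points.append(coords[i])
    return types, np.asarray(points, dtype=float)


def load_protein(pdb_path) -> Molecule:
    """Protein molecule with bonds perceived from residue templates/proximity.

    Nonstandard or unparseable content degrades gracefully: the toolkit
    leaves such atoms unbonded, which still yields a valid (if coarse) type.
    """
    rdmol = Chem.MolFromPDBFile(str(pdb_path), removeHs=True, sanitize=True)
    if rdmol is None:
        rdmol = Chem.MolFromPDBFile(str(pdb_path), removeHs=True, sanitize=False)
        if rdmol is None:
            raise ContractViolationError(f"cannot read protein PDB {pdb_path}")
        logger.warning("protein %s loaded without sanitization", pdb_path)
        Chem.SanitizeMol(rdmol, Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
    return Molecule(id=str(pdb_path), rdmol=rdmol, source="pdb_ligand")


def ecif_features(
    protein: Molecule, ligand: Molecule, cutoff: float = DEFAULT_CUTOFF
) -> EcifVector:
    """Counts of typed (protein atom, ligand atom) pairs within ``cutoff`` Å."""
    lig_types, lig_pts = _typed_heavy_atoms(ligand)
    if not lig_types:
        raise ContractViolationError("empty ligand")
    prot_types, prot_pts = _typed_heavy_atoms(protein)
    if not prot_types:
        raise ContractViolationError("empty protein")
    dists = cdist(prot_pts, lig_pts)
    counts: dict[str, int] = {}
    for pi, li in zip(*np.nonzero(dists <= cutoff)):
        key = f"{prot_types[pi]}|{lig_types[li]}"
        counts[key] = counts.get(key, 0) + 1
    return EcifVector(counts=counts, cutoff=cutoff)


@dataclass
class AffinityModel:
    kind: str  # linear_ridge | gradient_boosting
    cutoff: float
    feature_keys: tuple[str, ...]  # frozen sorted ordering
    estimator: object

    def vector_to_array(self, vector: EcifVector) -> np.ndarray:
        # unseen type-pairs contribute zero
        return np.array(
            [vector.counts.get(k, 0) for k in self.feature_keys], dtype=float
        )


def fit_affinity_model(
    vectors: Sequence[EcifVector],
    pki: Sequence[float],
    model_kind: str = "linear_ridge",
    seed: int = 0,
    ridge_alpha: float = 1e-8,
) -> AffinityModel:
    """Fit a regressor on feature vectors; deterministic under a fixed seed."""
    if len(vectors) < 10:
        raise ContractViolationError("need >= 10 training pairs")
    if len(vectors) != len(pki):
        raise ContractViolationError("vectors and pki lengths differ")
    cutoffs = {v.cutoff for v in vectors}
    if len(cutoffs) != 1:
        raise ContractViolationError(f"inconsistent cutoffs: {sorted(cutoffs)}")
    cutoff = cutoffs.pop()
    keys = tuple(sorted(set().union(*(v.counts.keys() for v in vectors))))
    X = np.array([[v.counts.get(k, 0) for k in keys] for v in vectors], dtype=float)
    y = np.asarray(pki, dtype=float)
    if model_kind == "linear_ridge":
        est = Ridge(alpha=ridge_alpha, random_state=seed)
    elif model_kind == "gradient_boosting":
        est = GradientBoostingRegressor(random_state=seed)
    else:
        raise ContractViolationError(f"unknown model kind {model_kind!r}")
    est.fit(X, y)
    return AffinityModel(kind=model_kind, cutoff=cutoff, feature_keys=keys, estimator=est)


def predict_pki(model: AffinityModel, vector: EcifVector) -> float:
    if abs(vector.cutoff - model.cutoff) > 1e-12:
        raise ContractViolationError(
            f"vector cutoff {vector.cutoff} != model cutoff {model.cutoff}"
        )
    return float(model.estimator.predict(model.vector_to_array(vector)[None, :])[0])


def vector_to_frame(vector: EcifVector) -> pd.DataFrame:
    """Sparse export: one row per (protein type, ligand type) pair."""
    rows = [
        (*key.split("|"), count) for key, count in sorted(vector.counts.items())
    ]
    return pd.DataFrame(rows, columns=["p_type", "l_type", "count"])
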