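"""Docking post-processing (funnel criterion 2).

External docking engines supply raw scores and poses; this stage normalizes
scores by heavy-atom count (ligand-efficiency style, removing the size bias
of score-based ranking), filters against a reference-calibrated cutoff, and
checks distance contacts against the key residues of the colchicine site in
single poses or multi-frame ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from ._util import round_half_away
from .chem_core import Molecule, heavy_atom_count
from .errors import ContractViolationError, FormatError

logger = logging.getLogger(__name__)

#: Reference ligand of the binding site (registry structure, C22H25NO6).
COLCHICINE_SMILES = "CC(=O)N[C@@H]1CCc2cc(OC)c(OC)c(OC)c2-c2ccc(OC)c(=O)cc21"

#: Key contact residues of the two reference ligands of the site.
KEY_RESIDUES = {
    "colchicine": ["Ala 180", "Val 181", "Cys 241", "Met 259", "Ala 316"],
    "dj101": ["Val 181", "Val 236", "Leu 246", "Asn 247", "Asn 347", "Lys 350"],
}

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, heavy-atom minimum distance, inclusive


@dataclass(frozen=True)
class DockingRecord:
    compound_id: str
    raw_score: float  # engine units, lower = better
    n_heavy: int
    pose_ref: Optional[str] = None

    @property
    def normalized_score(self) -> float:
        return normalize_score(self.raw_score, self.n_heavy)


@dataclass(frozen=True)
class ProteinAtom:
    element: str
    coord: tuple[float, float, float]
    chain: str
    residue_name: str
    residue_number: int

    @property
    def residue_id(self) -> str:
        return f"{self.residue_name.capitalize()} {self.residue_number}"


@dataclass(frozen=True)
class ComplexStructure:
    protein_atoms: tuple[ProteinAtom, ...]
    ligand_atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    frame_index: int = 0


@dataclass(frozen=True)
class ContactProfile:
    compound_id: str
    contacts: Mapping[str, float]  # residue id -> fraction of frames in contact
    n_frames: int


def normalize_score(raw_score: float, n_heavy: int) -> float:
    """raw_score / n_heavy. Full precision; round only in reports."""
    if n_heavy < 1:
        raise ContractViolationError(f"n_heavy must be >= 1, got {n_heavy}")
    return raw_score / n_heavy


def normalized_score_rounded(raw_score: float, n_heavy: int, ndigits: int = 3) -> float:
    """Report form of the normalized score (half-away-from-zero rounding)."""
    return round_half_away(normalize_score(raw_score, n_heavy), ndigits)


def read_score_table(path, molecules: Sequence[Molecule]) -> list[DockingRecord]:
    """Load a docking score CSV and join heavy-atom counts from the library.

    Expects columns ``compound_id, raw_score``.  Unknown ids are logged and
    excluded; duplicate ids keep the best (lowest) raw score.
    """
    df = pd.read_csv(path)
    missing = {"compound_id", "raw_score"} - set(df.columns)
    if missing:
        raise FormatError(f"score table missing columns: {sorted(missing)}")
    by_id = {m.id: m for m in molecules}
    records: dict[str, DockingRecord] = {}
    for row in df.itertuples(index=False):
        cid = str(row.compound_id)
        mol = by_id.get(cid)
        if mol is None:
            logger.warning("score table id %r not in library; excluded", cid)
            continue
        rec = DockingRecord(
            compound_id=cid,
            raw_score=float(row.raw_score),
            n_heavy=heavy_atom_count(mol),
            pose_ref=str(getattr(row, "pose_ref", "")) or None,
        )
        prev = records.get(cid)
        if prev is not None:
            logger.warning("duplicate score rows for %r; keeping best", cid)
            if rec.raw_score >= prev.raw_score:
                continue
        records[cid] = rec
    return list(records.values())


def docking_hits(
    records: Sequence[DockingRecord], reference: DockingRecord
) -> set[str]:
    """Ids with normalized score equal to or lower than the reference's."""
    cutoff = reference.normalized_score
    return {r.compound_id for r in records if r.normalized_score <= cutoff}


def read_complex_pdb(path, ligand_resnames: Optional[set[str]] = None) -> list[ComplexStructure]:
    """Parse a (possibly multi-MODEL) PDB into per-frame complex structures.

    Heteroatom residues (other than water) form the ligand; everything else
    is protein.  ``ligand_resnames`` restricts which residue names count as
    ligand when given.
    """
    structure = PDBParser(QUIET=True).get_structure("complex", str(path))
    frames = []
    for frame_index, model in enumerate(structure):
        protein: list[ProteinAtom] = []
        ligand: list[tuple[str, tuple[float, float, float]]] = []
        for chain in model:
            for res in chain:
                hetflag = res.id[0]
                resname = res.get_resname().strip()
                if resname in ("HOH", "WAT"):
                    continue
                is_ligand = (
                    resname in ligand_resnames
                    if ligand_resnames is not None
                    else hetflag.startswith("H_")
                )
                for atom in res:
                    element = (atom.element or "").strip().capitalize() or "C"
                    coord = tuple(float(c) for c in atom.coord)
                    if is_ligand:
                        ligand.append((element, coord))
                    else:
                        protein.append(
                            ProteinAtom(
                                element=element,
                                coord=coord,
                                chain=chain.id,
                                residue_name=resname,
                                residue_number=int(res.id[1]),
                            )
                        )
        frames.append(
            ComplexStructure(
                protein_atoms=tuple(protein),
                ligand_atoms=tuple(ligand),
                frame_index=frame_index,
            )
        )
    return frames


def detect_contacts(
    complex: ComplexStructure, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> set[str]:
    """Residues with any heavy atom within ``cutoff`` Å of any ligand heavy atom.

    Euclidean minimum distance, inclusive boundary.
    """
    lig = [c for el, c in complex.ligand_atoms if el != "H"]
    if not lig:
        raise ContractViolationError("empty ligand")
    prot = [a for a in complex.protein_atoms if a.element != "H"]
    if not prot:
        raise ContractViolationError("empty protein")
    dists = cdist(np.array([a.coord for a in prot]), np.array(lig))
    mins = dists.min(axis=1)
    return {a.residue_id for a, d in zip(prot, mins) if d <= cutoff}


def contact_persistence(
    frames: Sequence[ComplexStructure],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    compound_id: str = "",
) -> ContactProfile:
    """Fraction of frames in which each residue is in contact.

    All frames are weighted equally; dropping equilibration burn-in is the
    caller's responsibility.
    """
    if not frames:
        raise ContractViolationError("need >= 1 frame")
    residue_tables = [
        {(a.chain, a.residue_number, a.residue_name) for a in f.protein_atoms}
        for f in frames
    ]
    if any(t != residue_tables[0] for t in residue_tables[1:]):
        raise ContractViolationError("inconsistent residue tables across frames")
    counts: dict[str, int] = {}
    for frame in frames:
        for rid in detect_contacts(frame, cutoff):
            counts[rid] = counts.get(rid, 0) + 1
    n = len(frames)
    return ContactProfile(
        compound_id=compound_id,
        contacts={rid: c / n for rid, c in counts.items()},
        n_frames=n,
    )


def key_interaction_check(
    profile: ContactProfile,
    key_set: Sequence[str],
    min_matches: int = 3,
    min_fraction: float = 0.0,
) -> tuple[int, bool]:
    """Count key residues contacted above ``min_fraction``; pass at >= min_matches."""
    if not key_set:
        raise ContractViolationError("key_set must be nonempty")
    n_matched = sum(
        1 for rid in key_set if profile.contacts.get(rid, 0.0) > min_fraction
    )
    return n_matched, n_matched >= min_matches


def records_to_frame(records: Sequence[DockingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.compound_id,
                r.raw_score,
                r.n_heavy,
                normalized_score_rounded(r.raw_score, r.n_heavy),
            )
            for r in records
        ],
        columns=["compound_id", "raw_score", "n_heavy", "normalized_score"],
    )


def profile_to_frame(profile: ContactProfile) -> pd.DataFrame:
    rows = [
        (profile.compound_id, rid, frac)
        for rid, frac in sorted(profile.contacts.items())
    ]
    return pd.DataFrame(rows, columns=["compound_id", "residue", "fraction"])
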