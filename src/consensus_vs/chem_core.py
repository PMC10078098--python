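"""Core chemical structure handling.

Molecules are backed by RDKit for parsing, aromaticity perception and
canonicalization, and exposed through a small frozen view layer (:class:`Atom`,
:class:`Bond`) so downstream stages can reason about atoms without touching
the toolkit directly.  All parsing normalizes to implicit hydrogens: heavy-atom
operations never depend on the explicit-H representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import MoleculeParseError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

_BOND_ORDERS = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class Atom:
    """Perceived attributes of one heavy atom (or explicit H)."""

    element: str
    formal_charge: int
    is_aromatic: bool
    in_ring: bool
    explicit_valence: int
    attached_h: int
    heavy_degree: int


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: str


@dataclass(frozen=True)
class ScaffoldKey:
    """Canonical Bemis-Murcko framework; equality is string equality.

    Acyclic molecules have an empty framework and are flagged so the
    diversity stage can treat each one as its own class.
    """

    canonical_form: str
    is_empty: bool


@dataclass(frozen=True)
class DescriptorSet:
    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    tpsa: float


@dataclass
class Molecule:
    """A screened structure: id + perceived RDKit mol + provenance tag."""

    id: str
    rdmol: Chem.Mol
    source: str = "smiles"
    _atoms: Optional[list[Atom]] = field(default=None, repr=False, compare=False)

    @property
    def atoms(self) -> list[Atom]:
        if self._atoms is None:
            self._atoms = [_perceive_atom(a) for a in self.rdmol.GetAtoms()]
        return self._atoms

    @property
    def bonds(self) -> list[Bond]:
        return [
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDERS[b.GetBondType()])
            for b in self.rdmol.GetBonds()
        ]

    @property
    def coords(self) -> Optional[list[tuple[float, float, float]]]:
        if self.rdmol.GetNumConformers() == 0:
            return None
        conf = self.rdmol.GetConformer()
        return [tuple(conf.GetAtomPosition(i)) for i in range(self.rdmol.GetNumAtoms())]

    def __len__(self) -> int:
        return self.rdmol.GetNumAtoms()


def _perceive_atom(a: Chem.Atom) -> Atom:
    return Atom(
        element=a.GetSymbol(),
        formal_charge=a.GetFormalCharge(),
        is_aromatic=a.GetIsAromatic(),
        in_ring=a.IsInRing(),
        explicit_valence=a.GetTotalValence(),
        attached_h=a.GetTotalNumHs(),
        heavy_degree=sum(1 for n in a.GetNeighbors() if n.GetAtomicNum() > 1),
    )


def parse_smiles(text: str, id: str) -> Molecule:
    """Parse one SMILES record into a perceived :class:`Molecule`.

    Raises :class:`MoleculeParseError` naming the record on failure so batch
    callers can log and skip without aborting.
    """
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise MoleculeParseError(id, f"invalid SMILES {text!r}")
    return Molecule(id=id, rdmol=rdmol, source="smiles")


def parse_smiles_file(path) -> list[Molecule]:
    """Read a SMILES file (one record per line, optional tab-separated id).

    Unparsable lines are logged and skipped; ids default to LIB-<lineno>.
    """
    out: list[Molecule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"LIB-{lineno}"
            try:
                out.append(parse_smiles(smiles, mol_id))
            except MoleculeParseError as exc:
                logger.warning("skipping line %d: %s", lineno, exc)
    return out


def parse_sdf(path) -> list[Molecule]:
    """Read an SDF (MOL V2000) file; 3D coordinates are retained.

    Malformed records are logged with their index and skipped; record
    order is preserved.
    """
    out: list[Molecule] = []
    with open(path) as fh:
        if not fh.read().strip():
            return out
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            logger.warning("skipping malformed SDF record %d in %s", i, path)
            continue
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        out.append(Molecule(id=name or f"SDF-{i}", rdmol=rdmol, source="sdf"))
    return out


def write_smiles(mol: Molecule) -> str:
    """Canonical SMILES for a molecule (toolkit canonical ordering)."""
    return Chem.MolToSmiles(mol.rdmol)


def write_smiles_file(molecules: Sequence[Molecule], path) -> None:
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{write_smiles(mol)}\t{mol.id}\n")


def write_sdf(molecules: Sequence[Molecule], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for mol in molecules:
            rdmol = Chem.Mol(mol.rdmol)
            rdmol.SetProp("_Name", mol.id)
            writer.write(rdmol)
    finally:
        writer.close()


def heavy_atom_count(mol: Molecule) -> int:
    """Number of non-hydrogen atoms."""
    return mol.rdmol.GetNumHeavyAtoms()


def bemis_murcko_scaffold(mol: Molecule) -> ScaffoldKey:
    """Bemis-Murcko framework: ring systems plus linkers, side chains pruned.

    Acyclic molecules yield an empty key with ``is_empty=True``.
    """
    core = MurckoScaffold.GetScaffoldForMol(mol.rdmol)
    smiles = Chem.MolToSmiles(core) if core is not None else ""
    return ScaffoldKey(canonical_form=smiles, is_empty=(smiles == ""))


def _is_hb_donor(atom: Chem.Atom) -> bool:
    # donor convention: N or O bearing at least one H
    return atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() >= 1


def _is_hb_acceptor(atom: Chem.Atom) -> bool:
    # acceptor convention: any N or O not positively charged
    return atom.GetAtomicNum() in (7, 8) and atom.GetFormalCharge() <= 0


def basic_descriptors(mol: Molecule) -> DescriptorSet:
    """Deterministic physchem descriptors feeding the drug-likeness rules.

    logP is the Wildman-Crippen atom-contribution estimate (coefficients
    published with the toolkit); donors/acceptors follow the N/O conventions
    documented on :func:`_is_hb_donor` / :func:`_is_hb_acceptor`.
    """
    rdmol = mol.rdmol
    return DescriptorSet(
        mw=Descriptors.MolWt(rdmol),
        logp=Crippen.MolLogP(rdmol),
        hbd=sum(1 for a in rdmol.GetAtoms() if _is_hb_donor(a)),
        hba=sum(1 for a in rdmol.GetAtoms() if _is_hb_acceptor(a)),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(rdmol),
        tpsa=Descriptors.TPSA(rdmol),
    )


def aromatic_proportion(mol: Molecule) -> float:
    """Aromatic heavy atoms / total heavy atoms (used by the solubility model)."""
    n_heavy = heavy_atom_count(mol)
    if n_heavy == 0:
        return 0.0
    n_arom = sum(
        1
        for a in mol.rdmol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() > 1
    )
    return n_arom / n_heavy


def iter_heavy_atoms(mol: Molecule) -> Iterator[tuple[int, Atom]]:
    for i, atom in enumerate(mol.atoms):
        if atom.element != "H":
            yield i, atom
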