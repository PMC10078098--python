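"""Dual-fingerprint Tanimoto screening (funnel criterion 1).

Every library molecule is compared against every reference active with two
complementary fingerprints — 166-bit structural keys and a radius-2 circular
fingerprint — and a compound is a hit when, for at least one reference, BOTH
similarities exceed their consensus cutoff (median plus one sample standard
deviation of the pooled pairwise distribution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chem_core import Molecule
from .errors import ContractViolationError

FingerprintKind = Literal["structural_keys_166", "circular_r2"]

STRUCTURAL_KEYS = "structural_keys_166"
CIRCULAR = "circular_r2"

_N_STRUCTURAL_KEYS = 166


@dataclass(frozen=True)
class Fingerprint:
    kind: str
    bits: frozenset[int]
    nbits: int

    def __post_init__(self):
        if self.kind == STRUCTURAL_KEYS and self.nbits != _N_STRUCTURAL_KEYS:
            raise ContractViolationError("structural keys are 166 bits wide")
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ContractViolationError("bit position out of range")


@dataclass(frozen=True)
class SimilarityRecord:
    library_id: str
    reference_id: str
    t_skey: float
    t_circ: float


@dataclass(frozen=True)
class SimilarityThresholds:
    thr_skey: float
    thr_circ: float
    n_pairs: int


def compute_fingerprint(
    mol: Molecule, kind: str, nbits_circular: int = 2048
) -> Fingerprint:
    """Deterministic bit-set fingerprint of the requested kind.

    Structural keys use the 166-key public dictionary (toolkit bit 0 is a
    placeholder and is dropped, shifting keys to 0..165).  The circular
    fingerprint hashes radius-2 atom neighborhoods ("diameter 4") into
    ``nbits_circular`` positions.
    """
    if kind == STRUCTURAL_KEYS:
        bv = MACCSkeys.GenMACCSKeys(mol.rdmol)  # 167 bits, bit 0 unused
        return Fingerprint(
            kind=kind,
            bits=frozenset(b - 1 for b in bv.GetOnBits()),
            nbits=_N_STRUCTURAL_KEYS,
        )
    if kind == CIRCULAR:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=nbits_circular
        )
        bv = gen.GetFingerprint(mol.rdmol)
        return Fingerprint(kind=kind, bits=frozenset(bv.GetOnBits()), nbits=nbits_circular)
    raise ContractViolationError(f"unknown fingerprint kind {kind!r}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B|; 0.0 when both bit sets are empty."""
    if a.kind != b.kind or a.nbits != b.nbits:
        raise ContractViolationError(
            f"fingerprint mismatch: {a.kind}/{a.nbits} vs {b.kind}/{b.nbits}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def similarity_matrix(
    library: Sequence[Molecule],
    references: Sequence[Molecule],
    nbits_circular: int = 2048,
) -> list[SimilarityRecord]:
    """All |library| × |references| pairwise records, both fingerprint kinds."""
    if not library or not references:
        raise ContractViolationError("library and references must be nonempty")
    lib_fps = [
        (
            m.id,
            compute_fingerprint(m, STRUCTURAL_KEYS),
            compute_fingerprint(m, CIRCULAR, nbits_circular),
        )
        for m in library
    ]
    ref_fps = [
        (
            m.id,
            compute_fingerprint(m, STRUCTURAL_KEYS),
            compute_fingerprint(m, CIRCULAR, nbits_circular),
        )
        for m in references
    ]
    records = []
    for lid, ls, lc in lib_fps:
        for rid, rs, rc in ref_fps:
            records.append(
                SimilarityRecord(
                    library_id=lid,
                    reference_id=rid,
                    t_skey=tanimoto(ls, rs),
                    t_circ=tanimoto(lc, rc),
                )
            )
    return records


def consensus_thresholds(
    records: Sequence[SimilarityRecord], sd_ddof: int = 1
) -> SimilarityThresholds:
    """Median + one standard deviation per fingerprint kind, pooled over pairs.

    Sample SD (denominator n−1) by default; requires at least 2 records.
    """
    if len(records) < 2:
        raise ContractViolationError("need >= 2 records to define a threshold")
    skey = np.array([r.t_skey for r in records], dtype=float)
    circ = np.array([r.t_circ for r in records], dtype=float)
    return SimilarityThresholds(
        thr_skey=float(np.median(skey) + np.std(skey, ddof=sd_ddof)),
        thr_circ=float(np.median(circ) + np.std(circ, ddof=sd_ddof)),
        n_pairs=len(records),
    )


def similarity_hits(
    records: Iterable[SimilarityRecord],
    thresholds: SimilarityThresholds,
    consensus_mode: str = "same_reference",
) -> set[str]:
    """Library ids passing the dual-threshold consensus (strict '>').

    ``same_reference`` (default) requires both fingerprint conditions to hold
    against one and the same reference; ``any_reference`` lets each condition
    be satisfied by different references.
    """
    if consensus_mode == "same_reference":
        return {
            r.library_id
            for r in records
            if r.t_skey > thresholds.thr_skey and r.t_circ > thresholds.thr_circ
        }
    if consensus_mode == "any_reference":
        skey_ok = set()
        circ_ok = set()
        for r in records:
            if r.t_skey > thresholds.thr_skey:
                skey_ok.add(r.library_id)
            if r.t_circ > thresholds.thr_circ:
                circ_ok.add(r.library_id)
        return skey_ok & circ_ok
    raise ContractViolationError(f"unknown consensus_mode {consensus_mode!r}")


def records_to_frame(records: Sequence[SimilarityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.library_id, r.reference_id, r.t_skey, r.t_circ) for r in records],
        columns=["library_id", "reference_id", "t_skey", "t_circ"],
    )


def write_thresholds(thresholds: SimilarityThresholds, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "thr_skey": thresholds.thr_skey,
                "thr_circ": thresholds.thr_circ,
                "n_pairs": thresholds.n_pairs,
            },
            fh,
            indent=2,
        )
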