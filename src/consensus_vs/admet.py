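"""Deterministic ADMET / medicinal-chemistry filters (funnel criterion 4).

Local, auditable stand-ins for a web profiling service: rule-of-five
drug-likeness counts, an ESOL-style log-solubility estimate with the usual
qualitative bands, substructure interference (PAINS-like) alerts from a
bundled documented pattern subset, and optional externally supplied
cytochrome-inhibition flags joined in by compound id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from rdkit import Chem

from .chem_core import DescriptorSet, Molecule, aromatic_proportion, basic_descriptors
from .errors import FormatError

logger = logging.getLogger(__name__)

SOLUBILITY_CLASSES = ("insoluble", "poorly", "moderately", "soluble", "very", "highly")

# Bundled interference-alert subset: documented, human-readable SMARTS for
# classic assay-interference chemotypes. Not a full catalog — users can load
# their own pattern file for complete coverage.
DEFAULT_ALERTS: list[tuple[str, str]] = [
    ("quinone_1_4", "O=C1C=CC(=O)C=C1"),
    ("quinone_1_2", "O=C1C(=O)C=CC=C1"),
    ("catechol", "c1ccc(O)c(O)c1"),
    ("rhodanine", "S=C1SCC(=O)N1"),
    ("ene_rhodanine", "S=C1SC(=[CH1])C(=O)N1"),
    ("michael_acceptor_enone", "[CH2]=[CH1][CX3](=O)"),
    ("extended_enone", "C=CC=CC(=O)"),
    ("hydroxyphenyl_hydrazone", "c1ccc(O)cc1/C=N/N"),
    ("azo_aromatic", "cN=Nc"),
    ("nitroso", "[NX2]=O"),
    ("isothiocyanate", "N=C=S"),
    ("aldehyde_aromatic", "[CX3H1](=O)c"),
    ("alkyl_halide_activated", "[CH2][Cl,Br,I]"),
    ("thiourea", "NC(=S)N"),
    ("imine_of_phenol", "Oc1ccccc1C=N"),
    ("beta_lactam_fused", "O=C1CCN1"),
]


@dataclass(frozen=True)
class AdmetPolicy:
    """Pass policy; every clause configurable."""

    max_lipinski_violations: int = 1
    min_solubility_class: str = "moderately"
    max_pains_alerts: int = 0
    max_cyp_inhibited: int = 2


@dataclass(frozen=True)
class ADMETProfile:
    compound_id: str
    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    tpsa: float
    esol_logs: float
    solubility_class: str
    lipinski_violations: int
    pains_alerts: int
    cyp_flags: Optional[Mapping[str, bool]] = None


def lipinski_violations(d: DescriptorSet) -> int:
    """Count of violated rule-of-five conditions (strict inequalities)."""
    return sum(
        [d.mw > 500, d.logp > 5, d.hbd > 5, d.hba > 10]
    )


def esol_logs(d: DescriptorSet, aromatic_prop: float) -> tuple[float, str]:
    """ESOL-style estimated log10 aqueous solubility and its class band.

    logS = 0.16 − 0.63·logP − 0.0062·MW + 0.066·RB − 0.74·AP
    """
    logs = (
        0.16
        - 0.63 * d.logp
        - 0.0062 * d.mw
        + 0.066 * d.rotatable_bonds
        - 0.74 * aromatic_prop
    )
    return logs, solubility_class(logs)


def solubility_class(logs: float) -> str:
    if logs < -10:
        return "insoluble"
    if logs < -6:
        return "poorly"
    if logs < -4:
        return "moderately"
    if logs < -2:
        return "soluble"
    if logs < 0:
        return "very"
    return "highly"


def load_alert_library(
    patterns: Sequence[tuple[str, str]] = DEFAULT_ALERTS,
) -> list[tuple[str, Chem.Mol]]:
    """Compile SMARTS alert patterns; invalid patterns fail loudly at load."""
    compiled = []
    for name, smarts in patterns:
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise FormatError(f"invalid alert pattern {name!r}: {smarts!r}")
        compiled.append((name, query))
    return compiled


def load_alert_file(path) -> list[tuple[str, Chem.Mol]]:
    """Read a user pattern file: one `name<TAB>SMARTS` per line."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts = line.split("\t")
            patterns.append((name, smarts))
    return load_alert_library(patterns)


def pains_alerts(
    mol: Molecule, alert_library: Sequence[tuple[str, Chem.Mol]]
) -> int:
    """Number of distinct alert patterns with at least one substructure match."""
    return sum(1 for _, query in alert_library if mol.rdmol.HasSubstructMatch(query))


def matched_alert_names(
    mol: Molecule, alert_library: Sequence[tuple[str, Chem.Mol]]
) -> list[str]:
    return [name for name, query in alert_library if mol.rdmol.HasSubstructMatch(query)]


def profile_molecule(
    mol: Molecule,
    alert_library: Optional[Sequence[tuple[str, Chem.Mol]]] = None,
    cyp_flags: Optional[Mapping[str, bool]] = None,
) -> ADMETProfile:
    if alert_library is None:
        alert_library = load_alert_library()
    d = basic_descriptors(mol)
    logs, sol_class = esol_logs(d, aromatic_proportion(mol))
    return ADMETProfile(
        compound_id=mol.id,
        mw=d.mw,
        logp=d.logp,
        hbd=d.hbd,
        hba=d.hba,
        rotatable_bonds=d.rotatable_bonds,
        tpsa=d.tpsa,
        esol_logs=logs,
        solubility_class=sol_class,
        lipinski_violations=lipinski_violations(d),
        pains_alerts=pains_alerts(mol, alert_library),
        cyp_flags=cyp_flags,
    )


def admet_pass(profile: ADMETProfile, policy: AdmetPolicy = AdmetPolicy()) -> bool:
    """Conjunction of the drug-likeness, solubility, alert and CYP clauses.

    The CYP clause is skipped (and logged) when no flags were provided.
    """
    if profile.lipinski_violations > policy.max_lipinski_violations:
        return False
    min_rank = SOLUBILITY_CLASSES.index(policy.min_solubility_class)
    if SOLUBILITY_CLASSES.index(profile.solubility_class) < min_rank:
        return False
    if profile.pains_alerts > policy.max_pains_alerts:
        return False
    if profile.cyp_flags is None:
        logger.debug("no CYP flags for %s; clause skipped", profile.compound_id)
    elif sum(bool(v) for v in profile.cyp_flags.values()) > policy.max_cyp_inhibited:
        return False
    return True


def read_cyp_flags(path) -> dict[str, dict[str, bool]]:
    """Read an external flag CSV: compound_id plus 0/1 isoform columns."""
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise FormatError("cyp flag table missing compound_id column")
    isoforms = [c for c in df.columns if c != "compound_id"]
    return {
        str(row["compound_id"]): {iso: bool(row[iso]) for iso in isoforms}
        for _, row in df.iterrows()
    }


def profiles_to_frame(profiles: Sequence[ADMETProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "compound_id": p.compound_id,
            "mw": p.mw,
            "logp": p.logp,
            "hbd": p.hbd,
            "hba": p.hba,
            "rotatable_bonds": p.rotatable_bonds,
            "tpsa": p.tpsa,
            "esol_logs": p.esol_logs,
            "solubility_class": p.solubility_class,
            "lipinski_violations": p.lipinski_violations,
            "pains_alerts": p.pains_alerts,
        }
        if p.cyp_flags:
            for iso, v in p.cyp_flags.items():
                row[iso] = int(v)
        rows.append(row)
    return pd.DataFrame(rows)
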