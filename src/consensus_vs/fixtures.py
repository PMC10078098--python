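"""Synthetic input generators with recorded ground truth.

Every file the pipeline consumes — SMILES library, reference actives,
docking-score table, reference/candidate pose SDFs, multi-frame complex
PDBs — can be generated at desk scale with planted per-stage outcomes, so
every stage is testable offline.  Generators are pure functions of
(spec, seed).

Two deliberate abstractions, stated loudly:

- Toy complexes use single-atom "residues" carrying real residue names and
  numbers: geometrically exact for contact logic, biologically abstract.
- Candidate poses are feature-bearing fragment assemblies tagged with the
  compound id, not conformers of the library structure; the pharmacophore
  stage matches features in a shared frame, which is all it observes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import admet as admet_mod
from . import chem_core, similarity
from .chem_core import Molecule
from .docking_post import COLCHICINE_SMILES
from .errors import ContractViolationError
from .pharmacophore import min_reference_count

# Aromatic ring templates; each has at least 3 substitutable CH sites.
SCAFFOLD_TEMPLATES = [
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccoc1",             # furan
    "c1ccsc1",             # thiophene
    "c1cncnc1",            # pyrimidine
]

# Acyclic, alert-free substituents (scaffold class is preserved).
CLEAN_SUBSTITUENTS = ["C", "CC", "CCC", "O", "OC", "N", "NC", "F", "Cl", "CO", "C#N", "OCC"]

# Acyclic Michael-acceptor substituent: triggers the bundled enone alert
# without adding a ring, so planted ADMET failures keep their scaffold class.
ALERT_SUBSTITUENT = "C(=O)C=C"  # attached at the carbonyl C: aryl vinyl ketone

# Aliphatic decoy references, dissimilar to every aromatic library member.
DECOY_REFERENCES = ["CCCCO", "CCNCC", "OC1CCCCC1", "CC(C)CC(C)O", "NCCCCN", "CCOC(C)CC"]


@dataclass
class FixtureSpec:
    n_library: int = 50
    n_references: int = 10
    n_scaffolds: int = 5
    fraction_pass_per_stage: dict = field(
        default_factory=lambda: {"sim": 0.2, "dock": 0.4, "pharm": 0.5, "admet": 0.8}
    )
    seed: int = 0
    n_reference_poses: int = 12
    reference_raw_score: float = -10.01
    top_k: int = 5

    def __post_init__(self):
        if not 1 <= self.n_scaffolds <= len(SCAFFOLD_TEMPLATES):
            raise ContractViolationError(
                f"n_scaffolds must be in [1, {len(SCAFFOLD_TEMPLATES)}]"
            )
        for stage, frac in self.fraction_pass_per_stage.items():
            if not 0 <= frac <= 1:
                raise ContractViolationError(f"fraction for {stage} outside [0,1]")


def _attach(base: Chem.Mol, substituent_smiles: str, site: int) -> Chem.Mol:
    """Bond atom 0 of the substituent fragment to the given base atom."""
    frag = Chem.MolFromSmiles(substituent_smiles)
    combined = Chem.RWMol(Chem.CombineMols(base, frag))
    combined.AddBond(site, base.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return out


def _open_sites(mol: Chem.Mol) -> list[int]:
    """Aromatic CH positions available for substitution."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _decorate(
    template: str, substituents: Sequence[str], rng: np.random.Generator
) -> Chem.Mol:
    mol = Chem.MolFromSmiles(template)
    for sub in substituents:
        sites = _open_sites(mol)
        site = int(rng.choice(sites))
        mol = _attach(mol, sub, site)
    return mol


def _draw_clean_compound(
    template: str, rng: np.random.Generator, alert_library
) -> Chem.Mol:
    """Rejection-sample a decorated template that passes the ADMET policy."""
    for _ in range(50):
        n_subs = int(rng.integers(1, 4))
        subs = [str(s) for s in rng.choice(CLEAN_SUBSTITUENTS, size=n_subs)]
        mol = _decorate(template, subs, rng)
        probe = Molecule(id="probe", rdmol=mol)
        profile = admet_mod.profile_molecule(probe, alert_library)
        if admet_mod.admet_pass(profile):
            return mol
    raise ContractViolationError("could not draw an ADMET-clean compound")


def generate_library(
    spec: FixtureSpec, rng: Optional[np.random.Generator] = None
) -> tuple[list[Molecule], list[Molecule], dict]:
    """Library + reference actives + ground-truth table.

    Designated similarity hits get a near-duplicate reference (same scaffold
    and substituents plus one methyl); planted ADMET failures carry the
    acyclic enone alert.  The realized similarity hit set is recorded by
    running the similarity stage on the generated structures, since the
    median-plus-SD cutoff is data dependent.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    alert_library = admet_mod.load_alert_library()
    fracs = spec.fraction_pass_per_stage

    n = spec.n_library
    n_sim = round(fracs.get("sim", 0.2) * n)
    n_dock = round(fracs.get("dock", 0.4) * n)
    n_pharm = round(fracs.get("pharm", 0.5) * n)
    n_admet_fail = n - round(fracs.get("admet", 0.8) * n)
    if n_sim > spec.n_references:
        raise ContractViolationError("need n_references >= designated similarity hits")

    templates = SCAFFOLD_TEMPLATES[: spec.n_scaffolds]
    library: list[Molecule] = []
    truth_rows: dict[str, dict] = {}
    # nested prefix design: stage designations are prefixes of one id order,
    # ADMET failures are taken from the tail so intersections stay controlled
    for i in range(n):
        cid = f"LIB-{i:04d}"
        template = templates[i % len(templates)]
        is_admet_fail = i >= n - n_admet_fail
        mol = _draw_clean_compound(template, rng, alert_library)
        if is_admet_fail:
            sites = _open_sites(mol)
            mol = _attach(mol, ALERT_SUBSTITUENT, int(rng.choice(sites)))
        library.append(Molecule(id=cid, rdmol=mol))
        truth_rows[cid] = {
            "scaffold_class": i % len(templates),
            "designated_sim_hit": i < n_sim,
            "dock_hit": i < n_dock,
            "pharm_hit": i < n_pharm,
            "admet_hit": not is_admet_fail,
        }

    references: list[Molecule] = []
    for j in range(spec.n_references):
        rid = f"REF-{j:03d}"
        if j < n_sim:
            base = library[j].rdmol
            sites = _open_sites(base)
            near_dup = _attach(base, "C", int(rng.choice(sites)))
            # small molecules set few structural keys, so one methyl can drop
            # similarity a lot; fall back to an exact copy in that case
            fp_a = similarity.compute_fingerprint(
                Molecule(id="a", rdmol=base), similarity.STRUCTURAL_KEYS
            )
            fp_b = similarity.compute_fingerprint(
                Molecule(id="b", rdmol=near_dup), similarity.STRUCTURAL_KEYS
            )
            if similarity.tanimoto(fp_a, fp_b) <= 0.9:
                near_dup = Chem.Mol(base)
            references.append(Molecule(id=rid, rdmol=near_dup))
        else:
            decoy = DECOY_REFERENCES[(j - n_sim) % len(DECOY_REFERENCES)]
            references.append(Molecule(id=rid, rdmol=Chem.MolFromSmiles(decoy)))

    records = similarity.similarity_matrix(library, references)
    thresholds = similarity.consensus_thresholds(records)
    sim_hits = similarity.similarity_hits(records, thresholds)
    for cid, row in truth_rows.items():
        row["sim_hit"] = cid in sim_hits
        row["all_pass"] = (
            row["sim_hit"] and row["dock_hit"] and row["pharm_hit"] and row["admet_hit"]
        )

    truth = {
        "compounds": truth_rows,
        "thresholds": {"thr_skey": thresholds.thr_skey, "thr_circ": thresholds.thr_circ},
        "scaffold_keys": {
            m.id: chem_core.bemis_murcko_scaffold(m).canonical_form for m in library
        },
    }
    return library, references, truth


def generate_score_table(
    spec: FixtureSpec,
    library: Sequence[Molecule],
    truth: dict,
    rng: Optional[np.random.Generator] = None,
) -> "pd.DataFrame":
    """Score CSV such that planted dock hits fall at or below the cutoff.

    The cutoff is the reference raw score over the reference ligand's
    heavy-atom count (full precision); margins keep every row strictly away
    from the boundary.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    ref_mol = chem_core.parse_smiles(COLCHICINE_SMILES, "__reference__")
    cutoff = spec.reference_raw_score / chem_core.heavy_atom_count(ref_mol)
    rows = []
    for mol in library:
        is_hit = truth["compounds"][mol.id]["dock_hit"]
        margin = float(rng.uniform(0.02, 0.30))
        normalized = cutoff - margin if is_hit else cutoff + margin
        n_heavy = chem_core.heavy_atom_count(mol)
        rows.append((mol.id, normalized * n_heavy))
    return pd.DataFrame(rows, columns=["compound_id", "raw_score"])


# --- toy protein-ligand complexes -------------------------------------------

_PDB_ATOM = (
    "{record:<6}{serial:>5} {name:^4}{alt:1}{resname:>3} {chain:1}"
    "{resseq:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2}\n"
)


def _unit_directions(k: int) -> np.ndarray:
    """k well-separated unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(k) + 0.5
    phi = np.arccos(1 - 2 * i / k)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def generate_toy_complex(
    contact_plan: Mapping[str, Union[float, Sequence[float]]],
    n_frames: int = 1,
    path=None,
) -> str:
    """Multi-MODEL PDB with one CA atom per planned residue and a 1-atom ligand.

    ``contact_plan`` maps "ResName ResNum" to a distance in Å (all frames) or
    a per-frame distance sequence.  The nearest protein-ligand heavy-atom
    distance equals the plan exactly in every frame.
    """
    residues = list(contact_plan.items())
    dirs = _unit_directions(max(len(residues), 2))
    lines = []
    for frame in range(n_frames):
        lines.append(f"MODEL     {frame + 1:>4}\n")
        serial = 1
        for k, (rid, dist) in enumerate(residues):
            resname, resnum = rid.split()
            d = dist if np.isscalar(dist) else dist[frame]
            if d <= 0:
                raise ContractViolationError(f"distance for {rid} must be > 0")
            pos = dirs[k] * float(d)
            lines.append(
                _PDB_ATOM.format(
                    record="ATOM", serial=serial, name="CA", alt=" ",
                    resname=resname.upper(), chain="A", resseq=int(resnum), icode=" ",
                    x=pos[0], y=pos[1], z=pos[2], occ=1.0, b=0.0, element="C",
                )
            )
            serial += 1
        lines.append(
            _PDB_ATOM.format(
                record="HETATM", serial=serial, name="C1", alt=" ",
                resname="LIG", chain="B", resseq=1, icode=" ",
                x=0.0, y=0.0, z=0.0, occ=1.0, b=0.0, element="C",
            )
        )
        lines.append("ENDMDL\n")
    lines.append("END\n")
    text = "".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


# --- planted pharmacophore pose sets ----------------------------------------


def _fragment_for_feature(ftype: str, point: np.ndarray) -> Chem.Mol:
    """Small valid fragment exhibiting exactly one feature of one type at point.

    donor: ammonium (N-H, positively charged so not an acceptor);
    acceptor: dimethyl-ether oxygen (no H); aromatic: benzene ring centroid;
    hydrophobic: propane carbon-group centroid.
    """
    if ftype == "donor":
        smiles, offsets = "[NH4+]", np.zeros((1, 3))
    elif ftype == "acceptor":
        smiles = "COC"
        offsets = np.array([[-1.17, 0.64, 0.0], [0.0, 0.0, 0.0], [1.17, 0.64, 0.0]])
        offsets[1] = 0.0  # O exactly at the point
    elif ftype == "aromatic":
        smiles = "c1ccccc1"
        angles = np.arange(6) * np.pi / 3
        offsets = 1.39 * np.stack(
            [np.cos(angles), np.sin(angles), np.zeros(6)], axis=1
        )
    elif ftype == "hydrophobic":
        smiles = "CCC"
        offsets = np.array([[-1.26, 0.29, 0.0], [0.0, -0.58, 0.0], [1.26, 0.29, 0.0]])
    else:
        raise ContractViolationError(f"unknown feature type {ftype!r}")
    mol = Chem.MolFromSmiles(smiles)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, off in enumerate(offsets):
        conf.SetAtomPosition(i, tuple(np.asarray(point, dtype=float) + off))
    mol.AddConformer(conf)
    return mol


def _assemble_pose(
    features: Sequence[tuple[str, np.ndarray]],
    rng: np.random.Generator,
    jitter: float = 0.1,
    pose_id: str = "pose",
) -> Molecule:
    frags = []
    for ftype, point in features:
        shift = rng.uniform(-1.0, 1.0, size=3)
        norm = np.linalg.norm(shift)
        if norm > 0:
            shift = shift / norm * rng.uniform(0, jitter)
        frags.append(_fragment_for_feature(ftype, np.asarray(point) + shift))
    if not frags:
        # feature-free but valid pose: a lone carbon carries no feature
        methane = Chem.MolFromSmiles("C")
        conf = Chem.Conformer(1)
        conf.SetAtomPosition(0, (50.0, 50.0, 50.0))
        methane.AddConformer(conf)
        return Molecule(id=pose_id, rdmol=methane)
    combined = frags[0]
    for frag in frags[1:]:
        combined = Chem.CombineMols(combined, frag)
    Chem.SanitizeMol(combined)  # CombineMols leaves ring info uninitialized
    return Molecule(id=pose_id, rdmol=combined)


def default_planted_features() -> list[tuple[str, tuple[float, float, float], float]]:
    """Six well-separated features, all above the default 70% prevalence."""
    return [
        ("donor", (0.0, 0.0, 0.0), 0.90),
        ("acceptor", (8.0, 0.0, 0.0), 0.85),
        ("aromatic", (0.0, 9.0, 0.0), 0.80),
        ("hydrophobic", (0.0, 0.0, 10.0), 0.80),
        ("aromatic", (-9.0, -9.0, 0.0), 0.75),
        ("acceptor", (9.0, -9.0, 8.0), 0.75),
    ]


def generate_pose_set(
    planted_features: Sequence[tuple[str, tuple[float, float, float], float]],
    n_poses: int,
    seed: int = 0,
) -> tuple[list[Molecule], dict]:
    """Pre-aligned poses where each planted feature appears in exactly
    round(prevalence × n_poses) poses at its stated point (±0.1 Å jitter)."""
    rng = np.random.default_rng(seed)
    membership = []
    for ftype, point, prevalence in planted_features:
        if not 0 < prevalence <= 1:
            raise ContractViolationError("prevalence must be in (0, 1]")
        k = round(prevalence * n_poses)
        membership.append(set(rng.choice(n_poses, size=k, replace=False).tolist()))
    poses = []
    for p in range(n_poses):
        feats = [
            (ftype, np.asarray(point))
            for (ftype, point, _), members in zip(planted_features, membership)
            if p in members
        ]
        poses.append(_assemble_pose(feats, rng, pose_id=f"POSE-{p:03d}"))
    truth = {
        "planted": [
            {"ftype": f[0], "point": list(f[1]), "prevalence": f[2],
             "n_poses_present": len(m)}
            for f, m in zip(planted_features, membership)
        ],
        "n_poses": n_poses,
    }
    return poses, truth


def generate_candidate_poses(
    library: Sequence[Molecule],
    truth: dict,
    planted_features: Sequence[tuple[str, tuple[float, float, float], float]],
    seed: int = 0,
    n_pass_features: int = 6,
    n_fail_features: int = 3,
) -> list[Molecule]:
    """One pose per library compound: planted pharm-passes exhibit enough
    model features, failures too few."""
    rng = np.random.default_rng(seed)
    poses = []
    for mol in library:
        passes = truth["compounds"][mol.id]["pharm_hit"]
        k = n_pass_features if passes else n_fail_features
        feats = [(f[0], np.asarray(f[1])) for f in planted_features[:k]]
        poses.append(_assemble_pose(feats, rng, pose_id=mol.id))
    return poses


def generate_all(spec: FixtureSpec, out_dir) -> dict:
    """Write every pipeline input plus truth.json and a ready-to-run config."""
    import pandas as pd
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    library, references, truth = generate_library(spec, rng)
    chem_core.write_smiles_file(library, out / "library.smi")
    chem_core.write_smiles_file(references, out / "references.smi")

    scores = generate_score_table(spec, library, truth, rng)
    scores.to_csv(out / "scores.csv", index=False)

    planted = default_planted_features()
    ref_poses, pose_truth = generate_pose_set(
        planted, spec.n_reference_poses, seed=spec.seed + 2
    )
    chem_core.write_sdf(ref_poses, out / "reference_poses.sdf")
    cand_poses = generate_candidate_poses(library, truth, planted, seed=spec.seed + 3)
    chem_core.write_sdf(cand_poses, out / "library_poses.sdf")

    generate_toy_complex(
        {"Ala 180": 3.0, "Val 181": 3.5, "Cys 241": 4.0, "Met 259": 4.4, "Ala 316": 7.0},
        n_frames=4,
        path=out / "complex.pdb",
    )

    truth["pose_truth"] = pose_truth
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    config = {
        "inputs": {
            "library": str(out / "library.smi"),
            "references": str(out / "references.smi"),
            "scores": str(out / "scores.csv"),
            "reference_poses": str(out / "reference_poses.sdf"),
            "library_poses": str(out / "library_poses.sdf"),
        },
        "docking": {"reference_raw_score": spec.reference_raw_score},
        "seed": spec.seed,
        "top_k": spec.top_k,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    return truth
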