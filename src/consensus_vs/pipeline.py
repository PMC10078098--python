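"""Funnel orchestration: run criteria (1)-(4), build the consensus table,
select scaffold-diverse top hits and render reports.

All stages are evaluated for every compound (no early exit) so per-stage
funnel counts are reportable; ``fast=True`` enables short-circuiting.
Disabled stages default to pass-through true with a prominent log line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import math
import yaml

from . import admet as admet_mod
from . import chem_core, docking_post, pharmacophore, similarity
from ._util import round_half_away
from .chem_core import ScaffoldKey
from .errors import ContractViolationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusRecord:
    compound_id: str
    sim_hit: bool
    dock_hit: bool
    pharm_matched: int
    pharm_hit: bool
    admet_hit: bool
    normalized_score: float
    scaffold: ScaffoldKey

    @property
    def all_pass(self) -> bool:
        return self.sim_hit and self.dock_hit and self.pharm_hit and self.admet_hit


@dataclass
class RunConfig:
    """Validated pipeline configuration; every stage default overridable."""

    library: str = ""
    references: str = ""
    scores: Optional[str] = None
    reference_poses: Optional[str] = None
    model: Optional[str] = None
    library_poses: Optional[str] = None
    cyp_flags: Optional[str] = None

    consensus_mode: str = "same_reference"
    nbits_circular: int = 2048
    sd_ddof: int = 1

    reference_smiles: str = docking_post.COLCHICINE_SMILES
    reference_raw_score: Optional[float] = None

    prevalence_threshold: float = pharmacophore.DEFAULT_PREVALENCE
    merge_radius: float = pharmacophore.DEFAULT_MERGE_RADIUS
    min_match: int = pharmacophore.DEFAULT_MIN_MATCH

    admet_policy: admet_mod.AdmetPolicy = dc_field(default_factory=admet_mod.AdmetPolicy)

    stages: dict = dc_field(
        default_factory=lambda: {
            "similarity": True, "docking": True, "pharmacophore": True, "admet": True
        }
    )
    seed: int = 0
    top_k: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        inputs = raw.get("inputs", {})
        sim = raw.get("similarity", {})
        dock = raw.get("docking", {})
        pharm = raw.get("pharmacophore", {})
        admet_cfg = raw.get("admet", {})
        cfg = cls(
            library=inputs.get("library", ""),
            references=inputs.get("references", ""),
            scores=inputs.get("scores"),
            reference_poses=inputs.get("reference_poses"),
            model=inputs.get("model"),
            library_poses=inputs.get("library_poses"),
            cyp_flags=inputs.get("cyp_flags"),
            consensus_mode=sim.get("consensus_mode", "same_reference"),
            nbits_circular=int(sim.get("nbits_circular", 2048)),
            sd_ddof=int(sim.get("sd_ddof", 1)),
            reference_smiles=dock.get("reference_smiles", docking_post.COLCHICINE_SMILES),
            reference_raw_score=dock.get("reference_raw_score"),
            prevalence_threshold=float(pharm.get("prevalence_threshold", 0.70)),
            merge_radius=float(pharm.get("merge_radius", 1.5)),
            min_match=int(pharm.get("min_match", 5)),
            admet_policy=admet_mod.AdmetPolicy(
                max_lipinski_violations=int(admet_cfg.get("max_lipinski_violations", 1)),
                min_solubility_class=admet_cfg.get("min_solubility_class", "moderately"),
                max_pains_alerts=int(admet_cfg.get("max_pains_alerts", 0)),
                max_cyp_inhibited=int(admet_cfg.get("max_cyp_inhibited", 2)),
            ),
            stages={**{"similarity": True, "docking": True,
                       "pharmacophore": True, "admet": True},
                    **raw.get("stages", {})},
            seed=int(raw.get("seed", 0)),
            top_k=int(raw.get("top_k", 5)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.library or not self.references:
            raise ContractViolationError("library and references inputs are required")
        for label, path in [("library", self.library), ("references", self.references)]:
            if not Path(path).exists():
                raise ContractViolationError(f"{label} input not readable: {path}")
        for label, path in [
            ("scores", self.scores), ("reference_poses", self.reference_poses),
            ("model", self.model), ("library_poses", self.library_poses),
            ("cyp_flags", self.cyp_flags),
        ]:
            if path is not None and not Path(path).exists():
                raise ContractViolationError(f"{label} input not readable: {path}")
        if self.stages.get("docking", True) and self.reference_raw_score is None:
            raise ContractViolationError(
                "docking stage enabled but no reference_raw_score configured"
            )
        if self.consensus_mode not in ("same_reference", "any_reference"):
            raise ContractViolationError(f"bad consensus_mode {self.consensus_mode!r}")
        if self.top_k < 1:
            raise ContractViolationError("top_k must be >= 1")

    def to_dict(self) -> dict:
        return {
            "inputs": {
                "library": self.library, "references": self.references,
                "scores": self.scores, "reference_poses": self.reference_poses,
                "model": self.model, "library_poses": self.library_poses,
                "cyp_flags": self.cyp_flags,
            },
            "similarity": {
                "consensus_mode": self.consensus_mode,
                "nbits_circular": self.nbits_circular, "sd_ddof": self.sd_ddof,
            },
            "docking": {
                "reference_smiles": self.reference_smiles,
                "reference_raw_score": self.reference_raw_score,
            },
            "pharmacophore": {
                "prevalence_threshold": self.prevalence_threshold,
                "merge_radius": self.merge_radius, "min_match": self.min_match,
            },
            "admet": {
                "max_lipinski_violations": self.admet_policy.max_lipinski_violations,
                "min_solubility_class": self.admet_policy.min_solubility_class,
                "max_pains_alerts": self.admet_policy.max_pains_alerts,
                "max_cyp_inhibited": self.admet_policy.max_cyp_inhibited,
            },
            "stages": dict(self.stages),
            "seed": self.seed,
            "top_k": self.top_k,
        }


def stage_summary(n_total: int, n_hits: int) -> float:
    """Percentage of hits, one decimal, ties rounded away from zero."""
    if n_total <= 0:
        raise ContractViolationError("n_total must be > 0")
    if not 0 <= n_hits <= n_total:
        raise ContractViolationError("need 0 <= n_hits <= n_total")
    return round_half_away(100.0 * n_hits / n_total, 1)


def select_diverse_hits(
    records: Sequence[ConsensusRecord], top_k: int = 5
) -> list[str]:
    """Greedy scaffold-diverse selection among all-pass records.

    Sorted by normalized score ascending (more negative = better), ties by
    compound id; a compound is taken only when its scaffold differs from all
    already-selected scaffolds.  Acyclic (empty) scaffolds each count as
    their own diversity class.
    """
    passing = [r for r in records if r.all_pass]
    if not passing:
        logger.warning("no all-pass compounds; empty selection")
        return []
    passing.sort(key=lambda r: (r.normalized_score, r.compound_id))
    selected: list[str] = []
    seen_scaffolds: set[str] = set()
    for rec in passing:
        key = (
            f"__acyclic__:{rec.compound_id}"
            if rec.scaffold.is_empty
            else rec.scaffold.canonical_form
        )
        if key in seen_scaffolds:
            continue
        seen_scaffolds.add(key)
        selected.append(rec.compound_id)
        if len(selected) >= top_k:
            break
    return selected


def run_consensus(
    config: RunConfig, out_dir=None, fast: bool = False
) -> tuple[list[ConsensusRecord], dict]:
    """Execute stages (1)-(4) and assemble the consensus table + report."""
    library = chem_core.parse_smiles_file(config.library)
    references = chem_core.parse_smiles_file(config.references)
    if not library:
        logger.warning("empty library; empty consensus output")

    n = len(library)
    report: dict = {"n_library": n, "n_references": len(references), "stages": {}}

    # (1) similarity
    sim_hits: set[str] = set()
    sim_records: list[similarity.SimilarityRecord] = []
    thresholds = None
    if not config.stages.get("similarity", True):
        logger.warning("SIMILARITY STAGE DISABLED: all compounds pass through")
        sim_hits = {m.id for m in library}
    elif library and references:
        sim_records = similarity.similarity_matrix(
            library, references, config.nbits_circular
        )
        thresholds = similarity.consensus_thresholds(sim_records, config.sd_ddof)
        sim_hits = similarity.similarity_hits(
            sim_records, thresholds, config.consensus_mode
        )

    # (2) docking normalization + cutoff
    dock_hits: set[str] = set()
    norm_scores: dict[str, float] = {}
    if not config.stages.get("docking", True):
        logger.warning("DOCKING STAGE DISABLED: all compounds pass through")
        dock_hits = {m.id for m in library}
    elif config.scores and library:
        dock_records = docking_post.read_score_table(config.scores, library)
        ref_mol = chem_core.parse_smiles(config.reference_smiles, "__reference__")
        reference = docking_post.DockingRecord(
            compound_id="__reference__",
            raw_score=float(config.reference_raw_score),
            n_heavy=chem_core.heavy_atom_count(ref_mol),
        )
        candidates = dock_records if not fast else [
            r for r in dock_records if r.compound_id in sim_hits
        ]
        dock_hits = docking_post.docking_hits(candidates, reference)
        norm_scores = {r.compound_id: r.normalized_score for r in dock_records}
        report["docking_cutoff"] = reference.normalized_score

    # (3) pharmacophore
    pharm_results: dict[str, tuple[int, bool]] = {}
    model = None
    if not config.stages.get("pharmacophore", True):
        logger.warning("PHARMACOPHORE STAGE DISABLED: all compounds pass through")
        pharm_results = {m.id: (0, True) for m in library}
    else:
        if config.model:
            model = pharmacophore.load_model(config.model)
        elif config.reference_poses:
            ref_poses = chem_core.parse_sdf(config.reference_poses)
            model = pharmacophore.build_pharmacophore(
                ref_poses,
                prevalence_threshold=config.prevalence_threshold,
                merge_radius=config.merge_radius,
                min_match=config.min_match,
            )
        if model is not None and config.library_poses:
            poses = {p.id: p for p in chem_core.parse_sdf(config.library_poses)}
            for mol in library:
                pose = poses.get(mol.id)
                if pose is None:
                    logger.warning("no pose for %s; pharmacophore fail", mol.id)
                    pharm_results[mol.id] = (0, False)
                else:
                    pharm_results[mol.id] = pharmacophore.match_pharmacophore(pose, model)
        else:
            logger.warning("PHARMACOPHORE STAGE LACKS INPUTS: pass-through")
            pharm_results = {m.id: (0, True) for m in library}

    # (4) ADMET
    admet_hits: set[str] = set()
    profiles: list[admet_mod.ADMETProfile] = []
    if not config.stages.get("admet", True):
        logger.warning("ADMET STAGE DISABLED: all compounds pass through")
        admet_hits = {m.id for m in library}
    else:
        alert_library = admet_mod.load_alert_library()
        cyp = admet_mod.read_cyp_flags(config.cyp_flags) if config.cyp_flags else {}
        for mol in library:
            profile = admet_mod.profile_molecule(
                mol, alert_library, cyp.get(mol.id)
            )
            profiles.append(profile)
            if admet_mod.admet_pass(profile, config.admet_policy):
                admet_hits.add(mol.id)

    records = []
    for mol in library:
        matched, pharm_ok = pharm_results.get(mol.id, (0, False))
        records.append(
            ConsensusRecord(
                compound_id=mol.id,
                sim_hit=mol.id in sim_hits,
                dock_hit=mol.id in dock_hits,
                pharm_matched=matched,
                pharm_hit=pharm_ok,
                admet_hit=mol.id in admet_hits,
                normalized_score=norm_scores.get(mol.id, math.nan),
                scaffold=chem_core.bemis_murcko_scaffold(mol),
            )
        )

    selected = select_diverse_hits(records, config.top_k)
    n_all = sum(r.all_pass for r in records)
    if n:
        report["stages"] = {
            "similarity": {"n_hits": len(sim_hits & {m.id for m in library}),
                           "pct": stage_summary(n, len(sim_hits & {m.id for m in library}))},
            "docking": {"n_hits": len(dock_hits), "pct": stage_summary(n, len(dock_hits))},
            "pharmacophore": {
                "n_hits": sum(1 for _, ok in pharm_results.values() if ok),
                "pct": stage_summary(n, sum(1 for _, ok in pharm_results.values() if ok)),
            },
            "admet": {"n_hits": len(admet_hits), "pct": stage_summary(n, len(admet_hits))},
        }
        report["all_pass"] = {"n_hits": n_all, "pct": stage_summary(n, n_all)}
    report["selected"] = selected
    report["seed"] = config.seed
    if thresholds is not None:
        report["thresholds"] = {
            "thr_skey": thresholds.thr_skey, "thr_circ": thresholds.thr_circ,
            "n_pairs": thresholds.n_pairs,
        }

    if out_dir is not None:
        _write_outputs(
            Path(out_dir), config, records, report, sim_records, thresholds, profiles
        )
    return records, report


def records_to_frame(records: Sequence[ConsensusRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "sim_hit": r.sim_hit,
                "dock_hit": r.dock_hit,
                "pharm_matched": r.pharm_matched,
                "pharm_hit": r.pharm_hit,
                "admet_hit": r.admet_hit,
                "all_pass": r.all_pass,
                "normalized_score": r.normalized_score,
                "scaffold": r.scaffold.canonical_form,
            }
            for r in records
        ]
    )


def _write_outputs(out, config, records, report, sim_records, thresholds, profiles):
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(out / "consensus.csv", index=False)
    if sim_records:
        similarity.records_to_frame(sim_records).to_csv(
            out / "similarity.csv", index=False
        )
    if thresholds is not None:
        similarity.write_thresholds(thresholds, out / "thresholds.json")
    if profiles:
        admet_mod.profiles_to_frame(profiles).to_csv(out / "admet.csv", index=False)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    with open(out / "report.md", "w") as fh:
        fh.write(_render_report(report))


def _render_report(report: dict) -> str:
    lines = [
        "# Consensus screening report",
        "",
        f"- library size: {report.get('n_library', 0)}",
        f"- references: {report.get('n_references', 0)}",
        f"- seed: {report.get('seed', 0)}",
        "",
        "| stage | hits | % |",
        "|-------|------|---|",
    ]
    for stage, info in report.get("stages", {}).items():
        lines.append(f"| {stage} | {info['n_hits']} | {info['pct']} |")
    if "all_pass" in report:
        ap = report["all_pass"]
        lines.append(f"| all criteria | {ap['n_hits']} | {ap['pct']} |")
    lines += ["", "## Selected scaffold-diverse hits", ""]
    for i, cid in enumerate(report.get("selected", []), start=1):
        lines.append(f"{i}. {cid}")
    lines.append("")
    return "\n".join(lines)
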