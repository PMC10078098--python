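"""Consensus pharmacophore construction and matching (funnel criterion 3).

A model is built from pre-aligned reference binding modes: perceived features
of the same type are clustered across poses (single linkage) and a cluster
becomes a model feature only when a configurable fraction of the references
contribute to it (default 70%).  Candidate poses then pass when they match at
least ``min_match`` model features (default 5, i.e. 5 of a 6-feature model).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .chem_core import Molecule
from .errors import ContractViolationError

FEATURE_TYPES = ("donor", "acceptor", "aromatic", "hydrophobic")

DEFAULT_PREVALENCE = 0.70
DEFAULT_MIN_MATCH = 5
DEFAULT_MERGE_RADIUS = 1.5  # Å


@dataclass(frozen=True)
class PharmacophoreFeature:
    ftype: str
    centroid: tuple[float, float, float]
    tolerance: float  # Å
    prevalence: float  # fraction of references contributing


@dataclass(frozen=True)
class PharmacophoreModel:
    features: tuple[PharmacophoreFeature, ...]
    n_references: int
    prevalence_threshold: float = DEFAULT_PREVALENCE
    min_match: int = DEFAULT_MIN_MATCH


def min_reference_count(n_references: int, prevalence_threshold: float) -> int:
    """Minimum number of references a feature must appear in: ceil(t · n)."""
    if n_references < 1 or not (0 < prevalence_threshold <= 1):
        raise ContractViolationError("need n >= 1 and 0 < threshold <= 1")
    return math.ceil(prevalence_threshold * n_references)


def perceive_features(pose: Molecule) -> list[tuple[str, tuple[float, float, float]]]:
    """Typed feature points of a 3D pose.

    donor: N/O bearing >= 1 H; acceptor: N/O not positively charged;
    aromatic: centroid of each aromatic ring; hydrophobic: centroid of each
    maximal connected group of >= 3 carbons that are neither aromatic nor
    bonded to a heteroatom.
    """
    coords = pose.coords
    if coords is None:
        raise ContractViolationError(f"pose {pose.id!r} has no coordinates")
    pts = np.asarray(coords, dtype=float)
    rdmol = pose.rdmol
    features: list[tuple[str, tuple[float, float, float]]] = []

    for atom in rdmol.GetAtoms():
        if atom.GetAtomicNum() not in (7, 8):
            continue
        p = tuple(pts[atom.GetIdx()])
        if atom.GetTotalNumHs() >= 1:
            features.append(("donor", p))
        if atom.GetFormalCharge() <= 0:
            features.append(("acceptor", p))

    for ring in rdmol.GetRingInfo().AtomRings():
        if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            features.append(("aromatic", tuple(pts[list(ring)].mean(axis=0))))

    qualifying = {
        a.GetIdx()
        for a in rdmol.GetAtoms()
        if a.GetAtomicNum() == 6
        and not a.GetIsAromatic()
        and all(n.GetAtomicNum() in (1, 6) for n in a.GetNeighbors())
    }
    seen: set[int] = set()
    for start in sorted(qualifying):
        if start in seen:
            continue
        group = {start}
        stack = [start]
        while stack:
            idx = stack.pop()
            for nbr in rdmol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j in qualifying and j not in group:
                    group.add(j)
                    stack.append(j)
        seen |= group
        if len(group) >= 3:
            features.append(("hydrophobic", tuple(pts[sorted(group)].mean(axis=0))))
    return features


def build_pharmacophore(
    reference_poses: Sequence[Molecule],
    prevalence_threshold: float = DEFAULT_PREVALENCE,
    merge_radius: float = DEFAULT_MERGE_RADIUS,
    min_match: int = DEFAULT_MIN_MATCH,
) -> PharmacophoreModel:
    """Cluster features across pre-aligned poses; keep the prevalent clusters.

    Single-linkage clustering at ``merge_radius`` per feature type; a cluster
    is retained when contributions come from at least
    ``min_reference_count(n, prevalence_threshold)`` distinct poses.  The
    feature centroid is the mean of member points, tolerance the larger of the
    merge radius and the cluster radius.
    """
    n_ref = len(reference_poses)
    if n_ref < 2:
        raise ContractViolationError("need >= 2 reference poses")
    min_count = min_reference_count(n_ref, prevalence_threshold)

    by_type: dict[str, list[tuple[int, np.ndarray]]] = {t: [] for t in FEATURE_TYPES}
    for pose_idx, pose in enumerate(reference_poses):
        for ftype, point in perceive_features(pose):
            by_type[ftype].append((pose_idx, np.asarray(point)))

    features: list[PharmacophoreFeature] = []
    for ftype in FEATURE_TYPES:
        members = by_type[ftype]
        if not members:
            continue
        points = np.vstack([p for _, p in members])
        if len(members) == 1:
            labels = np.array([1])
        else:
            labels = fcluster(
                linkage(points, method="single"), t=merge_radius, criterion="distance"
            )
        for label in np.unique(labels):
            idx = np.nonzero(labels == label)[0]
            poses_in = {members[i][0] for i in idx}
            if len(poses_in) < min_count:
                continue
            cluster_pts = points[idx]
            centroid = cluster_pts.mean(axis=0)
            radius = float(np.linalg.norm(cluster_pts - centroid, axis=1).max())
            features.append(
                PharmacophoreFeature(
                    ftype=ftype,
                    centroid=tuple(float(x) for x in centroid),
                    tolerance=max(merge_radius, radius),
                    prevalence=len(poses_in) / n_ref,
                )
            )

    features.sort(key=lambda f: (f.ftype, f.centroid))
    return PharmacophoreModel(
        features=tuple(features),
        n_references=n_ref,
        prevalence_threshold=prevalence_threshold,
        min_match=min_match,
    )


def match_pharmacophore(
    pose: Molecule, model: PharmacophoreModel, optimal: bool = False
) -> tuple[int, bool]:
    """Count model features matched by the pose; pass at >= model.min_match.

    A model feature matches a perceived pose feature of the same type within
    its tolerance; assignment is one-to-one, greedy nearest-first by default
    (ties broken by model-feature index) or optimal bipartite when
    ``optimal=True``.
    """
    pose_features = perceive_features(pose)
    candidates = []  # (distance, model_idx, pose_idx)
    for mi, mf in enumerate(model.features):
        mc = np.asarray(mf.centroid)
        for pi, (ftype, point) in enumerate(pose_features):
            if ftype != mf.ftype:
                continue
            d = float(np.linalg.norm(mc - np.asarray(point)))
            if d <= mf.tolerance:
                candidates.append((d, mi, pi))

    if optimal and candidates:
        n_m, n_p = len(model.features), len(pose_features)
        cost = np.full((n_m, n_p), 1e6)
        for d, mi, pi in candidates:
            cost[mi, pi] = d
        rows, cols = linear_sum_assignment(cost)
        n_matched = int(sum(cost[r, c] < 1e6 for r, c in zip(rows, cols)))
    else:
        candidates.sort()
        used_m: set[int] = set()
        used_p: set[int] = set()
        for _, mi, pi in candidates:
            if mi in used_m or pi in used_p:
                continue
            used_m.add(mi)
            used_p.add(pi)
        n_matched = len(used_m)

    return n_matched, n_matched >= model.min_match


def save_model(model: PharmacophoreModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_references": model.n_references,
                "prevalence_threshold": model.prevalence_threshold,
                "min_match": model.min_match,
                "features": [
                    {
                        "ftype": f.ftype,
                        "centroid": list(f.centroid),
                        "tolerance": f.tolerance,
                        "prevalence": f.prevalence,
                    }
                    for f in model.features
                ],
            },
            fh,
            indent=2,
        )


def load_model(path) -> PharmacophoreModel:
    with open(path) as fh:
        data = json.load(fh)
    return PharmacophoreModel(
        features=tuple(
            PharmacophoreFeature(
                ftype=f["ftype"],
                centroid=tuple(f["centroid"]),
                tolerance=f["tolerance"],
                prevalence=f["prevalence"],
            )
            for f in data["features"]
        ),
        n_references=data["n_references"],
        prevalence_threshold=data["prevalence_threshold"],
        min_match=data["min_match"],
    )
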