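"""Rule-based structure pharmacophore extraction from one annotated pose.

Atom role typing (donor/acceptor/charge/hydrophobic) is an *input* — an
annotation table covering ligand and receptor atoms — so the geometric engine
stays testable and makes no chemistry-perception claims.  Candidate features
come from role-compatible atom pairs inside the distance cutoffs (hydrogen
bond 4.0 Å, charge–charge 8.0 Å, hydrophobic 5.5 Å, all inclusive); candidates
closer than the minimum interfeature distance (1.0 Å) are merged and a
priority rule (ionic > hydrogen bond > hydrophobic, then shorter interaction
distance) caps the model at 4–6 features.  No exclusion volumes are generated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_model import BindingSite, Pose

HBD, HBA, HBIC, NEGION, POSION = "HBD", "HBA", "Hbic", "NegIon", "PosIon"

ROLE_DONOR = "hb_donor"
ROLE_ACCEPTOR = "hb_acceptor"
ROLE_POS = "pos_charged"
ROLE_NEG = "neg_charged"
ROLE_HYDROPHOBIC = "hydrophobic"
VALID_ROLES = {ROLE_DONOR, ROLE_ACCEPTOR, ROLE_POS, ROLE_NEG, ROLE_HYDROPHOBIC}

DEFAULT_CUTOFFS = {"hbond": 4.0, "charge": 8.0, "hydrophobic": 5.5}
MIN_INTERFEATURE_DISTANCE = 1.0
FEATURE_COUNT_RANGE = (4, 6)

# stand-in for the unavailable rules-based ranking: ionic > H-bond > hydrophobic
_KIND_PRIORITY = {NEGION: 0, POSION: 0, HBD: 1, HBA: 1, HBIC: 2}
_VECTORED_KINDS = {HBD, HBA}


class ModelTooSmallError(ValueError):
    """Fewer than the minimum number of features survived candidate merging."""

    def __init__(self, message: str, candidates: list["PharmacophoreFeature"]):
        super().__init__(message)
        self.candidates = candidates


@dataclass
class TypedAtomAnnotation:
    """Role assignment for one atom (ligand atom index or receptor atom id)."""

    atom_ref: str | int
    roles: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.roles) - VALID_ROLES
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)} for atom {self.atom_ref!r}")


@dataclass
class PharmacophoreFeature:
    kind: str
    position: tuple[float, float, float]
    direction: tuple[float, float, float] | None = None
    tolerance_radius: float = 1.5
    interaction_distance: float = 0.0  # ligand-anchor to receptor-partner

    def __post_init__(self) -> None:
        if self.kind not in _KIND_PRIORITY:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("non-finite feature position")
        if self.kind in _VECTORED_KINDS and self.direction is None:
            raise ValueError(f"{self.kind} features must carry a direction")
        if self.direction is not None:
            norm = math.sqrt(sum(c * c for c in self.direction))
            if not math.isclose(norm, 1.0, rel_tol=1e-6):
                raise ValueError("direction must be a unit vector")


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    source_pose_id: str
    generation_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = FEATURE_COUNT_RANGE
        if not lo <= len(self.features) <= hi:
            raise ValueError(
                f"model must have {lo}-{hi} features, got {len(self.features)}"
            )
        pos = np.array([f.position for f in self.features])
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if np.linalg.norm(pos[i] - pos[j]) < MIN_INTERFEATURE_DISTANCE:
                    raise ValueError("features violate minimum interfeature distance")

    def distance_matrix(self) -> np.ndarray:
        pos = np.array([f.position for f in self.features])
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "source_pose_id": self.source_pose_id,
            "generation_params": self.generation_params,
            "features": [
                {
                    "kind": f.kind,
                    "position": [round(c, 6) for c in f.position],
                    "direction": (
                        None
                        if f.direction is None
                        else [round(c, 6) for c in f.direction]
                    ),
                    "tolerance_radius": f.tolerance_radius,
                }
                for f in self.features
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        payload = json.loads(text)
        features = [
            PharmacophoreFeature(
                kind=f["kind"],
                position=tuple(f["position"]),
                direction=None if f["direction"] is None else tuple(f["direction"]),
                tolerance_radius=f["tolerance_radius"],
            )
            for f in payload["features"]
        ]
        return cls(
            features=features,
            source_pose_id=payload["source_pose_id"],
            generation_params=payload.get("generation_params", {}),
        )


def read_annotations_csv(path: str | Path):
    """Parse a role-annotation CSV (scope, atom_ref, roles).

    ``scope`` is ``receptor`` or ``ligand:<compound_id>``; roles are
    ``|``-separated.  Returns ``(receptor_annotations, ligand_annotations)``
    where ligand annotations are keyed by compound id then atom index.
    """
    import csv

    receptor: dict[str, frozenset] = {}
    ligand: dict[str, dict[int, frozenset]] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            roles = frozenset(r for r in row["roles"].split("|") if r)
            bad = roles - VALID_ROLES
            if bad:
                raise ValueError(f"unknown roles {sorted(bad)} in {path}")
            scope = row["scope"]
            if scope == "receptor":
                receptor[row["atom_ref"]] = roles
            elif scope.startswith("ligand:"):
                compound_id = scope.split(":", 1)[1]
                ligand.setdefault(compound_id, {})[int(row["atom_ref"])] = roles
            else:
                raise ValueError(f"unknown annotation scope {scope!r}")
    return receptor, ligand


def _unit(v: np.ndarray) -> tuple[float, float, float]:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero-length direction vector")
    return tuple(float(c) for c in v / n)


def _roles_of(annotations: Mapping, key) -> frozenset[str]:
    ann = annotations.get(key)
    if ann is None:
        return frozenset()
    if isinstance(ann, TypedAtomAnnotation):
        return ann.roles
    return frozenset(ann)


def detect_interactions(
    pose: Pose,
    site: BindingSite,
    ligand_annotations: Mapping[int, frozenset[str] | TypedAtomAnnotation],
    receptor_annotations: Mapping[str, frozenset[str] | TypedAtomAnnotation],
    cutoffs: Mapping[str, float] = DEFAULT_CUTOFFS,
) -> list[PharmacophoreFeature]:
    """Candidate features from role-compatible ligand/receptor atom pairs.

    Ligand annotations are keyed by atom index in the pose, receptor
    annotations by binding-site atom id (annotated water atoms participate as
    receptor-side partners, covering bridging-water interactions).  The
    ligand-side role names the feature kind and anchors its position.
    Heavy atoms only on both sides; unannotated atoms are ignored.
    """
    hbond = float(cutoffs.get("hbond", DEFAULT_CUTOFFS["hbond"]))
    charge = float(cutoffs.get("charge", DEFAULT_CUTOFFS["charge"]))
    hydrophobic = float(cutoffs.get("hydrophobic", DEFAULT_CUTOFFS["hydrophobic"]))

    lig_heavy = [
        (i, np.array(xyz))
        for i, (element, is_h, xyz) in enumerate(pose.atoms)
        if not is_h
    ]
    rec_heavy = [
        (atom_id, np.array(atom.coords))
        for atom_id, atom in zip(site.atom_ids, site.atoms)
        if not atom.is_hydrogen
    ]

    candidates: list[PharmacophoreFeature] = []

    pair_rules = [
        # (ligand role, receptor role, max distance, feature kind)
        (ROLE_DONOR, ROLE_ACCEPTOR, hbond, HBD),
        (ROLE_ACCEPTOR, ROLE_DONOR, hbond, HBA),
        (ROLE_NEG, ROLE_POS, charge, NEGION),
        (ROLE_POS, ROLE_NEG, charge, POSION),
    ]
    for lig_idx, lig_xyz in lig_heavy:
        lig_roles = _roles_of(ligand_annotations, lig_idx)
        if not lig_roles:
            continue
        for rec_id, rec_xyz in rec_heavy:
            rec_roles = _roles_of(receptor_annotations, rec_id)
            if not rec_roles:
                continue
            d = float(np.linalg.norm(lig_xyz - rec_xyz))
            for lig_role, rec_role, cutoff, kind in pair_rules:
                if lig_role in lig_roles and rec_role in rec_roles and d <= cutoff:
                    direction = (
                        _unit(rec_xyz - lig_xyz) if kind in _VECTORED_KINDS else None
                    )
                    candidates.append(
                        PharmacophoreFeature(
                            kind=kind,
                            position=tuple(float(c) for c in lig_xyz),
                            direction=direction,
                            interaction_distance=d,
                        )
                    )

    # hydrophobic: centroids of single-linkage groups of hydrophobic ligand atoms
    hphob_atoms = [
        (i, xyz)
        for i, xyz in lig_heavy
        if ROLE_HYDROPHOBIC in _roles_of(ligand_annotations, i)
    ]
    for centroid in _centroid_groups([xyz for _, xyz in hphob_atoms]):
        best = None
        for rec_id, rec_xyz in rec_heavy:
            if ROLE_HYDROPHOBIC not in _roles_of(receptor_annotations, rec_id):
                continue
            d = float(np.linalg.norm(centroid - rec_xyz))
            if best is None or d < best:
                best = d
        if best is not None and best <= hydrophobic:
            candidates.append(
                PharmacophoreFeature(
                    kind=HBIC,
                    position=tuple(float(c) for c in centroid),
                    interaction_distance=best,
                )
            )
    return candidates


def _centroid_groups(points: Sequence[np.ndarray], link: float = 2.0) -> list[np.ndarray]:
    """Single-linkage grouping of nearby points; one centroid per group."""
    groups: list[list[np.ndarray]] = []
    for p in points:
        merged = False
        for group in groups:
            if any(np.linalg.norm(p - q) <= link for q in group):
                group.append(p)
                merged = True
                break
        if not merged:
            groups.append([p])
    return [np.mean(g, axis=0) for g in groups]


def build_model(
    candidates: Sequence[PharmacophoreFeature],
    source_pose_id: str = "",
    n_range: tuple[int, int] = FEATURE_COUNT_RANGE,
    min_interfeature: float = MIN_INTERFEATURE_DISTANCE,
    generation_params: dict | None = None,
) -> PharmacophoreModel:
    """Merge close candidates, rank by priority and cap at the allowed count.

    Candidates closer than ``min_interfeature`` are merged to their centroid;
    the merged feature takes the highest-priority kind in the cluster.  If
    more than ``n_range[1]`` features remain the top ones win by
    (kind priority, shorter interaction distance); fewer than ``n_range[0]``
    raises :class:`ModelTooSmallError` carrying the candidate dump.
    """
    lo, hi = n_range
    ordered = sorted(
        candidates,
        key=lambda f: (_KIND_PRIORITY[f.kind], f.interaction_distance, f.kind),
    )
    merged: list[PharmacophoreFeature] = []
    clusters: list[list[PharmacophoreFeature]] = []
    for cand in ordered:
        target = None
        for cluster in clusters:
            rep = cluster[0]
            d = math.dist(cand.position, rep.position)
            if d < min_interfeature:
                target = cluster
                break
        if target is None:
            clusters.append([cand])
        else:
            target.append(cand)
    for cluster in clusters:
        rep = cluster[0]  # highest priority member (input is sorted)
        centroid = tuple(
            float(c) for c in np.mean([f.position for f in cluster], axis=0)
        )
        merged.append(
            PharmacophoreFeature(
                kind=rep.kind,
                position=centroid,
                direction=rep.direction,
                tolerance_radius=rep.tolerance_radius,
                interaction_distance=min(f.interaction_distance for f in cluster),
            )
        )
    # merging can pull centroids together; drop lower-priority violators
    merged.sort(key=lambda f: (_KIND_PRIORITY[f.kind], f.interaction_distance, f.kind))
    separated: list[PharmacophoreFeature] = []
    for f in merged:
        if all(
            math.dist(f.position, g.position) >= min_interfeature for g in separated
        ):
            separated.append(f)
    if len(separated) < lo:
        raise ModelTooSmallError(
            f"only {len(separated)} candidate features after merging (need >= {lo})",
            list(candidates),
        )
    return PharmacophoreModel(
        features=separated[:hi],
        source_pose_id=source_pose_id,
        generation_params=dict(generation_params or {}),
    )


_ROLE_FOR_KIND = {
    HBD: ROLE_DONOR,
    HBA: ROLE_ACCEPTOR,
    NEGION: ROLE_NEG,
    POSION: ROLE_POS,
    HBIC: ROLE_HYDROPHOBIC,
}


def map_compound(
    model: PharmacophoreModel,
    conformer: Pose,
    annotations: Mapping[int, frozenset[str] | TypedAtomAnnotation],
    match_tolerance: float = 1.5,
) -> float:
    """Rigid greedy fit of an annotated conformer onto the model.

    Each feature may claim one role-compatible heavy atom within
    ``match_tolerance`` of its position; a match at distance *d* contributes
    ``1 - d / match_tolerance``.  The score lies in ``[0, |features|]`` and the
    source pose attains the maximum (every distance 0).
    """
    atoms = [
        (i, np.array(xyz))
        for i, (element, is_h, xyz) in enumerate(conformer.atoms)
        if not is_h
    ]
    pairs = []  # (distance, feature index, atom index)
    for fi, feat in enumerate(model.features):
        role = _ROLE_FOR_KIND[feat.kind]
        for ai, xyz in atoms:
            if role not in _roles_of(annotations, ai):
                continue
            d = float(np.linalg.norm(xyz - np.array(feat.position)))
            if d <= match_tolerance:
                pairs.append((d, fi, ai))
    pairs.sort()
    used_features: set[int] = set()
    used_atoms: set[int] = set()
    score = 0.0
    for d, fi, ai in pairs:
        if fi in used_features or ai in used_atoms:
            continue
        used_features.add(fi)
        used_atoms.add(ai)
        score += 1.0 - d / match_tolerance
    return score
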