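"""Consensus-vote scoring (top-20% rule) and RMSD-based pose deduplication.

A pose receives one vote from each scoring function that ranks it within the
best 20% of that function's column; votes are summed into a consensus score.
Poses of a compound closer than the RMSD threshold (heavy atoms, no
superposition) are duplicates; the one with the highest consensus survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_model import HIGHER_BETTER, Pose, ScoreTable

DEFAULT_TOP_FRACTION = 0.20
DEFAULT_RMSD_THRESHOLD = 2.0


@dataclass
class ConsensusScore:
    pose_id: str
    votes: int
    per_function_vote: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_function_vote and self.votes != sum(self.per_function_vote.values()):
            raise ValueError("votes must equal the sum of per-function votes")


@dataclass
class DedupResult:
    kept: list[str]
    removed: dict[str, str]  # removed pose_id -> its kept representative

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.removed)
        if overlap:
            raise ValueError(f"poses both kept and removed: {sorted(overlap)[:5]}")


def consensus_votes(
    table: ScoreTable,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    compound_of: Mapping[str, str] | None = None,
) -> list[ConsensusScore]:
    """Assign top-fraction votes per scoring column and sum them per pose.

    For each score column the poses are ranked by the column's direction and
    the best ``ceil(N * top_fraction)`` receive that column's vote.  Ties with
    the cutoff value are inclusive, so vote counts may exceed the nominal
    quota — no arbitrary ordering dependence.

    By default the ranking population is all poses in the table pooled
    together; pass ``compound_of`` (pose_id → compound_id) to rank within each
    compound instead.
    """
    if not 0 < top_fraction < 1:
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    if not table.rows:
        raise ValueError("empty score table")

    if compound_of is None:
        groups = [list(table.rows)]
    else:
        by_compound: dict[str, list[str]] = {}
        for pose_id in table.rows:
            by_compound.setdefault(compound_of[pose_id], []).append(pose_id)
        groups = list(by_compound.values())

    per_vote: dict[str, dict[str, int]] = {
        pose_id: {} for pose_id in table.rows
    }
    for name in table.score_names:
        higher = table.directions[name] == HIGHER_BETTER
        for group in groups:
            values = np.array([table.rows[p][name] for p in group], dtype=float)
            ranked = -values if higher else values  # ascending = best first
            quota = math.ceil(len(group) * top_fraction)
            cutoff = np.partition(ranked, quota - 1)[quota - 1]
            winners = ranked <= cutoff  # inclusive at the boundary value
            for pose_id, won in zip(group, winners):
                per_vote[pose_id][name] = int(won)
    return [
        ConsensusScore(
            pose_id=pose_id,
            votes=sum(per_vote[pose_id].values()),
            per_function_vote=per_vote[pose_id],
        )
        for pose_id in table.rows
    ]


def rmsd(pose_a: Pose, pose_b: Pose, heavy_only: bool = True) -> float:
    """Root-mean-square deviation over paired atoms, no superposition.

    Poses must belong to the same compound and share atom ordering (docked
    poses of one molecule share atom numbering; no Hungarian matching).
    """
    if pose_a.compound_id != pose_b.compound_id:
        raise ValueError(
            f"cannot compare poses of different compounds "
            f"({pose_a.compound_id!r} vs {pose_b.compound_id!r})"
        )
    if heavy_only:
        xyz_a, xyz_b = pose_a.heavy_coords, pose_b.heavy_coords
    else:
        xyz_a, xyz_b = pose_a.coords, pose_b.coords
    if xyz_a.shape != xyz_b.shape:
        raise ValueError(
            f"atom-count mismatch between poses {pose_a.pose_id} and {pose_b.pose_id}"
        )
    if xyz_a.shape[0] == 0:
        raise ValueError("no atoms available for RMSD")
    return float(np.sqrt(np.mean(np.sum((xyz_a - xyz_b) ** 2, axis=1))))


def dedup_poses(
    poses: Sequence[Pose],
    consensus: Sequence[ConsensusScore] | Mapping[str, int],
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
    heavy_only: bool = True,
    inclusive: bool = False,
) -> DedupResult:
    """Greedy dedup of one compound's poses, keeping high-consensus representatives.

    Poses are visited by (votes desc, pose_id asc); a pose is kept iff its
    RMSD to every already-kept pose clears the threshold (strict ``<``
    defines a duplicate by default; set ``inclusive`` for ``<=``).  A removed
    pose is recorded under its nearest kept pose.  A pose missing from
    ``consensus`` counts as 0 votes.  Idempotent on its own output.
    """
    compounds = {p.compound_id for p in poses}
    if len(compounds) > 1:
        raise ValueError(f"dedup_poses expects one compound, got {sorted(compounds)}")
    if isinstance(consensus, Mapping):
        votes = dict(consensus)
    else:
        votes = {c.pose_id: c.votes for c in consensus}
    ordered = sorted(poses, key=lambda p: (-votes.get(p.pose_id, 0), p.pose_id))

    kept: list[Pose] = []
    removed: dict[str, str] = {}
    for pose in ordered:
        nearest: tuple[float, str] | None = None
        duplicate = False
        for rep in kept:
            d = rmsd(pose, rep, heavy_only=heavy_only)
            if nearest is None or d < nearest[0]:
                nearest = (d, rep.pose_id)
            if d < rmsd_threshold or (inclusive and d == rmsd_threshold):
                duplicate = True
        if duplicate:
            assert nearest is not None
            removed[pose.pose_id] = nearest[1]
        else:
            kept.append(pose)
    return DedupResult(kept=[p.pose_id for p in kept], removed=removed)


def filter_by_consensus(
    poses: Sequence[Pose],
    consensus: Sequence[ConsensusScore] | Mapping[str, int],
    min_votes: int,
) -> list[Pose]:
    """Keep poses whose consensus votes reach ``min_votes`` (absent → 0)."""
    if min_votes < 0:
        raise ValueError("min_votes must be >= 0")
    if isinstance(consensus, Mapping):
        votes = dict(consensus)
    else:
        votes = {c.pose_id: c.votes for c in consensus}
    return [p for p in poses if votes.get(p.pose_id, 0) >= min_votes]
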