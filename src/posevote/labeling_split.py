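"""Activity-class assignment from IC50 and the every-fifth train/test split."""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .io_model import ACTIVE, INACTIVE, INTERMEDIATE, CompoundRecord

DEFAULT_ACTIVE_MAX_NM = 5000.0
DEFAULT_INACTIVE_MIN_NM = 20000.0

_CLASS_RANK = {ACTIVE: 0, INTERMEDIATE: 1, INACTIVE: 2}


@dataclass
class SplitAssignment:
    """Disjoint training/testing compound sets; poses follow their compound."""

    training_compounds: set[str] = field(default_factory=set)
    testing_compounds: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.training_compounds & self.testing_compounds
        if overlap:
            raise ValueError(f"compounds in both partitions: {sorted(overlap)[:5]}")

    def partition_of(self, compound_id: str) -> str:
        if compound_id in self.testing_compounds:
            return "testing"
        if compound_id in self.training_compounds:
            return "training"
        raise KeyError(compound_id)


def assign_class(
    ic50_nM: float,
    active_max: float = DEFAULT_ACTIVE_MAX_NM,
    inactive_min: float = DEFAULT_INACTIVE_MIN_NM,
) -> str:
    """Map an IC50 (nM) to an activity class.

    Boundaries are inclusive on the class side: ``ic50 <= active_max`` is
    active, ``ic50 >= inactive_min`` is inactive, strictly between is
    intermediate.
    """
    if ic50_nM is None or ic50_nM <= 0:
        raise ValueError(f"ic50_nM must be positive, got {ic50_nM}")
    if active_max >= inactive_min:
        raise ValueError("active_max must be below inactive_min")
    if ic50_nM <= active_max:
        return ACTIVE
    if ic50_nM >= inactive_min:
        return INACTIVE
    return INTERMEDIATE


def label_compounds(
    compounds: Sequence[CompoundRecord],
    active_max: float = DEFAULT_ACTIVE_MAX_NM,
    inactive_min: float = DEFAULT_INACTIVE_MIN_NM,
) -> list[CompoundRecord]:
    """Return compounds with ``activity_class`` filled in from IC50."""
    out = []
    for rec in compounds:
        cls = (
            assign_class(rec.ic50_nM, active_max, inactive_min)
            if rec.ic50_nM is not None
            else rec.activity_class
        )
        out.append(
            CompoundRecord(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                ic50_nM=rec.ic50_nM,
                activity_class=cls,
            )
        )
    return out


def class_counts(compounds: Sequence[CompoundRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in compounds:
        counts[rec.activity_class] = counts.get(rec.activity_class, 0) + 1
    return counts


def split_every_fifth(
    compounds: Sequence[CompoundRecord],
    seed: int,
    every: int = 5,
    start: int = 5,
) -> SplitAssignment:
    """Class-ordered, seeded-shuffle-within-class, every-fifth testing split.

    Compounds are ordered by class rank (active, intermediate, inactive, then
    unlabelled) with a seeded shuffle inside each class; positions
    ``start, start+every, ...`` (1-indexed) of the concatenated ordering go to
    the testing partition, everything else to training.  All poses of a
    compound follow it, so pose integrity across partitions is automatic.
    """
    if len(compounds) < every:
        raise ValueError(f"need at least {every} compounds, got {len(compounds)}")
    if not (1 <= start <= every):
        raise ValueError("start must be in [1, every]")
    rng = random.Random(seed)
    by_class: dict[int, list[str]] = {}
    for rec in compounds:
        rank = _CLASS_RANK.get(rec.activity_class, 3)
        by_class.setdefault(rank, []).append(rec.compound_id)
    ordered: list[str] = []
    for rank in sorted(by_class):
        ids = sorted(by_class[rank])
        rng.shuffle(ids)
        ordered.extend(ids)
    testing = {cid for pos, cid in enumerate(ordered, start=1)
               if pos >= start and (pos - start) % every == 0}
    training = set(ordered) - testing
    return SplitAssignment(training_compounds=training, testing_compounds=testing)
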