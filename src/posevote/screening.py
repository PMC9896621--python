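"""Active-pose-ratio threshold derivation and screening-hit triage.

Each compound's predicted poses are reduced to a percent-active figure; the
threshold for calling a screened compound promising is the *lowest* percent
among documented active testing compounds with enough poses (compounds below
``min_poses`` total poses are excluded — a single docked pose is not enough
augmentation to trust).  The comparison is inclusive, so the threshold-
defining compound passes its own threshold.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DEFAULT_MIN_POSES = 2


@dataclass
class PoseRatioRecord:
    compound_id: str
    n_active_poses: int
    n_inactive_poses: int

    def __post_init__(self) -> None:
        if self.n_active_poses < 0 or self.n_inactive_poses < 0:
            raise ValueError("pose counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_active_poses + self.n_inactive_poses

    @property
    def percent_active(self) -> float:
        return percent_active(self.n_active_poses, self.n_inactive_poses)


@dataclass
class ThresholdDecision:
    threshold_percent: float
    defining_compound: str
    excluded_compounds: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class TriageResult:
    compound_id: str
    percent_active: float
    promising: bool


def percent_active(n_active: int, n_inactive: int) -> float:
    """``100 * n_active / (n_active + n_inactive)``; zero total raises."""
    total = n_active + n_inactive
    if total <= 0:
        raise ValueError("compound has no predicted poses")
    return 100.0 * n_active / total


def round1(value: float) -> float:
    """Round to 1 decimal, half away from zero (report convention)."""
    return math.floor(abs(value) * 10 + 0.5) / 10 * (1 if value >= 0 else -1)


def derive_threshold(
    records: Sequence[PoseRatioRecord],
    min_poses: int = DEFAULT_MIN_POSES,
) -> ThresholdDecision:
    """Lowest percent-active among eligible documented actives.

    Compounds with fewer than ``min_poses`` total poses are excluded with a
    logged reason.  Raises when no record is eligible.
    """
    eligible = []
    excluded = []
    for rec in records:
        if rec.total < min_poses:
            excluded.append(
                (rec.compound_id, f"only {rec.total} pose(s) (< {min_poses})")
            )
        else:
            eligible.append(rec)
    if not eligible:
        raise ValueError("no eligible documented actives to derive a threshold from")
    defining = min(eligible, key=lambda r: (r.percent_active, r.compound_id))
    return ThresholdDecision(
        threshold_percent=defining.percent_active,
        defining_compound=defining.compound_id,
        excluded_compounds=excluded,
    )


def triage_hits(
    records: Sequence[PoseRatioRecord],
    threshold_percent: float,
) -> list[TriageResult]:
    """Flag compounds at or above the threshold, sorted best-first."""
    results = [
        TriageResult(
            compound_id=rec.compound_id,
            percent_active=rec.percent_active,
            promising=rec.percent_active >= threshold_percent,
        )
        for rec in records
        if rec.total > 0
    ]
    results.sort(key=lambda r: (-r.percent_active, r.compound_id))
    return results


def triage_union(
    per_model_records: Mapping[str, Sequence[PoseRatioRecord]],
    per_model_thresholds: Mapping[str, float],
) -> dict[str, bool]:
    """Promising = passes *either* model's threshold (per-model results kept)."""
    promising: dict[str, bool] = {}
    for model, records in per_model_records.items():
        for res in triage_hits(records, per_model_thresholds[model]):
            promising[res.compound_id] = promising.get(res.compound_id, False) or res.promising
    return promising


# ---------------------------------------------------------------------------
# bundled reference tables (plain-text package data)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrintedPoseCounts:
    """One published pose-count cell: integer counts + the printed percent."""

    compound_id: str
    model: str  # "xgb" | "rf"
    n_active: int
    n_inactive: int
    printed_percent: float
    printed_inconsistent: bool  # printed percent disagrees with its own counts


def _load_counts_csv(name: str) -> list[PrintedPoseCounts]:
    with resources.files("posevote.data").joinpath(name).open(
        "r", encoding="utf-8"
    ) as handle:
        reader = csv.DictReader(handle)
        out = []
        for row in reader:
            for model in ("xgb", "rf"):
                raw = row[f"{model}_active"].strip()
                if raw in ("", "ND"):
                    continue
                out.append(
                    PrintedPoseCounts(
                        compound_id=row["compound_id"],
                        model=model,
                        n_active=int(raw),
                        n_inactive=int(row[f"{model}_inactive"]),
                        printed_percent=float(row[f"{model}_percent"]),
                        printed_inconsistent=row.get(
                            f"{model}_inconsistent", ""
                        ).strip()
                        == "1",
                    )
                )
        return out


def load_screened_hit_counts() -> list[PrintedPoseCounts]:
    """Published per-model pose counts for the 26 screened hit compounds."""
    return _load_counts_csv("screened_hits_pose_counts.csv")


def load_testing_active_counts() -> list[PrintedPoseCounts]:
    """Published per-model pose counts for the documented active testing compounds."""
    return _load_counts_csv("testing_actives_pose_counts.csv")


def records_from_counts(
    counts: Iterable[PrintedPoseCounts], model: str
) -> list[PoseRatioRecord]:
    return [
        PoseRatioRecord(
            compound_id=c.compound_id,
            n_active_poses=c.n_active,
            n_inactive_poses=c.n_inactive,
        )
        for c in counts
        if c.model == model
    ]


def write_triage_csv(
    records: Sequence[PoseRatioRecord],
    results: Sequence[TriageResult],
    path: str | Path,
) -> None:
    by_id = {r.compound_id: r for r in records}
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["compound_id", "active_poses", "inactive_poses", "percent_active", "promising"]
        )
        for res in results:
            rec = by_id[res.compound_id]
            writer.writerow(
                [
                    res.compound_id,
                    rec.n_active_poses,
                    rec.n_inactive_poses,
                    f"{round1(res.percent_active):.1f}",
                    int(res.promising),
                ]
            )
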