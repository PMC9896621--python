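"""Binary ligand–receptor contact fingerprints over a fixed binding-site axis.

A fingerprint bit is 1 when the corresponding site atom lies within the
contact cutoff (default 2.5 Å, boundary inclusive) of *any* atom of the docked
pose.  Hydrogens participate on both sides; distances are taken in the shared
docking frame with no superposition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io_model import AxisError, BindingSite, Pose

DEFAULT_CONTACT_CUTOFF = 2.5


@dataclass
class ContactFingerprint:
    """One pose's binary contact vector over the project's atom axis.

    Stored sparsely as the sorted indices of set bits; densify with
    :meth:`to_dense`.
    """

    pose_id: str
    on_bits: tuple[int, ...]
    axis_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.axis_ids)
        if any(not (0 <= b < n) for b in self.on_bits):
            raise ValueError("set-bit index outside the fingerprint axis")
        if list(self.on_bits) != sorted(set(self.on_bits)):
            raise ValueError("on_bits must be sorted and unique")

    def to_dense(self) -> np.ndarray:
        bits = np.zeros(len(self.axis_ids), dtype=np.int8)
        bits[list(self.on_bits)] = 1
        return bits

    def __len__(self) -> int:
        return len(self.axis_ids)


def compute_lrcf(
    pose: Pose,
    site: BindingSite,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    axis_ids: Sequence[str] | None = None,
) -> ContactFingerprint:
    """Compute one pose's contact fingerprint.

    ``bit_j = 1`` iff the minimum Euclidean distance from site atom *j* to any
    ligand atom is ≤ ``cutoff``.  When ``axis_ids`` is given it must equal the
    site's atom ids (guards against mixing fingerprints across projects).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    site_axis = tuple(site.atom_ids)
    if axis_ids is not None and tuple(axis_ids) != site_axis:
        raise AxisError("binding site differs from the project fingerprint axis")
    dists = cdist(site.coords, pose.coords)
    on = np.flatnonzero(dists.min(axis=1) <= cutoff)
    return ContactFingerprint(
        pose_id=pose.pose_id,
        on_bits=tuple(int(i) for i in on),
        axis_ids=site_axis,
    )


def build_fingerprint_matrix(
    poses: Sequence[Pose],
    site: BindingSite,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> tuple[np.ndarray, list[str]]:
    """Stack per-pose fingerprints into a dense 0/1 matrix.

    Returns ``(matrix, pose_ids)`` where row *i* is the fingerprint of
    ``poses[i]`` and the column order equals ``site.atom_ids``.
    """
    pose_ids = [p.pose_id for p in poses]
    if len(set(pose_ids)) != len(pose_ids):
        raise ValueError("duplicate pose_id among poses")
    n = len(site)
    matrix = np.zeros((len(poses), n), dtype=np.int8)
    site_xyz = site.coords
    for i, pose in enumerate(poses):
        dists = cdist(site_xyz, pose.coords)
        matrix[i, dists.min(axis=1) <= cutoff] = 1
    return matrix, pose_ids


def write_fingerprint_csv(
    matrix: np.ndarray,
    pose_ids: Sequence[str],
    axis_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Serialize the dense 0/1 matrix with pose_id rows and atom_id columns."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["pose_id"] + list(axis_ids))
        for pose_id, row in zip(pose_ids, matrix):
            writer.writerow([pose_id] + [int(v) for v in row])


def read_fingerprint_csv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`write_fingerprint_csv`: (matrix, pose_ids, axis_ids)."""
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader)
        axis_ids = header[1:]
        pose_ids, rows = [], []
        for row in reader:
            pose_ids.append(row[0])
            rows.append([int(v) for v in row[1:]])
    matrix = np.asarray(rows, dtype=np.int8).reshape(len(pose_ids), len(axis_ids))
    return matrix, pose_ids, axis_ids
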