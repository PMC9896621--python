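"""Domain types and I/O for receptors, docked poses, score tables and activities.

All downstream stages operate on the types defined here.  Atom identity follows
the convention ``"RESNAME RESNUM ATOMNAME"`` with atom names verbatim from the
input file (hydrogen names included); the chain id is appended only when residue
numbering collides between chains.  Coordinates are read as-is — no protonation,
no minimisation, no superposition.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"

_HYDROGEN_ELEMENTS = {"H", "D", "T"}

ACTIVE = "active"
INTERMEDIATE = "intermediate"
INACTIVE = "inactive"
UNKNOWN = "unknown"


class FormatError(ValueError):
    """Input file failed to parse as its declared format."""


class EmptySiteError(ValueError):
    """Binding-site selection matched no atoms."""


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


class AxisError(ValueError):
    """Fingerprint axis mismatch between a pose set and a binding site."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One receptor atom with its PDB identity and coordinates (Å)."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    coords: tuple[float, float, float]
    is_hydrogen: bool

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.is_hydrogen != (self.element.upper() in _HYDROGEN_ELEMENTS):
            raise ValueError(
                f"is_hydrogen inconsistent with element {self.element!r}"
            )


@dataclass
class BindingSite:
    """Ordered, named receptor atoms defining the fingerprint axis.

    The order of ``atoms`` (and hence of ``atom_ids``) is fixed for the
    lifetime of a project: it is the column axis of every contact fingerprint.
    """

    atoms: list[Atom]
    atom_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atom_ids:
            self.atom_ids = _canonical_atom_ids(self.atoms)
        if len(self.atoms) != len(self.atom_ids):
            raise ValueError("atoms and atom_ids must have equal length")
        if len(set(self.atom_ids)) != len(self.atom_ids):
            dupes = sorted(
                {i for i in self.atom_ids if self.atom_ids.count(i) > 1}
            )
            raise ValueError(f"duplicate atom_ids in binding site: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of site-atom coordinates in file order."""
        return np.asarray([a.coords for a in self.atoms], dtype=float)


@dataclass
class Pose:
    """One docked conformer of a compound (element, hydrogen flag, xyz)."""

    compound_id: str
    pose_id: str
    atoms: list[tuple[str, bool, tuple[float, float, float]]]
    source_engine: str | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"pose {self.pose_id} has no atoms")
        for element, _, xyz in self.atoms:
            if not all(math.isfinite(c) for c in xyz):
                raise ValueError(f"non-finite coordinates in pose {self.pose_id}")
            if not element:
                raise ValueError(f"empty element in pose {self.pose_id}")

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([xyz for _, _, xyz in self.atoms], dtype=float)

    @property
    def heavy_coords(self) -> np.ndarray:
        pts = [xyz for _, is_h, xyz in self.atoms if not is_h]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def n_heavy(self) -> int:
        return sum(1 for _, is_h, _ in self.atoms if not is_h)


@dataclass
class ScoreTable:
    """Per-pose scoring-function values with per-column ranking direction."""

    rows: dict[str, dict[str, float]]
    directions: dict[str, str]

    def __post_init__(self) -> None:
        names = set(self.directions)
        for direction in self.directions.values():
            if direction not in (HIGHER_BETTER, LOWER_BETTER):
                raise ConfigError(f"unknown ranking direction {direction!r}")
        for pose_id, scores in self.rows.items():
            if set(scores) != names:
                raise ValueError(
                    f"pose {pose_id} score names differ from directions config"
                )

    @property
    def score_names(self) -> list[str]:
        return sorted(self.directions)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class CompoundRecord:
    """One curated compound: identity, structure and measured potency."""

    compound_id: str
    smiles: str = ""
    ic50_nM: float | None = None
    activity_class: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise ValueError(f"ic50_nM must be positive, got {self.ic50_nM}")


# ---------------------------------------------------------------------------
# selection specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueListSelection:
    """Explicit residue selection: (residue_name, residue_number) pairs."""

    residues: frozenset[tuple[str, int]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "ResidueListSelection":
        return cls(frozenset((name.strip().upper(), int(num)) for name, num in pairs))

    def matches(self, atom: Atom) -> bool:
        return (atom.residue_name.upper(), atom.residue_number) in self.residues


@dataclass(frozen=True)
class SphereSelection:
    """All atoms within ``radius`` Å (inclusive) of ``center``."""

    center: tuple[float, float, float]
    radius: float

    def matches(self, atom: Atom) -> bool:
        d = math.dist(atom.coords, self.center)
        return d <= self.radius


class AllAtomsSelection:
    """Identity selection: every atom in the file."""

    def matches(self, atom: Atom) -> bool:  # noqa: ARG002 - uniform interface
        return True


SelectionSpec = ResidueListSelection | SphereSelection | AllAtomsSelection


def selection_from_config(cfg: Mapping) -> SelectionSpec:
    """Build a selection spec from a config mapping (YAML-friendly).

    Recognised shapes::

        {"residues": [["SER", 613], ["HOH", 32]]}
        {"sphere": {"center": [x, y, z], "radius": 6.5}}
        {"all": true}
    """
    if "residues" in cfg:
        return ResidueListSelection.from_pairs(
            (str(r[0]), int(r[1])) for r in cfg["residues"]
        )
    if "sphere" in cfg:
        sph = cfg["sphere"]
        center = tuple(float(c) for c in sph["center"])
        return SphereSelection(center=center, radius=float(sph["radius"]))
    if cfg.get("all"):
        return AllAtomsSelection()
    raise ConfigError(f"unrecognised site selection spec: {dict(cfg)!r}")


# ---------------------------------------------------------------------------
# atom id convention
# ---------------------------------------------------------------------------


def _canonical_atom_ids(atoms: Sequence[Atom]) -> list[str]:
    """``"RESNAME RESNUM ATOMNAME"``; chain id appended only on collision."""
    base = [f"{a.residue_name} {a.residue_number} {a.atom_name}" for a in atoms]
    counts: dict[str, int] = {}
    for b in base:
        counts[b] = counts.get(b, 0) + 1
    ids = []
    for a, b in zip(atoms, base):
        ids.append(f"{b} {a.chain_id}".rstrip() if counts[b] > 1 else b)
    return ids


# ---------------------------------------------------------------------------
# PDB parsing (hand-rolled line reader kept out: Biopython handles the format;
# we only flatten its hierarchy back to file order)
# ---------------------------------------------------------------------------


def _parse_pdb_atoms(path: str | Path) -> list[Atom]:
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("receptor", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise FormatError(f"PDB file {path} contains no models")
    atoms: list[Atom] = []
    for chain in models[0]:
        for residue in chain:
            resname = residue.get_resname().strip()
            resnum = residue.get_id()[1]
            for atom in residue:
                element = (atom.element or "").strip() or _guess_element(
                    atom.get_name()
                )
                atoms.append(
                    Atom(
                        atom_name=atom.get_name().strip(),
                        residue_name=resname,
                        residue_number=resnum,
                        chain_id=chain.id.strip(),
                        element=element,
                        coords=tuple(float(c) for c in atom.coord),
                        is_hydrogen=element.upper() in _HYDROGEN_ELEMENTS,
                    )
                )
    return atoms


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise FormatError("atom with empty name")
    # PDB convention: names like "1H2", "HG21" are hydrogens; otherwise first letter
    stripped = name.lstrip("0123456789")
    first = stripped[:1].upper() or name[:1].upper()
    return first


def read_receptor(path: str | Path, site_definition: SelectionSpec) -> BindingSite:
    """Read a receptor PDB and restrict it to the binding-site selection.

    Atom order equals file order restricted to the selection; waters (HOH)
    and hydrogens are retained whenever the selection matches them.

    Raises
    ------
    FormatError
        If the file does not parse as PDB.
    EmptySiteError
        If the selection matches no atoms.
    """
    atoms = _parse_pdb_atoms(path)
    if not atoms:
        raise FormatError(f"no atoms found in {path}")
    selected = [a for a in atoms if site_definition.matches(a)]
    if not selected:
        raise EmptySiteError(f"site selection matched no atoms in {path}")
    return BindingSite(atoms=selected)


def write_receptor_pdb(site: BindingSite, path: str | Path) -> None:
    """Write a binding site back out as a minimal PDB (ATOM/HETATM records)."""
    lines = []
    for i, atom in enumerate(site.atoms, start=1):
        record = "HETATM" if atom.residue_name == "HOH" else "ATOM  "
        name = atom.atom_name
        # PDB atom-name column alignment: 1-char elements start in column 14
        padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
        x, y, z = atom.coords
        lines.append(
            f"{record}{i:>5d} {padded}{'':1s}{atom.residue_name:>3s} "
            f"{atom.chain_id or 'A':1s}{atom.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pose reading
# ---------------------------------------------------------------------------

DEFAULT_ID_TAG = "COMPOUND_ID"


def read_poses(
    path: str | Path,
    id_fields: Sequence[str] = (DEFAULT_ID_TAG,),
    pose_id_field: str | None = "POSE_ID",
    source_engine: str | None = None,
) -> list[Pose]:
    """Read docked poses from an SD file or a multi-model PDB.

    One :class:`Pose` per SD record / PDB MODEL.  The compound id is taken
    from the first matching SD property in ``id_fields``, falling back to the
    record title; pose ids default to ``"<compound_id>#<ordinal>"`` when no
    explicit ``pose_id_field`` tag is present.  Records with zero atoms are
    skipped with a logged warning; duplicate explicit pose ids raise.
    """
    path = Path(path)
    if path.suffix.lower() in (".sdf", ".sd", ".mol"):
        poses = _read_poses_sdf(path, id_fields, pose_id_field, source_engine)
    else:
        poses = _read_poses_multimodel_pdb(path, source_engine)
    _check_unique_pose_ids(poses)
    return poses


def _check_unique_pose_ids(poses: Sequence[Pose]) -> None:
    seen: set[str] = set()
    for p in poses:
        if p.pose_id in seen:
            raise ValueError(f"duplicate pose_id {p.pose_id!r}")
        seen.add(p.pose_id)


def _read_poses_sdf(
    path: Path,
    id_fields: Sequence[str],
    pose_id_field: str | None,
    source_engine: str | None,
) -> list[Pose]:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    poses: list[Pose] = []
    ordinals: dict[str, int] = {}
    supplier = Chem.ForwardSDMolSupplier(str(path), sanitize=False, removeHs=False)
    for record_index, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unreadable SD record %d in %s", record_index, path)
            continue
        if mol.GetNumAtoms() == 0:
            logger.warning("skipping zero-atom SD record %d in %s", record_index, path)
            continue
        compound_id = ""
        for tag in id_fields:
            if mol.HasProp(tag):
                compound_id = mol.GetProp(tag).strip()
                break
        if not compound_id and mol.HasProp("_Name"):
            compound_id = mol.GetProp("_Name").strip()
        if not compound_id:
            compound_id = f"record{record_index}"
        explicit = (
            mol.GetProp(pose_id_field).strip()
            if pose_id_field and mol.HasProp(pose_id_field)
            else None
        )
        if explicit:
            pose_id = explicit
        else:
            ordinals[compound_id] = ordinals.get(compound_id, 0) + 1
            pose_id = f"{compound_id}#{ordinals[compound_id]}"
        conf = mol.GetConformer()
        atoms = []
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol()
            xyz = conf.GetAtomPosition(atom.GetIdx())
            atoms.append((sym, sym.upper() in _HYDROGEN_ELEMENTS, (xyz.x, xyz.y, xyz.z)))
        poses.append(
            Pose(
                compound_id=compound_id,
                pose_id=pose_id,
                atoms=atoms,
                source_engine=source_engine,
            )
        )
    return poses


def _read_poses_multimodel_pdb(path: Path, source_engine: str | None) -> list[Pose]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("poses", str(path))
    except Exception as exc:  # Biopython raises several types here
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    compound_id = path.stem
    poses: list[Pose] = []
    for ordinal, model in enumerate(structure, start=1):
        atoms = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    element = (atom.element or "").strip() or _guess_element(
                        atom.get_name()
                    )
                    atoms.append(
                        (
                            element,
                            element.upper() in _HYDROGEN_ELEMENTS,
                            tuple(float(c) for c in atom.coord),
                        )
                    )
        if not atoms:
            logger.warning("skipping empty MODEL %d in %s", ordinal, path)
            continue
        poses.append(
            Pose(
                compound_id=compound_id,
                pose_id=f"{compound_id}#{ordinal}",
                atoms=atoms,
                source_engine=source_engine,
            )
        )
    return poses


def write_poses_sdf(poses: Sequence[Pose], path: str | Path) -> None:
    """Write poses as a V2000 SD file with COMPOUND_ID / POSE_ID tags."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for pose in poses:
            mol = Chem.RWMol()
            for element, _, _ in pose.atoms:
                atom = Chem.Atom(element)
                atom.SetNoImplicit(True)
                mol.AddAtom(atom)
            conf = Chem.Conformer(len(pose.atoms))
            for i, (_, _, xyz) in enumerate(pose.atoms):
                conf.SetAtomPosition(i, Point3D(*xyz))
            mol.AddConformer(conf)
            out = mol.GetMol()
            out.SetProp("_Name", pose.compound_id)
            out.SetProp(DEFAULT_ID_TAG, pose.compound_id)
            out.SetProp("POSE_ID", pose.pose_id)
            if pose.source_engine:
                out.SetProp("SOURCE_ENGINE", pose.source_engine)
            writer.write(out)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# score tables and activities
# ---------------------------------------------------------------------------


def read_scores(
    path: str | Path | io.TextIOBase,
    directions: Mapping[str, str],
) -> ScoreTable:
    """Read a per-pose score CSV into a :class:`ScoreTable`.

    The CSV must have a ``pose_id`` column plus one column per named score;
    every score column must appear in ``directions``.  A row with a missing or
    non-numeric cell is dropped with a logged warning — a pose absent from the
    table simply collects zero consensus votes downstream.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, newline="", encoding="utf-8")
        close = True
    else:
        handle = path
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "pose_id" not in reader.fieldnames:
            raise FormatError("score CSV must have a header with a pose_id column")
        score_cols = [c for c in reader.fieldnames if c != "pose_id"]
        if not score_cols:
            raise FormatError("score CSV has no score columns")
        missing = [c for c in score_cols if c not in directions]
        if missing:
            raise ConfigError(f"no ranking direction configured for: {missing}")
        rows: dict[str, dict[str, float]] = {}
        for line_no, row in enumerate(reader, start=2):
            pose_id = (row.get("pose_id") or "").strip()
            try:
                values = {c: float(row[c]) for c in score_cols}
            except (TypeError, ValueError, KeyError):
                logger.warning(
                    "dropping pose %r (line %d): non-numeric or missing score cell",
                    pose_id,
                    line_no,
                )
                continue
            if not all(math.isfinite(v) for v in values.values()):
                logger.warning("dropping pose %r: non-finite score", pose_id)
                continue
            rows[pose_id] = values
        return ScoreTable(rows=rows, directions={c: directions[c] for c in score_cols})
    finally:
        if close:
            handle.close()


def write_scores_csv(table: ScoreTable, path: str | Path) -> None:
    names = table.score_names
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["pose_id"] + names)
        for pose_id in sorted(table.rows):
            writer.writerow([pose_id] + [repr(table.rows[pose_id][n]) for n in names])


def read_activities(path: str | Path | io.TextIOBase) -> list[CompoundRecord]:
    """Read the compound activity CSV (compound_id, smiles, ic50_nM).

    ``ic50_nM`` may be blank for screening hits (activity unknown).
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, newline="", encoding="utf-8")
        close = True
    else:
        handle = path
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "compound_id" not in reader.fieldnames:
            raise FormatError("activity CSV must have a compound_id column")
        records = []
        for row in reader:
            raw = (row.get("ic50_nM") or "").strip()
            ic50 = float(raw) if raw else None
            records.append(
                CompoundRecord(
                    compound_id=row["compound_id"].strip(),
                    smiles=(row.get("smiles") or "").strip(),
                    ic50_nM=ic50,
                )
            )
        return records
    finally:
        if close:
            handle.close()


def write_activities_csv(records: Sequence[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["compound_id", "smiles", "ic50_nM", "activity_class"])
        for rec in records:
            writer.writerow(
                [
                    rec.compound_id,
                    rec.smiles,
                    "" if rec.ic50_nM is None else repr(rec.ic50_nM),
                    rec.activity_class,
                ]
            )
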