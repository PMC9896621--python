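"""Self-contained synthetic inputs with a planted contact→activity signal.

The generator synthesises every input the pipeline consumes — binding site,
docked poses, score table, activity table, role annotations — directly in the
site frame, with no physics.  Site atoms sit on a 3D lattice spaced wider than
twice the contact cutoff, so a ligand atom placed near one site atom can never
touch another: the intended bit pattern of each pose is exactly what the
contacts module recomputes from the coordinates.

Active compounds' poses touch the planted site atoms with probability
``signal_strength``; inactive poses with ``1 - signal_strength``.  One score
column correlates with activity in proportion to ``2*signal_strength - 1``
(so a null fixture at 0.5 carries no signal anywhere) and the other eight are
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_model import (
    ACTIVE,
    HIGHER_BETTER,
    INACTIVE,
    INTERMEDIATE,
    LOWER_BETTER,
    Atom,
    BindingSite,
    CompoundRecord,
    ConfigError,
    Pose,
    ScoreTable,
)
from .pharmacophore import (
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_HYDROPHOBIC,
    ROLE_NEG,
    ROLE_POS,
)

CONTACT_CUTOFF = 2.5
LATTICE_SPACING = 6.0  # > 2 * cutoff: planted contacts cannot bleed across atoms

SCORE_NAMES = (
    "scoreA1",
    "scoreA2",
    "scoreB",
    "scoreC1",
    "scoreC2",
    "scoreD",
    "scoreD4",
    "energy1",
    "energy2",
)
GOOD_SCORE = "scoreB"
SCORE_DIRECTIONS = {
    "scoreA1": HIGHER_BETTER,
    "scoreA2": HIGHER_BETTER,
    "scoreB": HIGHER_BETTER,
    "scoreC1": HIGHER_BETTER,
    "scoreC2": HIGHER_BETTER,
    "scoreD": HIGHER_BETTER,
    "scoreD4": HIGHER_BETTER,
    "energy1": LOWER_BETTER,
    "energy2": LOWER_BETTER,
}

_RESIDUE_NAMES = ("ALA", "SER", "VAL", "GLU", "LYS", "TYR", "MET", "HOH")
_ATOM_NAMES = ("CA", "CB", "N", "O", "OG", "NZ", "SD", "OH2")


@dataclass
class FixtureConfig:
    n_compounds: int = 200
    poses_per_compound: tuple[int, int] = (5, 20)
    n_site_atoms: int = 100
    planted_contact_ids: tuple[int, ...] = (3, 17, 42, 61, 88)
    signal_strength: float = 0.9
    background_contact_rate: float = 0.08
    score_noise_sd: float = 1.0
    class_proportions: dict = field(
        default_factory=lambda: {ACTIVE: 0.37, INTERMEDIATE: 0.29, INACTIVE: 0.34}
    )
    ligand_atoms: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.signal_strength <= 1.0:
            raise ConfigError("signal_strength must be in [0.5, 1]")
        if any(
            not 0 <= i < self.n_site_atoms for i in self.planted_contact_ids
        ):
            raise ConfigError("planted contact index outside the site")
        if len(set(self.planted_contact_ids)) != len(self.planted_contact_ids):
            raise ConfigError("planted contact indices must be unique")
        lo, hi = self.poses_per_compound
        if not 1 <= lo <= hi:
            raise ConfigError("poses_per_compound range invalid")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError("class proportions must sum to 1")


@dataclass
class FixtureBundle:
    site: BindingSite
    poses: list[Pose]
    scores: ScoreTable
    compounds: list[CompoundRecord]
    ligand_annotations: dict[str, dict[int, frozenset]]
    receptor_annotations: dict[str, frozenset]
    intended_bits: dict[str, tuple[int, ...]]  # pose_id -> sorted set-bit indices
    config: FixtureConfig

    def compound_of(self) -> dict[str, str]:
        return {p.pose_id: p.compound_id for p in self.poses}

    def labels_by_compound(self) -> dict[str, str]:
        return {c.compound_id: c.activity_class for c in self.compounds}

    def planted_column_ids(self) -> list[str]:
        return [self.site.atom_ids[i] for i in self.config.planted_contact_ids]


def _lattice_site(n_atoms: int, rng: np.random.Generator) -> BindingSite:
    side = int(np.ceil(n_atoms ** (1 / 3)))
    coords = []
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                coords.append((ix, iy, iz))
                if len(coords) == n_atoms:
                    break
            if len(coords) == n_atoms:
                break
        if len(coords) == n_atoms:
            break
    atoms = []
    for idx, (ix, iy, iz) in enumerate(coords):
        resname = _RESIDUE_NAMES[idx % len(_RESIDUE_NAMES)]
        atom_name = _ATOM_NAMES[idx % len(_ATOM_NAMES)]
        element = "O" if resname == "HOH" else atom_name[0]
        atoms.append(
            Atom(
                atom_name=atom_name,
                residue_name=resname,
                residue_number=idx + 1,  # unique per atom: ids stay collision-free
                chain_id="A",
                element=element,
                coords=(
                    ix * LATTICE_SPACING,
                    iy * LATTICE_SPACING,
                    iz * LATTICE_SPACING,
                ),
                is_hydrogen=False,
            )
        )
    return BindingSite(atoms=atoms)


def _sample_classes(config: FixtureConfig, rng: np.random.Generator) -> list[str]:
    classes = list(config.class_proportions)
    counts = {c: int(round(config.class_proportions[c] * config.n_compounds)) for c in classes}
    while sum(counts.values()) < config.n_compounds:
        counts[classes[0]] += 1
    while sum(counts.values()) > config.n_compounds:
        counts[max(counts, key=counts.get)] -= 1
    labels = [c for c in classes for _ in range(counts[c])]
    rng.shuffle(labels)
    return labels


def _ic50_for_class(cls: str, rng: np.random.Generator) -> float:
    if cls == ACTIVE:
        return float(10 ** rng.uniform(1.0, np.log10(5000.0)))
    if cls == INTERMEDIATE:
        return float(rng.uniform(5001.0, 19999.0))
    return float(10 ** rng.uniform(np.log10(20000.0), 5.5))


def generate(config: FixtureConfig) -> FixtureBundle:
    """Deterministically generate the full synthetic input bundle."""
    rng = np.random.default_rng(config.seed)
    site = _lattice_site(config.n_site_atoms, rng)
    site_xyz = site.coords
    planted = set(config.planted_contact_ids)
    non_planted = [i for i in range(config.n_site_atoms) if i not in planted]

    class_labels = _sample_classes(config, rng)
    compounds = []
    poses: list[Pose] = []
    intended: dict[str, tuple[int, ...]] = {}
    score_rows: dict[str, dict[str, float]] = {}
    signal_scale = 2.0 * config.signal_strength - 1.0

    for c_idx, cls in enumerate(class_labels):
        compound_id = f"C{c_idx + 1:04d}"
        smiles = "C" * (3 + c_idx % 10)
        compounds.append(
            CompoundRecord(
                compound_id=compound_id,
                smiles=smiles,
                ic50_nM=_ic50_for_class(cls, rng),
                activity_class=cls,
            )
        )
        touch_p = (
            config.signal_strength
            if cls == ACTIVE
            else (1.0 - config.signal_strength)
            if cls == INACTIVE
            else 0.5
        )
        n_poses = int(rng.integers(config.poses_per_compound[0],
                                   config.poses_per_compound[1] + 1))
        for p_ord in range(1, n_poses + 1):
            pose_id = f"{compound_id}#{p_ord}"
            bits = set()
            for i in config.planted_contact_ids:
                if rng.random() < touch_p:
                    bits.add(i)
            n_bg = rng.binomial(len(non_planted), config.background_contact_rate)
            bg_bits = [int(i) for i in rng.choice(non_planted, size=n_bg, replace=False)]
            # keep planted bits; cap background so geometry can encode every bit
            room = config.ligand_atoms - len(bits)
            bits.update(bg_bits[:room])
            bits_sorted = tuple(sorted(bits))
            atoms = []
            for j, bit in enumerate(bits_sorted):
                offset = rng.normal(size=3)
                offset *= rng.uniform(0.3, 2.3) / np.linalg.norm(offset)
                xyz = site_xyz[bit] + offset
                atoms.append(("C", False, tuple(float(v) for v in xyz)))
            # pad to a fixed atom count (same ordering across a compound's poses)
            while len(atoms) < config.ligand_atoms:
                base = site_xyz[int(rng.integers(config.n_site_atoms))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                xyz = base + direction * 3.0  # 3.0 Å from nearest lattice atom
                atoms.append(("C", False, tuple(float(v) for v in xyz)))
            poses.append(Pose(compound_id=compound_id, pose_id=pose_id, atoms=atoms))
            intended[pose_id] = tuple(sorted(bits))

            row = {
                name: float(rng.normal(scale=config.score_noise_sd))
                for name in SCORE_NAMES
            }
            activity_push = 1.0 if cls == ACTIVE else -1.0 if cls == INACTIVE else 0.0
            row[GOOD_SCORE] += 1.5 * signal_scale * activity_push
            score_rows[pose_id] = row

    scores = ScoreTable(rows=score_rows, directions=dict(SCORE_DIRECTIONS))

    # role annotations: give every compound's ligand atoms a cycle of roles and
    # mark a slice of receptor atoms so the pharmacophore stage is exercisable
    role_cycle = (ROLE_DONOR, ROLE_ACCEPTOR, ROLE_NEG, ROLE_HYDROPHOBIC, ROLE_POS)
    ligand_annotations: dict[str, dict[int, frozenset]] = {}
    for compound in compounds:
        ligand_annotations[compound.compound_id] = {
            i: frozenset({role_cycle[i % len(role_cycle)]})
            for i in range(config.ligand_atoms)
        }
    receptor_roles = (ROLE_ACCEPTOR, ROLE_DONOR, ROLE_POS, ROLE_HYDROPHOBIC, ROLE_NEG)
    receptor_annotations = {
        atom_id: frozenset({receptor_roles[i % len(receptor_roles)]})
        for i, atom_id in enumerate(site.atom_ids)
    }

    return FixtureBundle(
        site=site,
        poses=poses,
        scores=scores,
        compounds=compounds,
        ligand_annotations=ligand_annotations,
        receptor_annotations=receptor_annotations,
        intended_bits=intended,
        config=config,
    )


def write_bundle(bundle: FixtureBundle, out_dir) -> dict[str, str]:
    """Write the bundle in the same plain-text formats the ingest CLI reads."""
    import csv
    from pathlib import Path

    from .io_model import (
        write_activities_csv,
        write_poses_sdf,
        write_receptor_pdb,
        write_scores_csv,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "receptor": str(out / "site.pdb"),
        "poses": str(out / "poses.sdf"),
        "scores": str(out / "scores.csv"),
        "activities": str(out / "activities.csv"),
        "annotations": str(out / "annotations.csv"),
    }
    write_receptor_pdb(bundle.site, paths["receptor"])
    write_poses_sdf(bundle.poses, paths["poses"])
    write_scores_csv(bundle.scores, paths["scores"])
    write_activities_csv(bundle.compounds, paths["activities"])
    with open(paths["annotations"], "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["scope", "atom_ref", "roles"])
        for atom_id, roles in bundle.receptor_annotations.items():
            writer.writerow(["receptor", atom_id, "|".join(sorted(roles))])
        for compound_id, per_atom in bundle.ligand_annotations.items():
            for idx, roles in per_atom.items():
                writer.writerow(
                    [f"ligand:{compound_id}", idx, "|".join(sorted(roles))]
                )
    return paths


# ---------------------------------------------------------------------------
# end-to-end recovery harness
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    seed: int
    kappa_test: float
    best_learner: str
    selected_descriptors: list[str]
    consistent_descriptors: list[str]
    planted_descriptors: list[str]
    n_planted_selected: int
    n_planted_consistent: int
    threshold_percent: float | None
    excluded_compounds: list[str]


def end_to_end_recovery(
    config: FixtureConfig,
    learner: str = "rf",
    min_votes: int = 1,
    rmsd_threshold: float = 2.0,
    preset: str = "desk",
    learners: Sequence[str] = ("rf",),
    shap_max_rows: int = 400,
) -> RecoveryReport:
    """Generate fixtures and run the whole pipeline, reporting signal recovery.

    Stages: contacts → consensus votes → RMSD dedup → every-fifth split →
    learner scan → two-phase GA selection → SHAP consistency → active-pose-
    ratio threshold.  The report states whether the planted contact columns
    survive into the SHAP-consistent descriptor set.
    """
    from . import consensus_dedup, contacts, gfa_select, labeling_split, ml_engine
    from . import screening as screening_mod
    from . import shap_consistency as shap_mod

    bundle = generate(config)
    compound_of = bundle.compound_of()

    votes = consensus_dedup.consensus_votes(bundle.scores)
    votes_map = {v.pose_id: v.votes for v in votes}

    by_compound: dict[str, list[Pose]] = {}
    for pose in bundle.poses:
        by_compound.setdefault(pose.compound_id, []).append(pose)
    surviving: list[Pose] = []
    for compound_poses in by_compound.values():
        result = consensus_dedup.dedup_poses(
            compound_poses, votes_map, rmsd_threshold=rmsd_threshold
        )
        keep = {pid for pid in result.kept}
        pool = [p for p in compound_poses if p.pose_id in keep]
        surviving.extend(
            consensus_dedup.filter_by_consensus(pool, votes_map, min_votes)
        )

    fp, pose_ids = contacts.build_fingerprint_matrix(surviving, bundle.site)
    matrix = ml_engine.assemble_features(
        fp,
        pose_ids,
        bundle.site.atom_ids,
        bundle.scores,
        bundle.labels_by_compound(),
        compound_of,
    )
    matrix = matrix.drop_class(INTERMEDIATE)

    split = labeling_split.split_every_fifth(
        [c for c in bundle.compounds if c.activity_class != INTERMEDIATE],
        seed=config.seed,
    )

    reports = ml_engine.scan_learners(
        matrix, split, learners=learners, seed=config.seed, fast=True
    )
    best = reports[0]

    selected, _ = gfa_select.two_phase_select(
        matrix, split, learner=learner, seed=config.seed, preset=preset
    )

    # SHAP on the refitted model over the selected descriptors, testing rows only
    sub = matrix.subset_columns(selected)
    train_mask, test_mask = ml_engine.partition_rows(sub, split)
    model = ml_engine.make_learner(learner, seed=config.seed, fast=True)
    model.fit(sub.X[train_mask], sub.y()[train_mask])
    test_rows = np.flatnonzero(test_mask)
    rng = np.random.default_rng(config.seed)
    if len(test_rows) > shap_max_rows:
        test_rows = np.sort(rng.choice(test_rows, size=shap_max_rows, replace=False))
    background = shap_mod.kmeans_background(
        sub.X[test_mask], k=min(50, int(test_mask.sum())), seed=config.seed
    )
    contribs, _ = shap_mod.shap_values(
        model,
        sub.X[test_rows],
        background,
        class_label=ACTIVE,
        n_permutations=8,
        seed=config.seed,
    )
    row_labels = [sub.labels[sub.pose_ids[i]] for i in test_rows]
    summaries = shap_mod.summarize_by_class(contribs, selected, row_labels)
    consistent = shap_mod.filter_consistent(summaries)

    # active-pose-ratio threshold over documented actives in the testing set
    pred = model.predict(sub.X)
    ratio_records = []
    for compound_id in sorted(split.testing_compounds):
        if bundle.labels_by_compound().get(compound_id) != ACTIVE:
            continue
        rows = [i for i, p in enumerate(sub.pose_ids)
                if sub.compound_of[p] == compound_id]
        if not rows:
            continue
        n_act = int(np.sum(pred[rows] == ACTIVE))
        ratio_records.append(
            screening_mod.PoseRatioRecord(
                compound_id=compound_id,
                n_active_poses=n_act,
                n_inactive_poses=len(rows) - n_act,
            )
        )
    threshold = None
    excluded: list[str] = []
    if ratio_records:
        try:
            decision = screening_mod.derive_threshold(ratio_records)
            threshold = decision.threshold_percent
            excluded = [c for c, _ in decision.excluded_compounds]
        except ValueError:
            pass

    planted_ids = bundle.planted_column_ids()
    return RecoveryReport(
        seed=config.seed,
        kappa_test=best.kappa_test,
        best_learner=best.learner_name,
        selected_descriptors=selected,
        consistent_descriptors=consistent,
        planted_descriptors=planted_ids,
        n_planted_selected=len(set(selected) & set(planted_ids)),
        n_planted_consistent=len(set(consistent) & set(planted_ids)),
        threshold_percent=threshold,
        excluded_compounds=excluded,
    )
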