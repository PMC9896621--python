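import math

import numpy as np
import pytest

from posevote.pharmacophore import (
    FEATURE_COUNT_RANGE,
    HBA,
    HBD,
    HBIC,
    NEGION,
    POSION,
    ModelTooSmallError,
    PharmacophoreFeature,
    PharmacophoreModel,
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_HYDROPHOBIC,
    ROLE_NEG,
    ROLE_POS,
    TypedAtomAnnotation,
    build_model,
    detect_interactions,
    map_compound,
    read_annotations_csv,
)

from conftest import make_pose, make_site


def site_with_roles(points_roles):
    """points_roles: list of (xyz, roles). Returns (site, receptor_annotations)."""
    site = make_site([p for p, _ in points_roles])
    annotations = {
        atom_id: frozenset(roles)
        for atom_id, (_, roles) in zip(site.atom_ids, points_roles)
    }
    return site, annotations


class TestDetectInteractions:
    def test_acceptor_within_4A_gives_hba(self):
        site, rec_ann = site_with_roles([((3.5, 0, 0), {ROLE_DONOR})])
        pose = make_pose([(0.0, 0, 0)], elements=["O"])
        feats = detect_interactions(pose, site, {0: {ROLE_ACCEPTOR}}, rec_ann)
        assert [f.kind for f in feats] == [HBA]
        assert feats[0].position == (0.0, 0.0, 0.0)
        assert feats[0].direction == (1.0, 0.0, 0.0)

    def test_pair_beyond_4A_ignored(self):
        site, rec_ann = site_with_roles([((4.5, 0, 0), {ROLE_DONOR})])
        pose = make_pose([(0.0, 0, 0)], elements=["O"])
        assert detect_interactions(pose, site, {0: {ROLE_ACCEPTOR}}, rec_ann) == []

    def test_hbond_boundary_inclusive(self):
        site, rec_ann = site_with_roles([((4.0, 0, 0), {ROLE_ACCEPTOR})])
        pose = make_pose([(0.0, 0, 0)], elements=["N"])
        feats = detect_interactions(pose, site, {0: {ROLE_DONOR}}, rec_ann)
        assert [f.kind for f in feats] == [HBD]

    def test_negion_distance_window(self):
        site, rec_ann = site_with_roles([((7.9, 0, 0), {ROLE_POS})])
        pose = make_pose([(0.0, 0, 0)], elements=["O"])
        feats = detect_interactions(pose, site, {0: {ROLE_NEG}}, rec_ann)
        assert [f.kind for f in feats] == [NEGION]
        site, rec_ann = site_with_roles([((8.1, 0, 0), {ROLE_POS})])
        assert detect_interactions(pose, site, {0: {ROLE_NEG}}, rec_ann) == []

    def test_posion_from_positive_ligand_atom(self):
        site, rec_ann = site_with_roles([((5.0, 0, 0), {ROLE_NEG})])
        pose = make_pose([(0.0, 0, 0)], elements=["N"])
        feats = detect_interactions(pose, site, {0: {ROLE_POS}}, rec_ann)
        assert [f.kind for f in feats] == [POSION]

    def test_hydrophobic_centroid_within_5p5(self):
        site, rec_ann = site_with_roles([((5.0, 0, 0), {ROLE_HYDROPHOBIC})])
        pose = make_pose([(0.0, 0, 0)], elements=["C"])
        feats = detect_interactions(pose, site, {0: {ROLE_HYDROPHOBIC}}, rec_ann)
        assert [f.kind for f in feats] == [HBIC]

    def test_unannotated_atoms_ignored(self):
        site, rec_ann = site_with_roles([((1.0, 0, 0), {ROLE_DONOR})])
        pose = make_pose([(0.0, 0, 0)], elements=["O"])
        assert detect_interactions(pose, site, {}, rec_ann) == []

    def test_water_partner_supported(self):
        # annotated water oxygen acts as receptor-side donor partner
        from conftest import make_atom
        from posevote.io_model import BindingSite

        water = make_atom(name="OH2", resname="HOH", resnum=107, element="O",
                          coords=(3.0, 0, 0))
        site = BindingSite(atoms=[water])
        rec_ann = {site.atom_ids[0]: frozenset({ROLE_DONOR})}
        pose = make_pose([(0.0, 0, 0)], elements=["O"])
        feats = detect_interactions(pose, site, {0: {ROLE_ACCEPTOR}}, rec_ann)
        assert [f.kind for f in feats] == [HBA]


def well_separated_candidates(n, kind=HBA):
    feats = []
    for i in range(n):
        feats.append(
            PharmacophoreFeature(
                kind=kind,
                position=(3.0 * i, 0.0, 0.0),
                direction=(0.0, 0.0, 1.0) if kind in (HBA, HBD) else None,
                interaction_distance=2.0 + 0.1 * i,
            )
        )
    return feats


class TestBuildModel:
    def test_five_candidates_give_five_features(self):
        model = build_model(well_separated_candidates(5), source_pose_id="P")
        assert len(model.features) == 5

    def test_close_pair_merged(self):
        close = [
            PharmacophoreFeature(HBA, (0.0, 0, 0), (0, 0, 1.0),
                                 interaction_distance=2.0),
            PharmacophoreFeature(HBA, (0.5, 0, 0), (0, 0, 1.0),
                                 interaction_distance=3.0),
        ]
        model = build_model(close + well_separated_candidates(4, HBIC)[1:],
                            source_pose_id="P")
        hba = [f for f in model.features if f.kind == HBA]
        assert len(hba) == 1
        assert hba[0].position == pytest.approx((0.25, 0.0, 0.0))

    def test_eight_candidates_capped_at_six_with_ionic_priority(self):
        ionic = [
            PharmacophoreFeature(NEGION, (0.0, 10.0 + 3 * i, 0.0),
                                 interaction_distance=5.0)
            for i in range(2)
        ]
        hbic = well_separated_candidates(6, HBIC)
        model = build_model(ionic + hbic, source_pose_id="P")
        assert len(model.features) == 6
        assert sum(1 for f in model.features if f.kind == NEGION) == 2

    def test_too_few_candidates_raise_with_dump(self):
        candidates = well_separated_candidates(3)
        with pytest.raises(ModelTooSmallError) as err:
            build_model(candidates, source_pose_id="P")
        assert err.value.candidates == candidates

    def test_feature_count_invariant(self):
        for n in range(4, 12):
            model = build_model(well_separated_candidates(n), source_pose_id="P")
            lo, hi = FEATURE_COUNT_RANGE
            assert lo <= len(model.features) <= hi

    def test_min_interfeature_distance_enforced(self):
        model = build_model(well_separated_candidates(6), source_pose_id="P")
        d = model.distance_matrix()
        off_diag = d[~np.eye(len(model.features), dtype=bool)]
        assert (off_diag >= 1.0).all()


class TestRigidMotionInvariance:
    def test_congruent_model_after_rotation_translation(self):
        rng = np.random.default_rng(0)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([5.0, -3.0, 2.0])

        lig_pts = np.array([[0.0, 0, 0], [6.0, 0, 0], [0, 6.0, 0], [6.0, 6.0, 0]])
        rec_pts = lig_pts + np.array([3.0, 0.5, 0.5])
        lig_ann = {i: frozenset({ROLE_ACCEPTOR}) for i in range(4)}

        def build(l, r):
            site, rec_ann = site_with_roles([(tuple(p), {ROLE_DONOR}) for p in r])
            pose = make_pose(l, elements=["O"] * 4)
            return build_model(
                detect_interactions(pose, site, lig_ann, rec_ann), source_pose_id="P"
            )

        m1 = build(lig_pts, rec_pts)
        m2 = build(lig_pts @ q.T + shift, rec_pts @ q.T + shift)
        assert len(m1.features) == len(m2.features)
        assert sorted(f.kind for f in m1.features) == sorted(
            f.kind for f in m2.features
        )
        np.testing.assert_allclose(
            np.sort(m1.distance_matrix(), axis=None),
            np.sort(m2.distance_matrix(), axis=None),
            atol=1e-6,
        )


class TestMapCompound:
    def build_simple_model(self):
        candidates = [
            PharmacophoreFeature(HBA, (0.0, 0, 0), (0, 0, 1.0),
                                 interaction_distance=2.0),
            PharmacophoreFeature(HBD, (4.0, 0, 0), (0, 0, 1.0),
                                 interaction_distance=2.5),
            PharmacophoreFeature(HBIC, (8.0, 0, 0), interaction_distance=3.0),
            PharmacophoreFeature(NEGION, (12.0, 0, 0), interaction_distance=4.0),
        ]
        return build_model(candidates, source_pose_id="P")

    def test_self_match_attains_maximum(self):
        model = self.build_simple_model()
        pose = make_pose(
            [(0.0, 0, 0), (4.0, 0, 0), (8.0, 0, 0), (12.0, 0, 0)],
            elements=["O", "N", "C", "O"],
        )
        ann = {
            0: {ROLE_ACCEPTOR},
            1: {ROLE_DONOR},
            2: {ROLE_HYDROPHOBIC},
            3: {ROLE_NEG},
        }
        assert map_compound(model, pose, ann) == pytest.approx(len(model.features))

    def test_no_compatible_atoms_scores_zero(self):
        model = self.build_simple_model()
        pose = make_pose([(0.0, 0, 0)], elements=["C"])
        assert map_compound(model, pose, {}) == 0.0

    def test_partial_match_counts_one_feature(self):
        candidates = [
            PharmacophoreFeature(HBA, (0.0, 0, 0), (0, 0, 1.0),
                                 interaction_distance=2.0),
            PharmacophoreFeature(HBD, (4.0, 0, 0), (0, 0, 1.0),
                                 interaction_distance=2.0),
            PharmacophoreFeature(HBIC, (8.0, 0, 0), interaction_distance=2.0),
            PharmacophoreFeature(NEGION, (12.0, 0, 0), interaction_distance=2.0),
        ]
        model = build_model(candidates, source_pose_id="P")
        pose = make_pose([(0.0, 0, 0), (100.0, 0, 0)], elements=["O", "N"])
        ann = {0: {ROLE_ACCEPTOR}, 1: {ROLE_DONOR}}
        score = map_compound(model, pose, ann)
        assert score == pytest.approx(1.0)  # exactly one feature, distance 0

    def test_distance_weighting(self):
        model = self.build_simple_model()
        pose = make_pose([(0.75, 0, 0)], elements=["O"])
        score = map_compound(model, pose, {0: {ROLE_ACCEPTOR}},
                             match_tolerance=1.5)
        assert score == pytest.approx(0.5)

    def test_greedy_one_to_one_assignment(self):
        model = self.build_simple_model()
        # one acceptor atom cannot satisfy two features
        pose = make_pose([(0.0, 0, 0)], elements=["O"])
        score = map_compound(model, pose, {0: {ROLE_ACCEPTOR, ROLE_DONOR}})
        assert score == pytest.approx(1.0)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        model = build_model(well_separated_candidates(5), source_pose_id="P5",
                            generation_params={"hbond": 4.0})
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PharmacophoreModel.from_json(path.read_text())
        assert back.source_pose_id == "P5"
        assert len(back.features) == len(model.features)
        np.testing.assert_allclose(back.distance_matrix(), model.distance_matrix())

    def test_annotation_csv_roundtrip(self, tmp_path, tiny_bundle):
        from posevote.synthetic_fixtures import write_bundle

        paths = write_bundle(tiny_bundle, tmp_path)
        rec, lig = read_annotations_csv(paths["annotations"])
        assert rec == tiny_bundle.receptor_annotations
        assert lig == tiny_bundle.ligand_annotations


class TestAnnotationType:
    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="unknown roles"):
            TypedAtomAnnotation("X", frozenset({"magic"}))
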