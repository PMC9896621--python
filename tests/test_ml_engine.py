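import numpy as np
import pytest

from posevote.io_model import ACTIVE, INACTIVE, INTERMEDIATE
from posevote.labeling_split import split_every_fifth
from posevote.ml_engine import (
    ConfusionCounts,
    FeatureMatrix,
    PNNClassifier,
    accuracy,
    assemble_features,
    cohens_kappa,
    cv_metrics,
    expand_learner_names,
    make_learner,
    partition_rows,
    roc_curve,
    scan_learners,
)
from posevote.contacts import build_fingerprint_matrix


class TestAccuracy:
    def test_perfect(self):
        counts = ConfusionCounts.binary(tp=10, tn=10, fp=0, fn=0)
        assert accuracy(counts) == 1.0

    def test_everything_wrong(self):
        counts = ConfusionCounts.binary(tp=0, tn=0, fp=10, fn=10)
        assert accuracy(counts) == 0.0

    def test_hand_computed(self):
        counts = ConfusionCounts.binary(tp=40, tn=30, fp=20, fn=10)
        assert accuracy(counts) == pytest.approx(0.7)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            ConfusionCounts.binary(0, 0, 0, 0)

    def test_multiclass_trace(self):
        table = np.array([[5, 1, 0], [0, 7, 1], [2, 0, 4]])
        counts = ConfusionCounts(table, ["a", "b", "c"])
        assert accuracy(counts) == pytest.approx(16 / 20)


class TestCohensKappa:
    def test_complete_agreement_is_one(self):
        counts = ConfusionCounts(np.array([[10, 0], [0, 10]]), ["a", "b"])
        assert cohens_kappa(counts) == pytest.approx(1.0)

    def test_chance_level_is_zero(self):
        counts = ConfusionCounts(np.array([[25, 25], [25, 25]]), ["a", "b"])
        assert cohens_kappa(counts) == pytest.approx(0.0)

    def test_hand_computed_point_four(self):
        # P0 = 0.7; marginals rows (50, 50), cols (60, 40) -> Pe = 0.5
        counts = ConfusionCounts(np.array([[40, 10], [20, 30]]), ["a", "b"])
        assert cohens_kappa(counts) == pytest.approx(0.4)

    def test_degenerate_returns_zero(self):
        counts = ConfusionCounts(np.array([[10, 0], [0, 0]]), ["a", "b"])
        assert cohens_kappa(counts) == 0.0

    def test_worse_than_chance_is_negative(self):
        counts = ConfusionCounts(np.array([[5, 45], [45, 5]]), ["a", "b"])
        assert cohens_kappa(counts) < 0

    def test_kappa_one_iff_accuracy_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            table = rng.integers(0, 20, size=(2, 2)).astype(float)
            if table.sum() == 0:
                continue
            counts = ConfusionCounts(table, ["a", "b"])
            row = table.sum(axis=1)
            col = table.sum(axis=0)
            degenerate = (row == 0).any() or (col == 0).any()
            if degenerate:
                continue
            assert (cohens_kappa(counts) == pytest.approx(1.0)) == (
                accuracy(counts) == pytest.approx(1.0)
            )

    def test_from_labels(self):
        counts = ConfusionCounts.from_labels(
            ["a", "a", "b", "b"], ["a", "b", "b", "b"]
        )
        assert counts.table.tolist() == [[1, 1], [0, 2]]


def auc_by_pair_counting(scores, labels, pos="pos"):
    """Concordant-pair oracle (ties count 1/2)."""
    pos_scores = [s for k, s in scores.items() if labels[k] == pos]
    neg_scores = [s for k, s in scores.items() if labels[k] != pos]
    total = concordant = 0
    for p in pos_scores:
        for n in neg_scores:
            total += 1
            concordant += 1.0 if p > n else 0.5 if p == n else 0.0
    return concordant / total


class TestRocCurve:
    def test_perfect_separation(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}
        labels = {"a": "pos", "b": "pos", "c": "neg", "d": "neg"}
        result = roc_curve(scores, labels)
        assert result.auc == pytest.approx(1.0)
        assert result.sensitivity == pytest.approx(1.0)
        assert result.specificity == pytest.approx(1.0)

    def test_identical_scores_half(self):
        scores = {k: 0.5 for k in "abcd"}
        labels = {"a": "pos", "b": "pos", "c": "neg", "d": "neg"}
        assert roc_curve(scores, labels).auc == pytest.approx(0.5)

    def test_four_item_toy_three_quarters(self):
        scores = {"p1": 0.9, "p2": 0.6, "n1": 0.7, "n2": 0.2}
        labels = {"p1": "pos", "p2": "pos", "n1": "neg", "n2": "neg"}
        assert roc_curve(scores, labels).auc == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve({"a": 0.5}, {"a": "pos"})

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            scores = {f"i{j}": round(float(rng.normal()), 1) for j in range(n)}
            labels = {k: "pos" if rng.random() < 0.5 else "neg" for k in scores}
            if len(set(labels.values())) < 2:
                continue
            got = roc_curve(scores, labels).auc
            assert got == pytest.approx(auc_by_pair_counting(scores, labels))


def planted_matrix(n_poses=300, n_features=12, signal_cols=(0, 1), seed=0):
    rng = np.random.default_rng(seed)
    # one compound per 3 poses; each pose inherits its compound's label
    compound_of = {f"P{i}": f"C{i // 3}" for i in range(n_poses)}
    compound_label = {
        f"C{c}": ACTIVE if rng.random() < 0.5 else INACTIVE
        for c in range(-(-n_poses // 3))
    }
    labels = {p: compound_label[compound_of[p]] for p in compound_of}
    labels_arr = np.array([labels[f"P{i}"] for i in range(n_poses)])
    X = (rng.random((n_poses, n_features)) < 0.2).astype(float)
    for c in signal_cols:
        p = np.where(labels_arr == ACTIVE, 0.9, 0.1)
        X[:, c] = (rng.random(n_poses) < p).astype(float)
    return FeatureMatrix(
        X=X,
        columns=[f"f{j}" for j in range(n_features)],
        pose_ids=[f"P{i}" for i in range(n_poses)],
        labels=labels,
        compound_of=compound_of,
    )


def compound_split(matrix, seed=0):
    from posevote.io_model import CompoundRecord

    ids = sorted(set(matrix.compound_of.values()))
    recs = [CompoundRecord(cid, "C", 100.0, ACTIVE) for cid in ids]
    return split_every_fifth(recs, seed=seed)


class TestScanLearners:
    def test_planted_signal_recovered(self):
        matrix = planted_matrix(seed=4)
        split = compound_split(matrix)
        reports = scan_learners(
            matrix, split, learners=("rf", "nb"), seed=0, fast=True
        )
        assert reports[0].kappa_test > 0.5
        assert reports == sorted(reports, key=lambda r: -r.kappa_test)

    def test_permuted_labels_near_chance(self):
        matrix = planted_matrix(n_poses=600, seed=5)
        rng = np.random.default_rng(13)
        permuted = list(matrix.labels.values())
        # permute at compound level to keep within-compound consistency
        ids = sorted(set(matrix.compound_of.values()))
        label_of = {cid: matrix.labels[f"P{3 * int(cid[1:])}"] for cid in ids}
        shuffled = rng.permutation([label_of[c] for c in ids])
        new_label_of = dict(zip(ids, shuffled))
        matrix.labels = {
            p: new_label_of[matrix.compound_of[p]] for p in matrix.pose_ids
        }
        split = compound_split(matrix)
        reports = scan_learners(
            matrix, split, learners=("rf", "nb", "knn"), seed=0, fast=True,
            knn_ks=(5,),
        )
        for report in reports:
            assert abs(report.kappa_test) < 0.15, report

    def test_single_class_training_raises(self):
        matrix = planted_matrix(seed=6)
        matrix.labels = {p: ACTIVE for p in matrix.pose_ids}
        split = compound_split(matrix)
        with pytest.raises(ValueError, match="single class"):
            scan_learners(matrix, split, learners=("rf",), seed=0)

    def test_constant_features_give_chance_kappa(self):
        matrix = planted_matrix(seed=7)
        matrix.X = np.zeros_like(matrix.X)
        split = compound_split(matrix)
        reports = scan_learners(matrix, split, learners=("rf",), seed=0, fast=True)
        assert abs(reports[0].kappa_test) <= 0.2

    def test_cv_is_seed_reproducible(self):
        matrix = planted_matrix(seed=8)
        split = compound_split(matrix)
        r1 = scan_learners(matrix, split, learners=("rf",), seed=3, fast=True)
        r2 = scan_learners(matrix, split, learners=("rf",), seed=3, fast=True)
        assert r1[0].kappa_cv == r2[0].kappa_cv
        assert r1[0].kappa_test == r2[0].kappa_test

    def test_knn_variants_expand(self):
        names = expand_learner_names(["rf", "knn"], knn_ks=(1, 3))
        assert names == ["rf", "knn(k=1)", "knn(k=3)", "knn-wd(k=1)", "knn-wd(k=3)"]

    def test_three_class_mode_keeps_intermediates(self):
        matrix = planted_matrix(seed=9)
        # relabel one third as intermediate
        for i, p in enumerate(matrix.pose_ids):
            if int(matrix.compound_of[p][1:]) % 3 == 0:
                matrix.labels[p] = INTERMEDIATE
        split = compound_split(matrix)
        reports = scan_learners(
            matrix, split, learners=("rf",), seed=0,
            drop_intermediates=False, fast=True,
        )
        assert len(reports) == 1  # runs through in 3-class mode


class TestPnn:
    def test_separable_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(3, 0.3, (40, 2))])
        y = np.array(["a"] * 40 + ["b"] * 40)
        model = PNNClassifier(bandwidth=0.5).fit(X, y)
        assert (model.predict(X) == y).mean() > 0.95
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_bandwidth_grid_selection(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.5, (30, 2)), rng.normal(2, 0.5, (30, 2))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        model = PNNClassifier().fit(X, y)
        assert model.bandwidth_ in (0.25, 0.5, 1.0, 2.0)


class TestAssembleFeatures:
    def test_joins_bits_and_scores(self, tiny_bundle):
        fp, pose_ids = build_fingerprint_matrix(tiny_bundle.poses, tiny_bundle.site)
        matrix = assemble_features(
            fp,
            pose_ids,
            tiny_bundle.site.atom_ids,
            tiny_bundle.scores,
            tiny_bundle.labels_by_compound(),
            tiny_bundle.compound_of(),
        )
        n_scores = len(tiny_bundle.scores.score_names)
        assert matrix.X.shape[1] == len(tiny_bundle.site.atom_ids) + n_scores
        assert matrix.X.shape[0] == len(tiny_bundle.poses)
        # score columns carry the raw values
        j = matrix.columns.index(tiny_bundle.scores.score_names[0])
        pid = matrix.pose_ids[0]
        assert matrix.X[0, j] == pytest.approx(
            tiny_bundle.scores.rows[pid][tiny_bundle.scores.score_names[0]]
        )

    def test_poses_without_scores_dropped(self, tiny_bundle):
        fp, pose_ids = build_fingerprint_matrix(tiny_bundle.poses, tiny_bundle.site)
        scores = tiny_bundle.scores
        victim = pose_ids[0]
        reduced_rows = {k: v for k, v in scores.rows.items() if k != victim}
        reduced = type(scores)(rows=reduced_rows, directions=scores.directions)
        matrix = assemble_features(
            fp,
            pose_ids,
            tiny_bundle.site.atom_ids,
            reduced,
            tiny_bundle.labels_by_compound(),
            tiny_bundle.compound_of(),
        )
        assert victim not in matrix.pose_ids


class TestPartitionRows:
    def test_masks_follow_compounds(self):
        matrix = planted_matrix(n_poses=30, seed=2)
        split = compound_split(matrix)
        train, test = partition_rows(matrix, split)
        for pose_id, tr, te in zip(matrix.pose_ids, train, test):
            cid = matrix.compound_of[pose_id]
            assert tr == (cid in split.training_compounds)
            assert te == (cid in split.testing_compounds)
        assert not (train & test).any()
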