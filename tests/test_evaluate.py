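import importlib

import numpy as np
import pytest

# the package re-exports the evaluate *function* at leafmorph.evaluate, so
# fetch the submodule itself for monkeypatching
ev = importlib.import_module("leafmorph.evaluate")
from leafmorph.evaluate import random_split, evaluate, EvalReport
from leafmorph.features import FeatureMatrix, assemble_features
from leafmorph.classify import ClassifierSpec
from leafmorph.errors import InvalidInputError


def random_blocks(n, seed=0):
    rng = np.random.default_rng(seed)
    return [
        {
            "msd": rng.normal(size=20),
            "hog": rng.normal(size=81),
            "hu": rng.normal(size=7),
            "zm": rng.normal(size=25),
        }
        for _ in range(n)
    ]


class TestAssemble:
    @pytest.mark.parametrize(
        "combo,width",
        [
            (("msd",), 20),
            (("msd", "hog", "hu", "zm"), 133),
            (("hu", "zm"), 32),
            (("hog",), 81),
        ],
    )
    def test_dimensionality(self, combo, width):
        fm = assemble_features(random_blocks(6), np.arange(6) % 2, combo)
        assert fm.n_features == width

    def test_fixed_block_order_regardless_of_request(self):
        blocks = random_blocks(3)
        a = assemble_features(blocks, np.zeros(3), ("zm", "msd"))
        b = assemble_features(blocks, np.zeros(3), ("msd", "zm"))
        assert a.feature_names == b.feature_names
        assert a.feature_names[0].startswith("msd")

    def test_missing_block_reports_image_ids(self):
        blocks = random_blocks(4)
        del blocks[2]["hog"]
        with pytest.raises(InvalidInputError, match="2"):
            assemble_features(blocks, np.zeros(4), ("msd", "hog"))


class TestRandomSplit:
    def test_paper_sized_split(self):
        labels = np.repeat(np.arange(45), 30)  # 1,350 samples
        tr, te = random_split(labels, 0.8, seed=0)
        assert len(tr) == 1080 and len(te) == 270
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 1350
        # stratification: 24 train per class
        for c in range(45):
            assert (labels[tr] == c).sum() == 24

    def test_same_seed_identical(self):
        labels = np.repeat(np.arange(5), 10)
        assert np.array_equal(random_split(labels, 0.8, 3)[0],
                              random_split(labels, 0.8, 3)[0])

    def test_full_train_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            random_split(np.repeat([0, 1], 10), 1.0, 0)

    def test_tiny_class_rejected(self):
        labels = np.array([0, 0, 0, 0, 1])
        with pytest.raises(InvalidInputError):
            random_split(labels, 0.8, 0)


def _feature_matrix(n_classes=10, per_class=12, d=5, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_classes), per_class)
    X = rng.normal(size=(len(labels), d)) + labels[:, None]
    return FeatureMatrix(X, [f"f{i}" for i in range(d)], labels)


class TestEvaluate:
    def test_perfect_classifier_stub(self, monkeypatch):
        fm = _feature_matrix()
        truth = {}

        def fake_train(spec, X, y):
            return ("oracle", X.tobytes())

        def fake_predict(model, X):
            return truth[X.tobytes()]

        monkeypatch.setattr(ev, "train_classifier", fake_train)
        monkeypatch.setattr(ev, "predict", fake_predict)
        # pre-register the answers for every repeat's test split
        for r in range(10):
            tr, te = random_split(fm.labels, 0.8, seed=r)
            truth[fm.values[te].tobytes()] = fm.labels[te]
        rep = evaluate(fm, ClassifierSpec("knn"), repeats=10, base_seed=0)
        assert rep.mean_accuracy == 1.0

    def test_majority_stub_is_chance_level(self, monkeypatch):
        fm = _feature_matrix(n_classes=10, per_class=20)
        monkeypatch.setattr(ev, "train_classifier", lambda s, X, y: y[0])
        monkeypatch.setattr(
            ev, "predict", lambda model, X: np.full(len(X), model)
        )
        rep = evaluate(fm, ClassifierSpec("knn"), repeats=10, base_seed=0)
        assert rep.mean_accuracy == pytest.approx(0.10, abs=0.02)

    def test_mean_equals_recomputed_mean(self):
        fm = _feature_matrix()
        rep = evaluate(fm, ClassifierSpec("knn"), repeats=5, base_seed=1)
        assert rep.mean_accuracy == np.mean(rep.accuracies)
        assert len(rep.accuracies) == 5
        assert rep.seeds == [1, 2, 3, 4, 5]

    def test_selection_sees_training_rows_only(self, monkeypatch):
        """No leakage: the selector is fitted on exactly the training split
        of each repeat."""
        fm = _feature_matrix(d=8)
        seen = []
        real = ev.select_features

        def spy(X, y, **kw):
            seen.append((X.copy(), np.asarray(y).copy(), kw["seed"]))
            return real(X, y, **kw)

        monkeypatch.setattr(ev, "select_features", spy)
        evaluate(
            fm,
            ClassifierSpec("knn"),
            selection={"method": "pcc", "keep_fraction": 0.5},
            repeats=3,
            base_seed=5,
        )
        assert len(seen) == 3  # refit per repeat
        for X, y, seed in seen:
            tr, _ = random_split(fm.labels, 0.8, seed=seed)
            assert np.array_equal(X, fm.values[tr])
            assert np.array_equal(y, fm.labels[tr])

    def test_test_only_marker_feature_cannot_be_selected(self):
        """A feature informative only on the test split must not be
        retained by training-split selection."""
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(5), 20)
        X = rng.normal(size=(100, 4))
        X[:, 0] += labels  # genuinely informative column
        seed = 11
        tr, te = random_split(labels, 0.8, seed=seed)
        X[te, 3] = labels[te]  # marker: perfect on test, noise on train
        fm = FeatureMatrix(X, ["inf", "n1", "n2", "marker"], labels)
        from leafmorph.featsel import select_features

        res = select_features(
            fm.values[tr], fm.labels[tr], method="pcc", keep_fraction=0.25,
            feature_names=fm.feature_names,
        )
        assert res.retained_names == ["inf"]

    def test_error_carries_repeat_index(self):
        fm = _feature_matrix(n_classes=2, per_class=3)
        bad = FeatureMatrix(fm.values[:5], fm.feature_names, np.array([0, 0, 0, 0, 1]))
        with pytest.raises(InvalidInputError, match="repeat 0"):
            evaluate(bad, ClassifierSpec("knn"), repeats=2, base_seed=0)

    def test_report_serialization(self, tmp_path):
        fm = _feature_matrix()
        rep = evaluate(fm, ClassifierSpec("knn"), repeats=2, base_seed=0)
        rep.save(tmp_path / "rep.json")
        import json

        loaded = json.loads((tmp_path / "rep.json").read_text())
        assert loaded["mean_accuracy"] == rep.mean_accuracy
        assert loaded["classifier"] == "knn"
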