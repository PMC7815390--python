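"""Cross-validation protocols and the grid-searched SVM."""

import numpy as np
import pandas as pd
import pytest

from exprfeat import EXPRESSIONS, ExpressionSVC, SVMConfig, make_folds, run_cv
from exprfeat.cv import ProtocolError

from conftest import FAST_SVM


def _manifest(n_subjects=10, n_classes=7, reps=1):
    rows = [
        {"path": f"s{s}_{EXPRESSIONS[c]}_{r}", "label": EXPRESSIONS[c],
         "subject": f"subj{s}"}
        for s in range(n_subjects) for c in range(n_classes) for r in range(reps)
    ]
    return pd.DataFrame(rows)


class TestMakeFolds:
    def test_sd_fold_sizes_and_stratification(self):
        m = _manifest(10, 7, 1)  # 70 images
        folds = make_folds(m, "SD", k=10, seed=0)
        assert sorted(np.concatenate(folds)) == list(range(70))
        labels = m["label"].to_numpy()
        for f in folds:
            assert len(f) == 7
            counts = pd.Series(labels[f]).value_counts()
            assert counts.max() - counts.min() <= 1

    def test_si_folds_never_split_subjects(self):
        m = _manifest(12, 5, 2)
        folds = make_folds(m, "SI", k=10, seed=3)
        subjects = m["subject"].to_numpy()
        all_idx = np.arange(len(m))
        for f in folds:
            train = np.setdiff1d(all_idx, f)
            assert not set(subjects[f]) & set(subjects[train])

    def test_determinism_and_row_order_invariance(self):
        m = _manifest(10, 7, 1)
        f1 = make_folds(m, "SD", k=10, seed=5)
        f2 = make_folds(m, "SD", k=10, seed=5)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)
        # shuffling rows must yield the same folds as sets of records
        perm = np.random.default_rng(0).permutation(len(m))
        shuffled = m.iloc[perm].reset_index(drop=True)
        f3 = make_folds(shuffled, "SD", k=10, seed=5)
        keys = m["path"].to_numpy()
        sets1 = [frozenset(keys[f]) for f in f1]
        sets3 = [frozenset(shuffled["path"].to_numpy()[f]) for f in f3]
        assert sorted(map(sorted, sets1)) == sorted(map(sorted, sets3))

    def test_protocol_errors(self):
        with pytest.raises(ProtocolError):
            make_folds(_manifest(5, 7), "SI", k=10, seed=0)
        with pytest.raises(ProtocolError):
            make_folds(_manifest(10, 7), "LOSO", k=10, seed=0)


class TestRunCv:
    def test_one_hot_features_are_perfectly_classified(self):
        m = _manifest(10, 7, 1)
        codes = np.array([EXPRESSIONS.index(l) for l in m["label"]])
        X = np.eye(7)[codes] * 10.0
        res = run_cv(X, m, protocol="SD", k=10, repeats=1, seed=0, svm_config=FAST_SVM)
        assert res.mean_accuracy == 1.0
        assert np.trace(res.confusion) == res.confusion.sum() == 70
        assert len(res.fold_accuracies) == 10

    def test_confusion_row_sums_match_class_counts(self):
        m = _manifest(10, 3, 1)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(len(m), 5))
        res = run_cv(X, m, protocol="SD", k=5, repeats=2, seed=0, svm_config=FAST_SVM)
        present = [EXPRESSIONS.index(l) for l in sorted(set(m["label"]))]
        for ci in present:
            assert res.confusion[ci].sum() == 2 * 10  # repeats * class count
        assert res.mean_accuracy == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum()
        )

    def test_si_not_above_sd_on_subject_shifted_data(self):
        """With a strong subject-specific nuisance component, evaluating on
        held-out subjects cannot beat subject-dependent folding."""
        rng = np.random.default_rng(2)
        m = _manifest(10, 3, 4)
        codes = np.array([EXPRESSIONS.index(l) for l in m["label"]])
        subj = np.array([int(s[4:]) for s in m["subject"]])
        subj_shift = rng.normal(0, 4.0, (10, 6))
        X = np.eye(3)[codes] @ rng.normal(0, 1, (3, 6)) + subj_shift[subj]
        X += rng.normal(0, 0.3, X.shape)
        sd = run_cv(X, m, "SD", k=5, repeats=2, seed=0, svm_config=FAST_SVM)
        si = run_cv(X, m, "SI", k=10, repeats=2, seed=0, svm_config=FAST_SVM)
        assert si.mean_accuracy <= sd.mean_accuracy

    def test_result_serialization(self):
        m = _manifest(10, 3, 1)
        X = np.eye(3)[[EXPRESSIONS.index(l) for l in m["label"]]]
        res = run_cv(X, m, "SD", k=3, repeats=1, seed=0, svm_config=FAST_SVM)
        d = res.to_dict()
        assert d["protocol"] == "SD" and len(d["confusion"]) == 7
        assert d["mean_accuracy"] == res.mean_accuracy

    def test_unknown_label_rejected(self):
        m = _manifest(10, 3, 1)
        m.loc[0, "label"] = "boredom"
        with pytest.raises(ValueError, match="unknown expression"):
            run_cv(np.zeros((len(m), 2)), m, "SD", svm_config=FAST_SVM)


class TestExpressionSVC:
    def test_fit_predict_and_sklearn_protocol(self):
        from sklearn.base import clone

        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(i * 3, 0.5, (20, 4)) for i in range(3)])
        y = np.repeat(["a", "b", "c"], 20)
        clf = ExpressionSVC(svm_config=FAST_SVM, random_state=0)
        clone(clf)  # get_params/set_params round-trip
        clf.fit(X, y)
        assert set(clf.classes_) == {"a", "b", "c"}
        assert clf.C_ in FAST_SVM.C_grid
        assert clf.score(X, y) == 1.0
        assert clf.predict(np.full((1, 4), 3.0))[0] == "b"
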