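"""SVM classification and the two cross-validation protocols.

Two evaluation protocols are standard for expression recognition:

* subject-dependent (SD): images are partitioned at random (stratified by
  expression label), so a person seen in training may reappear at test —
  the optimistic setting;
* subject-independent (SI): *subjects* are partitioned, so every test
  image shows a person the classifier has never seen — the deployment
  setting.  SI accuracy is typically below SD accuracy.

The classifier is an RBF-kernel SVM (one-vs-one multiclass, as in
LibSVM), with C and gamma chosen per training fold by an inner
cross-validated grid search so model selection never sees test data.
Gamma is parameterized as a multiplier of the scale heuristic
1 / (d * Var(X_train)), which keeps the grid meaningful regardless of
feature dimension and spread.  All kernels are evaluated from a single
precomputed pairwise squared-distance matrix, which makes the nested
search cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: Canonical closed label set, alphabetical; confusion-matrix axis order.
EXPRESSIONS = ("anger", "disgust", "fear", "happy", "neutral", "sad", "surprise")


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameter grid for the inner model selection.

    C_grid: absolute soft-margin values (powers of two spanning 2^-3..2^10).
    gamma_grid: multipliers of the per-fold scale gamma 1/(d*Var(X_train)).
    inner_k: folds of the inner selection CV.
    """

    C_grid: tuple = tuple(2.0**p for p in (-3, -1, 1, 3, 5, 7, 9, 10))
    gamma_grid: tuple = tuple(2.0**p for p in (-4, -2, 0, 2, 4))
    inner_k: int = 3


@dataclass
class CVResult:
    """Outcome of a repeated k-fold cross-validation run."""

    protocol: str
    k: int
    repeats: int
    fold_accuracies: list[float]
    confusion: np.ndarray
    labels: tuple = EXPRESSIONS
    notes: list[str] = field(default_factory=list)
    best_params: list[tuple] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else float("nan")

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies)) if self.fold_accuracies else float("nan")

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "k": self.k,
            "repeats": self.repeats,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "notes": list(self.notes),
        }


def _sorted_order(manifest: pd.DataFrame) -> np.ndarray:
    """Positions of records in sorted-key order, so folds are invariant to
    the row order of the manifest."""
    keys = manifest["path"].astype(str).to_numpy()
    return np.argsort(keys, kind="stable")


def make_folds(
    manifest: pd.DataFrame,
    protocol: str,
    k: int = 10,
    seed: int = 0,
) -> list[np.ndarray]:
    """Build k disjoint test partitions (as integer row positions).

    protocol "SD": label-stratified random partition of images — a subject
    may appear on both sides of a fold.  protocol "SI": random partition
    of *subjects* into k groups; no subject ever spans train and test.
    Deterministic given seed, and independent of manifest row order.
    """
    if protocol not in ("SD", "SI"):
        raise ProtocolError(f"protocol must be 'SD' or 'SI', got {protocol!r}")
    order = _sorted_order(manifest)
    labels = manifest["label"].to_numpy()[order]
    subjects = manifest["subject"].astype(str).to_numpy()[order]
    if protocol == "SD":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
        return [order[test] for _, test in skf.split(np.zeros(len(labels)), labels)]
    uniq = np.array(sorted(set(subjects)))
    if len(uniq) < k:
        raise ProtocolError(
            f"subject-independent CV needs at least {k} subjects, have {len(uniq)}"
        )
    rng = np.random.default_rng(seed)
    groups = np.array_split(rng.permutation(uniq), k)
    return [order[np.isin(subjects, g)] for g in groups]


def _sq_dists(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    return pairwise_distances(A, B, metric="sqeuclidean")


def _scale_gamma(X_train: np.ndarray) -> float:
    var = X_train.var()
    if var <= 0:
        var = 1.0
    return 1.0 / (X_train.shape[1] * var)


def _grid_select(
    D2_tr: np.ndarray,
    y_tr: np.ndarray,
    g0: float,
    config: SVMConfig,
    seed: int,
) -> tuple[float, float]:
    """Inner-CV grid search on a training fold's precomputed distances.

    Returns (C, absolute gamma) with the best mean inner accuracy; ties go
    to the earliest grid entry (gamma-major, C-minor order).
    """
    n = len(y_tr)
    k = min(config.inner_k, min(np.bincount(np.unique(y_tr, return_inverse=True)[1])))
    k = max(k, 2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    splits = list(skf.split(np.zeros(n), y_tr))
    best = (-1.0, None, None)
    for gmult in config.gamma_grid:
        gamma = gmult * g0
        K = np.exp(-gamma * D2_tr)
        for C in config.C_grid:
            correct = 0
            for tr, va in splits:
                clf = SVC(C=C, kernel="precomputed")
                clf.fit(K[np.ix_(tr, tr)], y_tr[tr])
                correct += int((clf.predict(K[np.ix_(va, tr)]) == y_tr[va]).sum())
            acc = correct / n
            if acc > best[0]:
                best = (acc, C, gamma)
    return best[1], best[2]


class ExpressionSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM with built-in inner-CV grid search.

    fit(X, y) selects (C, gamma) by stratified inner cross-validation on
    the training data, then refits on all of it; predict(X) classifies new
    rows.  gamma candidates are multiples of 1/(d*Var(X_train)).

    Fitted attributes: ``classes_``, ``C_``, ``gamma_``, ``X_train_``.
    """

    def __init__(self, svm_config: SVMConfig | None = None, random_state: int = 0):
        self.svm_config = svm_config
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        config = self.svm_config or SVMConfig()
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        D2 = _sq_dists(X)
        g0 = _scale_gamma(X)
        self.C_, self.gamma_ = _grid_select(D2, y_enc, g0, config, self.random_state)
        self._svc = SVC(C=self.C_, kernel="precomputed")
        self._svc.fit(np.exp(-self.gamma_ * D2), y_enc)
        self.X_train_ = X
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        K = np.exp(-self.gamma_ * _sq_dists(X, self.X_train_))
        return self.classes_[self._svc.predict(K)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    lut = {name: i for i, name in enumerate(EXPRESSIONS)}
    try:
        return np.array([lut[l] for l in labels])
    except KeyError as e:
        raise ValueError(f"unknown expression label {e.args[0]!r}; "
                         f"expected one of {EXPRESSIONS}") from None


def run_cv(
    features: np.ndarray,
    manifest: pd.DataFrame,
    protocol: str = "SD",
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    svm_config: SVMConfig | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation of the SVM on a feature matrix.

    Per repeat, fresh folds are drawn (SD or SI); per outer training fold
    an inner grid search picks (C, gamma); accuracies are pooled over
    repeats x folds into one 7x7 confusion matrix (rows true, columns
    predicted, axes in EXPRESSIONS order).

    In SD mode a fold set leaving some class absent from a training fold
    is rerolled with a fresh derived seed; in SI mode it is accepted with
    a note (subject partitions cannot always be stratified).
    """
    X = np.asarray(features, dtype=float)
    if len(X) != len(manifest):
        raise ValueError("feature rows must align with manifest records")
    config = svm_config or SVMConfig()
    y = _encode_labels(manifest["label"].to_numpy())
    n_classes_present = len(np.unique(y))
    D2 = _sq_dists(X)

    confusion = np.zeros((len(EXPRESSIONS), len(EXPRESSIONS)), dtype=np.int64)
    fold_accs: list[float] = []
    notes: list[str] = []
    best_params: list[tuple] = []

    for rep in range(repeats):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        rep_seed = int(ss.generate_state(1)[0]) % 2**31
        folds = make_folds(manifest, protocol, k=k, seed=rep_seed)
        if protocol == "SD":
            attempt = 0
            while attempt < 20:
                bad = any(
                    len(np.unique(y[np.setdiff1d(np.arange(len(y)), f)])) < n_classes_present
                    for f in folds
                )
                if not bad:
                    break
                attempt += 1
                warnings.warn("class missing from a training fold; rerolling folds",
                              stacklevel=2)
                folds = make_folds(manifest, protocol, k=k, seed=rep_seed + attempt)
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            if protocol == "SI" and len(np.unique(y[train_idx])) < n_classes_present:
                notes.append(f"repeat {rep} fold {fi}: class absent from training fold")
            g0 = _scale_gamma(X[train_idx])
            C, gamma = _grid_select(
                D2[np.ix_(train_idx, train_idx)], y[train_idx], g0, config, rep_seed + fi
            )
            best_params.append((C, gamma))
            clf = SVC(C=C, kernel="precomputed")
            clf.fit(np.exp(-gamma * D2[np.ix_(train_idx, train_idx)]), y[train_idx])
            pred = clf.predict(np.exp(-gamma * D2[np.ix_(test_idx, train_idx)]))
            fold_accs.append(float(np.mean(pred == y[test_idx])))
            np.add.at(confusion, (y[test_idx], pred), 1)

    return CVResult(
        protocol=protocol, k=k, repeats=repeats,
        fold_accuracies=fold_accs, confusion=confusion,
        notes=notes, best_params=best_params,
    )
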