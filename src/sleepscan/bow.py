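"""Bag-of-words featurization and the seven classical classifiers.

Features per candidate: the 6 structured layout values (left, top, width,
height, page, parsed value) concatenated with tf-idf weights over the top
400 training-set terms (raw term-frequency ranking, lexicographic
tie-break), L2-normalized per segment. Classifiers: unpenalized logistic
regression, L1- and L2-penalized logistic regression (lambda = 0.01),
polynomial-kernel SVM, kNN (k = 3), multinomial naive Bayes (alpha = 0.5),
and a 500-tree random forest. Hyperparameters are selected by 5-fold
cross-validation at the report level, maximizing mean fold accuracy.
"""

from __future__ import annotations

import enum
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from sleepscan.segmenter import CLASS_ORDER, Candidate, Label
from sleepscan.stopwords import ENGLISH_STOPWORDS

__all__ = [
    "BowClassifier",
    "BowVocab",
    "FeatureVector",
    "TrainedBowModel",
    "CLASS_ORDER",
    "MAX_VOCAB",
    "build_vocab",
    "featurize",
    "featurize_batch",
    "train_bow",
    "cross_validate",
]

MAX_VOCAB = 400

#: Models whose distance/margin geometry needs standardized structured
#: features; tree and count-based models take them raw.
_SCALED_MODELS = frozenset({"LR", "LASSO", "RIDGE", "SVM", "KNN"})


class BowClassifier(enum.Enum):
    LR = "LR"
    LASSO = "LASSO"
    RIDGE = "RIDGE"
    SVM = "SVM"
    KNN = "KNN"
    NB = "NB"
    RF = "RF"


@dataclass(frozen=True)
class BowVocab:
    """tf-idf vocabulary: ordered terms with smoothed idf weights."""

    terms: tuple[str, ...]
    idf: np.ndarray
    stopword_list_id: str = "vendored-english-v1"

    def __post_init__(self):
        if len(self.terms) != len(self.idf):
            raise ValueError("terms and idf must align")

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


@dataclass(frozen=True)
class FeatureVector:
    """6 structured floats + L2-normalized tf-idf block."""

    structured: np.ndarray
    tfidf: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.structured, self.tfidf])


def _tokenize(window: Sequence[str]) -> list[str]:
    return [t.lower() for t in window if t.lower() not in ENGLISH_STOPWORDS]


def build_vocab(train_windows: Sequence[Sequence[str]], max_terms: int = MAX_VOCAB) -> BowVocab:
    """Build the top-``max_terms`` vocabulary from training windows only.

    Terms are lowercased non-stopwords ranked by raw corpus term
    frequency (ties broken lexicographically). idf is smoothed:
    ln((1 + n) / (1 + df)) + 1 with n = number of training segments.
    """
    if len(train_windows) == 0:
        raise ValueError("empty training corpus")
    tf: dict[str, int] = {}
    df: dict[str, int] = {}
    for window in train_windows:
        toks = _tokenize(window)
        for t in toks:
            tf[t] = tf.get(t, 0) + 1
        for t in set(toks):
            df[t] = df.get(t, 0) + 1
    ranked = sorted(tf, key=lambda t: (-tf[t], t))[:max_terms]
    n = len(train_windows)
    idf = np.array([np.log((1 + n) / (1 + df[t])) + 1.0 for t in ranked])
    return BowVocab(terms=tuple(ranked), idf=idf)


def featurize(cand: Candidate, vocab: BowVocab) -> FeatureVector:
    """Featurize one candidate against a built vocabulary."""
    vec = np.zeros(len(vocab.terms))
    index = vocab.index
    for t in _tokenize(cand.window):
        j = index.get(t)
        if j is not None:
            vec[j] += 1.0
    vec *= vocab.idf
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return FeatureVector(structured=np.array(cand.structured), tfidf=vec)


def featurize_batch(cands: Sequence[Candidate], vocab: BowVocab) -> np.ndarray:
    """Feature matrix (n, 6 + |vocab|) for a candidate sequence."""
    if not cands:
        return np.zeros((0, 6 + len(vocab.terms)))
    return np.stack([featurize(c, vocab).vector for c in cands])


def _make_estimator(clf: BowClassifier, params: Mapping, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import MultinomialNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    p = dict(params)
    if clf is BowClassifier.LR:
        return LogisticRegression(penalty=None, max_iter=2000, **p)
    if clf is BowClassifier.LASSO:
        lam = p.pop("lam", 0.01)
        return LogisticRegression(penalty="l1", C=1.0 / lam, solver="saga", max_iter=2000, **p)
    if clf is BowClassifier.RIDGE:
        lam = p.pop("lam", 0.01)
        return LogisticRegression(penalty="l2", C=1.0 / lam, max_iter=2000, **p)
    if clf is BowClassifier.SVM:
        p.setdefault("kernel", "poly")
        return SVC(probability=True, random_state=seed, **p)
    if clf is BowClassifier.KNN:
        p.setdefault("n_neighbors", 3)
        return KNeighborsClassifier(**p)
    if clf is BowClassifier.NB:
        p.setdefault("alpha", 0.5)
        return MultinomialNB(**p)
    if clf is BowClassifier.RF:
        p.setdefault("n_estimators", 500)
        p.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    raise ValueError(f"unknown classifier {clf}")


@dataclass
class TrainedBowModel:
    """A fitted bag-of-words classifier with its vocabulary and provenance."""

    clf: BowClassifier
    estimator: object
    vocab: BowVocab
    params: dict = field(default_factory=dict)
    seed: int = 0
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            return X
        X = X.copy()
        X[:, :6] = (X[:, :6] - self.scaler_mean) / self.scaler_sd
        return X

    def predict_proba(self, cands_or_X) -> np.ndarray:
        """Per-class probabilities in fixed order (AHI, SaO2, Other)."""
        if isinstance(cands_or_X, np.ndarray):
            X = cands_or_X
        else:
            X = featurize_batch(cands_or_X, self.vocab)
        proba = self.estimator.predict_proba(self._transform(X))
        cols = {c: i for i, c in enumerate(self.estimator.classes_)}
        out = np.zeros((len(X), len(CLASS_ORDER)))
        for j, lab in enumerate(CLASS_ORDER):
            if lab.value in cols:
                out[:, j] = proba[:, cols[lab.value]]
        return out

    def predict(self, cands_or_X) -> list[Label]:
        proba = self.predict_proba(cands_or_X)
        return [CLASS_ORDER[int(i)] for i in np.argmax(proba, axis=1)]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedBowModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train_bow(
    X: np.ndarray,
    labels: Sequence[Label],
    clf: BowClassifier,
    vocab: BowVocab,
    params: Mapping | None = None,
    seed: int = 0,
) -> TrainedBowModel:
    """Fit one classifier on a feature matrix (columns: 6 structured + tfidf)."""
    params = dict(params or {})
    y = np.array([lab.value for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    model = TrainedBowModel(clf=clf, estimator=_make_estimator(clf, params, seed),
                            vocab=vocab, params=params, seed=seed)
    if clf.value in _SCALED_MODELS:
        mean = X[:, :6].mean(axis=0)
        sd = X[:, :6].std(axis=0)
        sd[sd == 0] = 1.0
        model.scaler_mean, model.scaler_sd = mean, sd
    model.estimator.fit(model._transform(X), y)
    return model


def cross_validate(
    X: np.ndarray,
    labels: Sequence[Label],
    report_ids: Sequence[str],
    clf: BowClassifier,
    grid: Sequence[Mapping],
    vocab: BowVocab,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, TrainedBowModel, np.ndarray]:
    """Report-level k-fold CV over a parameter grid; refit best on full dev.

    Folds partition *reports*, never segments. The parameter set with the
    highest mean fold accuracy wins (ties -> first in grid order).
    Returns (best params, refit model, mean fold accuracy per grid point).
    """
    if len(grid) == 0:
        raise ValueError("empty parameter grid")
    ids = np.array(report_ids)
    uniq = np.unique(ids)
    if len(uniq) < k:
        raise ValueError(f"need >= {k} reports for {k}-fold CV, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    folds = np.array_split(uniq[order], k)
    y = np.array([lab.value for lab in labels])

    mean_acc = np.zeros(len(grid))
    for g, params in enumerate(grid):
        accs = []
        for fold in folds:
            mask = np.isin(ids, fold)
            model = train_bow(X[~mask], [Label(v) for v in y[~mask]], clf, vocab, params, seed)
            pred = [lab.value for lab in model.predict(X[mask])]
            accs.append(float(np.mean(np.array(pred) == y[mask])))
        mean_acc[g] = np.mean(accs)
    best_idx = int(np.argmax(mean_acc))  # argmax returns first maximum
    best = dict(grid[best_idx])
    final = train_bow(X, list(labels), clf, vocab, best, seed)
    return best, final, mean_acc
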