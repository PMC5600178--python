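"""Six classifiers behind one adapter contract.

ann / rf / svm / knn / lda are standard scikit-learn estimators wrapped in
a pipeline that z-scores features on training statistics (descriptor
scales span many orders of magnitude). The sixth, a directed-acyclic-graph
multiclass least-squares twin SVM (DAG MLSTSVM), is implemented here from
first principles: each one-vs-one node fits two non-parallel hyperplanes,
each the solution of a single linear system (no quadratic programming),
and prediction walks the DAG eliminating one class per node, so exactly
K-1 nodes are evaluated for K classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y

from .errors import InvalidInputError, LeafmorphError

KNOWN_CLASSIFIERS = ("ann", "rf", "svm", "knn", "lda", "dag_mlstsvm")


@dataclass
class ClassifierSpec:
    """Classifier name + hyperparameter overrides + seed."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in KNOWN_CLASSIFIERS:
            raise InvalidInputError(
                f"unknown classifier {self.name!r}; choose from {KNOWN_CLASSIFIERS}"
            )


@dataclass
class TwinHyperplanePair:
    """The two non-parallel hyperplanes of one binary LSTSVM node."""

    w_pos: np.ndarray
    b_pos: float
    w_neg: np.ndarray
    b_neg: float
    c1: float
    c2: float


def lstsvm_fit_binary(
    A: np.ndarray,
    B: np.ndarray,
    c1: float = 1.0,
    c2: float = 1.0,
    ridge: float = 1e-8,
) -> TwinHyperplanePair:
    """Fit a binary least-squares twin SVM.

    With augmented matrices E = [A 1], F = [B 1], the positive plane
    solves (F'F + (1/c1) E'E) z = -F'1 and the negative plane solves
    (E'E + (1/c2) F'F) z = E'1; a small ridge keeps both systems solvable.
    Each plane hugs its own class and pushes the other to distance ~1.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) == 0 or len(B) == 0:
        raise InvalidInputError("both classes must be non-empty")
    E = np.hstack([A, np.ones((len(A), 1))])
    F = np.hstack([B, np.ones((len(B), 1))])
    EtE = E.T @ E
    FtF = F.T @ F
    eye = np.eye(E.shape[1])
    try:
        z1 = np.linalg.solve(FtF + EtE / c1 + ridge * eye, -F.sum(axis=0))
        z2 = np.linalg.solve(EtE + FtF / c2 + ridge * eye, E.sum(axis=0))
    except np.linalg.LinAlgError as exc:
        raise LeafmorphError(f"singular LSTSVM system even after ridge: {exc}") from exc
    return TwinHyperplanePair(
        w_pos=z1[:-1], b_pos=float(z1[-1]), w_neg=z2[:-1], b_neg=float(z2[-1]),
        c1=c1, c2=c2,
    )


def _plane_distances(pair: TwinHyperplanePair, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Perpendicular distances of rows of X to each plane."""
    X = np.atleast_2d(X)
    npos = np.linalg.norm(pair.w_pos)
    nneg = np.linalg.norm(pair.w_neg)
    d_pos = np.abs(X @ pair.w_pos + pair.b_pos) / (npos if npos > 0 else 1.0)
    d_neg = np.abs(X @ pair.w_neg + pair.b_neg) / (nneg if nneg > 0 else 1.0)
    return d_pos, d_neg


class DagMlstsvm(BaseEstimator, ClassifierMixin):
    """Directed-acyclic-graph multiclass LSTSVM (one-vs-one).

    All K(K-1)/2 pairwise twin-SVM nodes are trained at fit time; a
    prediction starts at the (first, last) node in sorted class order and
    eliminates one candidate class per node, reaching a leaf after exactly
    K-1 evaluations.
    """

    def __init__(self, c1: float = 1.0, c2: float = 1.0, ridge: float = 1e-8):
        self.c1 = c1
        self.c2 = c2
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise InvalidInputError("need at least two classes")
        self.nodes_ = {}
        for i in range(len(self.classes_)):
            for j in range(i + 1, len(self.classes_)):
                A = X[y == self.classes_[i]]
                B = X[y == self.classes_[j]]
                try:
                    self.nodes_[(i, j)] = lstsvm_fit_binary(
                        A, B, self.c1, self.c2, self.ridge
                    )
                except LeafmorphError as exc:
                    raise LeafmorphError(
                        f"node ({self.classes_[i]}, {self.classes_[j]}): {exc}"
                    ) from exc
        return self

    @property
    def n_nodes_(self) -> int:
        return len(self.nodes_)

    def _predict_one(self, x: np.ndarray, count_evals: bool = False):
        lo, hi = 0, len(self.classes_) - 1
        evals = 0
        while lo < hi:
            pair = self.nodes_[(lo, hi)]
            d_pos, d_neg = _plane_distances(pair, x[None, :])
            evals += 1
            if d_pos[0] <= d_neg[0]:
                hi -= 1  # looks like class lo -> eliminate hi
            else:
                lo += 1
        return (self.classes_[lo], evals) if count_evals else self.classes_[lo]

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self._predict_one(x) for x in X])


def dag_fit(X: np.ndarray, y: np.ndarray, c1: float = 1.0, c2: float = 1.0) -> DagMlstsvm:
    """Train a DAG MLSTSVM on labelled data."""
    return DagMlstsvm(c1=c1, c2=c2).fit(X, y)


def dag_predict(model: DagMlstsvm, x: np.ndarray):
    """Predict the class of a single sample (or an array of samples)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return model.predict(x[None, :])[0]
    return model.predict(x)


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.name == "ann":
        # patience sized for the small validation carve-outs typical of
        # 30-samples-per-class datasets; default 10 stops on noise
        return MLPClassifier(
            hidden_layer_sizes=(hp.pop("hidden", 100),),
            max_iter=hp.pop("max_epochs", 500),
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=hp.pop("patience", 50),
            random_state=spec.seed,
            **hp,
        )
    if spec.name == "rf":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=spec.seed, **hp
        )
    if spec.name == "svm":
        # one-vs-all RBF SVM; gamma='auto' is 1/n_features
        return OneVsRestClassifier(
            SVC(
                kernel=hp.pop("kernel", "rbf"),
                C=hp.pop("C", 10.0),
                gamma=hp.pop("gamma", "auto"),
                random_state=spec.seed,
                **hp,
            )
        )
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("k", 1), **hp)
    if spec.name == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if spec.name == "dag_mlstsvm":
        return DagMlstsvm(c1=hp.pop("c1", 1.0), c2=hp.pop("c2", 1.0), **hp)
    raise InvalidInputError(f"unknown classifier {spec.name!r}")


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> Pipeline:
    """Fit the named classifier behind a train-statistics z-scoring step."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise InvalidInputError("feature matrix contains NaN")
    model = Pipeline(
        [("scale", StandardScaler()), ("clf", _build_estimator(spec))]
    )
    model.fit(X, np.asarray(y))
    return model


def predict(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Predict labels with a model from :func:`train_classifier`."""
    return model.predict(np.asarray(X, dtype=float))
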