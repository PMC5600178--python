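"""Evaluation protocol: stratified random 80:20 splits, 10 repeats.

Feature selection (when requested) and z-scoring statistics are fitted on
the training split only, each repeat, so no test information leaks into
the model. The report carries the per-repeat accuracies and their mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .features import FeatureMatrix
from .featsel import select_features
from .classify import ClassifierSpec, train_classifier, predict


@dataclass
class EvalReport:
    """Per-repeat accuracies for one descriptor-set x classifier run."""

    combo: tuple
    classifier: str
    selection: dict | None
    accuracies: list[float]
    seeds: list[int]
    selection_refit_per_repeat: bool = True

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_accuracy"] = self.mean_accuracy
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def random_split(
    labels: np.ndarray,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; round(train_fraction * n_c) per class.

    Returns disjoint, exhaustive (train, test) index arrays.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 5:
        raise InvalidInputError("need at least 5 samples to split")
    if not 0 < train_fraction < 1:
        raise InvalidInputError("train_fraction must be in (0, 1) exclusive")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise InvalidInputError(f"class {c!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = round(train_fraction * len(idx))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def evaluate(
    features: FeatureMatrix,
    classifier: ClassifierSpec,
    selection: dict | None = None,
    repeats: int = 10,
    base_seed: int = 0,
    train_fraction: float = 0.8,
    combo: tuple = (),
) -> EvalReport:
    """Run the repeated random-split protocol.

    ``selection`` is e.g. {"method": "relief", "keep_fraction": 0.4}; when
    given, scores are computed on the training split of each repeat and the
    retained columns applied to both splits.
    """
    accuracies = []
    seeds = []
    for r in range(repeats):
        seed = base_seed + r
        seeds.append(seed)
        try:
            tr, te = random_split(features.labels, train_fraction, seed=seed)
            Xtr, Xte = features.values[tr], features.values[te]
            ytr, yte = features.labels[tr], features.labels[te]
            if selection:
                result = select_features(
                    Xtr,
                    ytr,
                    method=selection["method"],
                    keep_fraction=selection["keep_fraction"],
                    k_neighbors=selection.get("k_neighbors", 10),
                    seed=seed,
                    feature_names=features.feature_names,
                )
                Xtr = Xtr[:, result.retained]
                Xte = Xte[:, result.retained]
            spec = ClassifierSpec(
                classifier.name, dict(classifier.hyperparameters), seed=seed
            )
            model = train_classifier(spec, Xtr, ytr)
            accuracies.append(float(np.mean(predict(model, Xte) == yte)))
        except Exception as exc:
            raise type(exc)(f"repeat {r}: {exc}") from exc
    return EvalReport(
        combo=tuple(combo),
        classifier=classifier.name,
        selection=selection,
        accuracies=accuracies,
        seeds=seeds,
    )
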