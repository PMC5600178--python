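"""Filter feature selection: ReliefF, CFS and Pearson correlation.

All three methods produce a per-feature ranking that is cut at a retention
fraction (e.g. keep 40% of 133 descriptors -> 53). ReliefF weights contrast
near-hit against near-miss feature differences over all instances; CFS
performs a greedy forward search maximizing the merit
M_S = k * mean(r_cf) / sqrt(k + k*(k-1) * mean(r_ff)) and its inclusion
order is used as the ranking; the PCC score of a feature is the largest
absolute Pearson correlation with any one-vs-rest class indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass
class SelectionResult:
    """Outcome of scoring + cutting at a retention fraction.

    scores: per-feature weight (relief/pcc) or negated inclusion rank (cfs,
    so that higher is always better). retained: indices in rank order.
    """

    method: str
    scores: np.ndarray
    retained: np.ndarray
    keep_fraction: float
    feature_names: list[str] | None = None

    @property
    def retained_names(self) -> list[str] | None:
        if self.feature_names is None:
            return None
        return [self.feature_names[i] for i in self.retained]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "keep_fraction": self.keep_fraction,
            "scores": self.scores.tolist(),
            "retained": self.retained.tolist(),
            "retained_names": self.retained_names,
        }


def _minmax_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    return (X - lo) / safe, rng


def relief_scores(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Multiclass ReliefF feature weights.

    Features are min-max scaled internally so weights live in [-1, 1]. For
    every instance the k nearest same-class hits (excluding itself) and,
    for each other class, the k nearest misses are found with Manhattan
    distance; hit differences are subtracted and miss differences added
    with prior weights P(c)/(1 - P(class_i)). All instances are used, so
    the result is deterministic (neighbour ties broken by sample index);
    ``seed`` is accepted for interface symmetry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InvalidInputError("ReliefF needs at least two classes")
    n, d = X.shape
    Xs, _ = _minmax_scale(X)
    priors = counts / n
    prior_of = dict(zip(classes.tolist(), priors.tolist()))
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    short = [c for c in classes if len(idx_by_class[c]) < k_neighbors + 1]
    if short:
        warnings.warn(
            f"classes {short} have fewer than k+1={k_neighbors + 1} members; "
            "k reduced for those classes",
            stacklevel=2,
        )
    W = np.zeros(d)
    for i in range(n):
        diffs = np.abs(Xs - Xs[i])  # (n, d)
        dist = diffs.sum(axis=1)
        # hits
        hits = idx_by_class[y[i]]
        hits = hits[hits != i]
        if len(hits) > 0:
            kh = min(k_neighbors, len(hits))
            order = hits[np.argsort(dist[hits], kind="stable")][:kh]
            W -= diffs[order].mean(axis=0) / n
        # misses per other class
        denom = 1.0 - prior_of[y[i].item() if hasattr(y[i], "item") else y[i]]
        for c in classes:
            if c == y[i]:
                continue
            miss = idx_by_class[c]
            km = min(k_neighbors, len(miss))
            order = miss[np.argsort(dist[miss], kind="stable")][:km]
            W += (prior_of[c.item() if hasattr(c, "item") else c] / denom) * diffs[
                order
            ].mean(axis=0) / n
    return W


def _class_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature max over one-vs-rest class indicators of |Pearson r|.

    Zero-variance features (or indicators) score 0.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    classes = np.unique(y)
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    best = np.zeros(d)
    for c in classes:
        ind = (y == c).astype(float)
        ic = ind - ind.mean()
        si = np.sqrt((ic**2).sum())
        if si == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(Xc.T @ ic) / (sx * si)
        r[sx == 0] = 0.0
        best = np.maximum(best, r)
    return best


def pcc_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson-correlation relevance score per feature (one-vs-rest max)."""
    if len(np.unique(y)) < 2:
        raise InvalidInputError("PCC scoring needs at least two classes")
    return _class_correlations(X, y)


def _abs_corr_matrix(X: np.ndarray) -> np.ndarray:
    """|Pearson r| between features; zero-variance features correlate 0."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.abs(np.nan_to_num(C, nan=0.0))
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def cfs_merit(r_cf_sum: float, r_ff_sum: float, k: int) -> float:
    """CFS merit of a k-feature subset given summed correlations."""
    if k == 0:
        return 0.0
    mean_cf = r_cf_sum / k
    mean_ff = r_ff_sum / (k * (k - 1) / 2) if k > 1 else 0.0
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_rank(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Greedy-forward CFS inclusion order over all features.

    At each step the feature whose addition maximizes the merit is
    appended (ties by feature index); the search continues past the merit
    peak so every feature receives a rank and any retention fraction can
    be honoured. Returns feature indices in inclusion order.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if d < 2:
        return np.arange(d)
    r_cf = _class_correlations(X, y)
    r_ff = _abs_corr_matrix(X)
    selected: list[int] = []
    remaining = list(range(d))
    cf_sum = 0.0
    ff_sum = 0.0
    ff_with_sel = np.zeros(d)  # sum of |r| between each feature and selected set
    while remaining:
        merits = np.array(
            [
                cfs_merit(cf_sum + r_cf[j], ff_sum + ff_with_sel[j], len(selected) + 1)
                for j in remaining
            ]
        )
        best = remaining[int(np.argmax(merits))]  # argmax takes first -> index tie-break
        selected.append(best)
        remaining.remove(best)
        cf_sum += r_cf[best]
        ff_sum += ff_with_sel[best]
        ff_with_sel += r_ff[:, best]
    return np.array(selected)


def select_fraction(
    scores: np.ndarray,
    keep_fraction: float,
    method: str = "scores",
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Cut a score vector at a retention fraction.

    Keeps round(keep_fraction * n_features) features (round-half-to-even,
    so 133 * 0.4 = 53.2 -> 53), ranked by descending score with ties broken
    by feature index.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if not 0 < keep_fraction <= 1:
        raise InvalidInputError("keep_fraction must be in (0, 1]")
    n_keep = round(keep_fraction * n)
    if n_keep == 0:
        raise InvalidInputError(
            f"keep_fraction={keep_fraction} retains zero of {n} features"
        )
    order = np.argsort(-scores, kind="stable")
    return SelectionResult(
        method=method,
        scores=scores,
        retained=order[:n_keep],
        keep_fraction=keep_fraction,
        feature_names=feature_names,
    )


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    keep_fraction: float,
    k_neighbors: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Score with the named method and retain the top fraction."""
    if method == "relief":
        scores = relief_scores(X, y, k_neighbors=k_neighbors, seed=seed)
    elif method == "pcc":
        scores = pcc_scores(X, y)
    elif method == "cfs":
        ranking = cfs_rank(X, y)
        scores = np.empty(len(ranking))
        scores[ranking] = -np.arange(len(ranking), dtype=float)
    else:
        raise InvalidInputError(f"unknown selection method {method!r}")
    return select_fraction(scores, keep_fraction, method=method, feature_names=feature_names)
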