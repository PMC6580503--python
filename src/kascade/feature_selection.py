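"""Two-step feature selection: mRMR ranking, then incremental selection by MCC.

Step 1 ranks all features with greedy minimum-redundancy / maximum-relevance
(mRMR, MID difference criterion) on mutual information between discretised
features and the class label, and truncates the ranking to the top ``k``
(default 300).  A Fisher-score ranker is provided as an alternative.

Step 2 (IFS) walks prefixes of the ranked list, trains a classifier on each
prefix and evaluates its Matthews correlation coefficient on a validation
split; the smallest prefix achieving the maximum MCC is the selected subset.

Continuous features are discretised into 3 bins at mean +/- SD (codes
-1/0/+1), the reference mRMR implementation's default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cascade_svm import default_scorer_factory
from .evaluation import evaluate
from .feature_encoding import FeatureMatrix

logger = logging.getLogger(__name__)


def discretize(column: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Discretise a column into integer codes; default 3 bins at mean +/- SD.

    Values below mean - SD code -1, above mean + SD code +1, else 0.  A
    constant column collapses to a single code.  Only ``n_bins=3`` (the
    reference scheme) is currently supported.
    """
    if n_bins != 3:
        raise NotImplementedError("only the 3-bin mean +/- SD scheme is implemented")
    col = np.asarray(column, dtype=float)
    if not np.all(np.isfinite(col)):
        raise ValueError("discretize requires finite values")
    mean, sd = col.mean(), col.std(ddof=0)
    if sd == 0.0:
        return np.zeros(col.shape, dtype=np.int8)
    codes = np.zeros(col.shape, dtype=np.int8)
    # inclusive edges so a two-valued column maps to {-1, +1}, not a constant
    codes[col <= mean - sd] = -1
    codes[col >= mean + sd] = 1
    return codes


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) between two discrete code vectors.

    Computed from the joint contingency table via bincount; used both for
    relevance I(f; y) and redundancy I(f; g) in the mRMR score.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("code vectors must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb).astype(float)
    n = joint.sum()
    pij = joint / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    mask = pij > 0
    return float(np.sum(pij[mask] * np.log(pij[mask] / (pi @ pj)[mask])))


@dataclass(frozen=True)
class RankedFeatures:
    """Features in selection order with the score each had when picked."""

    names: list[str]
    scores: list[float]
    indices: list[int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranked feature names must be unique")
        if not (len(self.names) == len(self.scores) == len(self.indices)):
            raise ValueError("names/scores/indices length mismatch")

    def __len__(self) -> int:
        return len(self.names)


def _as_arrays(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None,
    names: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(features, FeatureMatrix):
        X = features.X
        y = features.labels if labels is None else np.asarray(labels, dtype=int)
        cols = list(features.columns)
    else:
        X = np.asarray(features, dtype=float)
        y = None if labels is None else np.asarray(labels, dtype=int)
        cols = list(names) if names is not None else [f"f{i}" for i in range(X.shape[1])]
    if y is None:
        raise ValueError("labels are required")
    if len(cols) != X.shape[1]:
        raise ValueError("feature name count != matrix width")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 samples per class")
    return X, y, cols


def mrmr_rank(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 300,
    names: Sequence[str] | None = None,
) -> RankedFeatures:
    """Greedy mRMR (MID) ranking of features against a binary label.

    The first feature maximises I(f; y); each subsequent pick maximises
    I(f; y) - (1/|S|) * sum_{g in S} I(f; g) over the not-yet-selected
    features.  Ties break to the lowest column index.  ``k`` larger than the
    feature count is clamped with a warning.
    """
    X, y, cols = _as_arrays(features, labels, names)
    n_feat = X.shape[1]
    if k > n_feat:
        logger.warning("k=%d exceeds feature count %d; clamped", k, n_feat)
        k = n_feat
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = [discretize(X[:, j]) for j in range(n_feat)]
    relevance = np.array([mutual_information(c, y) for c in codes])

    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)
    for step in range(k):
        if step == 0:
            crit = relevance.copy()
        else:
            crit = relevance - red_sum / len(selected)
        crit[~remaining] = -np.inf
        j = int(np.argmax(crit))  # first max -> lowest index on ties
        selected.append(j)
        scores.append(float(crit[j]))
        remaining[j] = False
        if step < k - 1:
            cj = codes[j]
            for g in np.nonzero(remaining)[0]:
                red_sum[g] += mutual_information(codes[g], cj)
    return RankedFeatures(
        names=[cols[j] for j in selected], scores=scores, indices=selected
    )


def fisher_rank(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 300,
    names: Sequence[str] | None = None,
) -> RankedFeatures:
    """Alternative ranker: two-class Fisher score (m1-m0)^2 / (v1+v0)."""
    X, y, cols = _as_arrays(features, labels, names)
    k = min(k, X.shape[1])
    X1, X0 = X[y == 1], X[y == 0]
    num = (X1.mean(axis=0) - X0.mean(axis=0)) ** 2
    den = X1.var(axis=0, ddof=0) + X0.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(den > 0, num / den, 0.0)
    order = np.argsort(-score, kind="stable")[:k]
    return RankedFeatures(
        names=[cols[j] for j in order],
        scores=[float(score[j]) for j in order],
        indices=[int(j) for j in order],
    )


RANKERS: dict[str, Callable] = {"mrmr": mrmr_rank, "fisher": fisher_rank}


def balanced_svm_trainer(
    svm_params: dict | None = None, seed: int = 0
) -> Callable[[np.ndarray, np.ndarray], object]:
    """A trainer callable fitting an RBF SVM on a class-balanced undersample.

    The majority class is undersampled (seeded, without replacement) to the
    minority size before fitting; the scorer is the package default
    (standardised RBF, C=1, dimension-scaled gamma).
    """
    factory = default_scorer_factory(svm_params)

    def _train(X: np.ndarray, y: np.ndarray) -> object:
        rng = np.random.default_rng(seed)
        pos = np.nonzero(y == 1)[0]
        neg = np.nonzero(y == 0)[0]
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("training data must contain both classes")
        if len(neg) > len(pos):
            neg = rng.choice(neg, size=len(pos), replace=False)
        elif len(pos) > len(neg):
            pos = rng.choice(pos, size=len(neg), replace=False)
        idx = np.sort(np.concatenate([pos, neg]))
        clf = factory()
        clf.fit(X[idx], y[idx])
        return clf

    return _train


@dataclass
class IFSCurve:
    """The incremental-feature-selection MCC curve and the chosen subset."""

    sizes: list[int]
    mcc_values: list[float]
    best_size: int
    selected_names: list[str] = field(default_factory=list)
    selected_indices: list[int] = field(default_factory=list)

    @property
    def best_mcc(self) -> float:
        return self.mcc_values[self.sizes.index(self.best_size)]


def ifs_select(
    ranked: RankedFeatures,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    trainer: Callable[[np.ndarray, np.ndarray], object] | None = None,
    max_size: int | None = None,
) -> IFSCurve:
    """Incremental feature selection over prefixes of an mRMR ranking.

    For each prefix size s the trainer is fitted on the first s ranked
    features and scored by validation MCC; the smallest s attaining the
    maximum MCC wins.  ``X_train``/``X_val`` are indexed by the ranking's
    original column indices.
    """
    if len(ranked) == 0:
        raise ValueError("ranked feature list is empty")
    y_val = np.asarray(y_val, dtype=int)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation set must contain both classes")
    trainer = trainer or balanced_svm_trainer()
    limit = len(ranked) if max_size is None else min(max_size, len(ranked))
    sizes, mccs = [], []
    for s in range(1, limit + 1):
        idx = ranked.indices[:s]
        model = trainer(X_train[:, idx], np.asarray(y_train, dtype=int))
        y_hat = model.predict(X_val[:, idx])
        mccs.append(evaluate(y_val, y_hat).mcc)
        sizes.append(s)
    best_i = int(np.argmax(mccs))  # first max -> smallest prefix on ties
    best_size = sizes[best_i]
    return IFSCurve(
        sizes=sizes,
        mcc_values=mccs,
        best_size=best_size,
        selected_names=ranked.names[:best_size],
        selected_indices=ranked.indices[:best_size],
    )
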