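"""Cascade of balanced SVM layers for heavily imbalanced site prediction.

With roughly ten negative (non-acetylated) lysines per positive, a single SVM
trained on everything collapses to the majority class, and a single SVM on a
balanced undersample discards most of the negative information.  The cascade
resolves both problems by consuming the negative pool iteratively:

1. Draw a random balanced negative subset ND (|ND| = |PD| = M) from the total
   negative pool TND and fit an RBF SVM S_i on PD against ND.
2. Score PD and TND with S_i.
3. Sort the positive decision values descending; the value at 1-based rank
   ceil(q * M) (q = 0.95) is the layer threshold T_i, so at least ceil(q * M)
   positives stay above it — at most a fraction 1 - q of positives is
   sacrificed per layer.
4. Remove from TND every negative scoring below T_i; (S_i, T_i) becomes
   layer i.
5. The next ND is the M surviving negatives with the LOWEST decision values —
   the negatives most confusable with positives once the easy ones are gone.
6. Repeat until a round removes fewer than ``stop_frac`` (default 0.05) of
   the original |TND|; the layer that triggers the stop is retained.

Prediction is a conjunction with short-circuiting: a sample is positive only
if its decision value clears every layer's threshold, and is rejected at the
first layer it fails.

The scorer is an injected interface: anything with ``fit(X, y)`` and a
``decision_function(X)`` whose larger values mean "more positive" works; the
default is scikit-learn's ``SVC(kernel='rbf', C=1, gamma='auto')`` (gamma =
1/n_features).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

ScorerFactory = Callable[[], object]

#: Default kernel width as a multiple of 1/n_features (on standardised inputs).
DEFAULT_GAMMA_FACTOR = 0.03


class RBFScorer:
    """Standardising RBF-SVM scorer with a dimension-scaled kernel width.

    Features are standardised before the kernel: the descriptor blocks live
    on wildly different scales (ASA in squared angstroms, integer PSSM
    log-odds, unit-variance properties), and an RBF kernel on the raw mix is
    dominated by the widest block.  Unless ``gamma`` is given explicitly, the
    kernel width is ``gamma_factor / n_features``; the smooth default keeps
    decision values of training points comparable to those of unseen points,
    which the layer-threshold rule relies on.
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: float | str | None = None,
        gamma_factor: float = DEFAULT_GAMMA_FACTOR,
    ) -> None:
        self.C = C
        self.gamma = gamma
        self.gamma_factor = gamma_factor

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RBFScorer":
        X = np.asarray(X, dtype=float)
        gamma = self.gamma if self.gamma is not None else self.gamma_factor / X.shape[1]
        self.pipe_ = make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=self.C, gamma=gamma)
        )
        self.pipe_.fit(X, y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.pipe_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipe_.predict(np.asarray(X, dtype=float))


def default_scorer_factory(svm_params: dict | None = None) -> ScorerFactory:
    """Factory for the default scorer; ``svm_params`` may override C, gamma
    or gamma_factor (see :class:`RBFScorer`)."""
    params: dict = {}
    params.update(svm_params or {})
    return lambda: RBFScorer(**params)


@dataclass
class CascadeLayer:
    """One (scorer, threshold) stage of the cascade."""

    scorer: object
    threshold: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.scorer.decision_function(X), dtype=float)


@dataclass
class LayerLog:
    """Per-layer training accounting (negative-pool sizes and threshold)."""

    layer: int
    tnd_before: int
    tnd_after: int
    removed: int
    threshold: float


@dataclass
class CascadeModel:
    """An ordered cascade {(S_1, T_1), ..., (S_n, T_n)} plus training metadata."""

    layers: list[CascadeLayer]
    q: float
    stop_frac: float
    seed: int
    feature_names: list[str] | None = None
    log: list[LayerLog] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.feature_names is not None and X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature mismatch: model expects {len(self.feature_names)} columns, "
                f"got {X.shape[1]}"
            )
        return X

    def predict_trace(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels plus the layer at which each sample exited.

        ``exit_layer[i]`` is the 1-based layer whose threshold sample i failed,
        or 0 if it passed all layers (predicted positive).  Samples rejected at
        layer i are never scored by later layers.
        """
        X = self._check(X)
        n = X.shape[0]
        exit_layer = np.zeros(n, dtype=int)
        active = np.ones(n, dtype=bool)
        for i, layer in enumerate(self.layers, start=1):
            if not active.any():
                break
            scores = layer.decision(X[active])
            failed = scores < layer.threshold
            idx = np.nonzero(active)[0]
            exit_layer[idx[failed]] = i
            active[idx[failed]] = False
        labels = active.astype(int)
        return labels, exit_layer

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 iff the sample clears every layer's threshold, else 0."""
        return self.predict_trace(X)[0]

    def save(self, path: str | Path) -> None:
        """Serialise the full model (layers, thresholds, config, log) to one archive."""
        joblib.dump(
            {
                "format": "kascade-cascade-v1",
                "layers": [(l.scorer, l.threshold) for l in self.layers],
                "q": self.q,
                "stop_frac": self.stop_frac,
                "seed": self.seed,
                "feature_names": self.feature_names,
                "log": [vars(e) for e in self.log],
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CascadeModel":
        blob = joblib.load(path)
        if blob.get("format") != "kascade-cascade-v1":
            raise ValueError(f"{path}: not a cascade model archive")
        return cls(
            layers=[CascadeLayer(s, t) for s, t in blob["layers"]],
            q=blob["q"],
            stop_frac=blob["stop_frac"],
            seed=blob["seed"],
            feature_names=blob["feature_names"],
            log=[LayerLog(**e) for e in blob["log"]],
        )


def train_balanced_layer(
    PD: np.ndarray,
    ND: np.ndarray,
    scorer_factory: ScorerFactory | None = None,
) -> object:
    """Fit one balanced scorer on PD (label 1) against ND (label 0)."""
    PD = np.asarray(PD, dtype=float)
    ND = np.asarray(ND, dtype=float)
    if len(ND) != len(PD):
        raise ValueError(f"balanced layer requires |ND| == |PD| ({len(ND)} != {len(PD)})")
    if len(PD) < 1:
        raise ValueError("empty training data")
    factory = scorer_factory or default_scorer_factory()
    X = np.vstack([PD, ND])
    y = np.concatenate([np.ones(len(PD), dtype=int), np.zeros(len(ND), dtype=int)])
    scorer = factory()
    scorer.fit(X, y)
    return scorer


def layer_threshold(pd_scores: Sequence[float], q: float = 0.95) -> float:
    """Threshold = the decision value at 1-based rank ceil(q*M), scores sorted
    descending, so at least ceil(q*M) positives satisfy score >= T."""
    scores = np.asarray(pd_scores, dtype=float)
    M = scores.shape[0]
    if M == 0:
        raise ValueError("cannot take a threshold of empty positive scores")
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    rank = math.ceil(q * M)  # 1-based
    return float(np.sort(scores)[::-1][rank - 1])


def train_cascade(
    PD: np.ndarray,
    TND: np.ndarray,
    q: float = 0.95,
    stop_frac: float = 0.05,
    svm_params: dict | None = None,
    seed: int = 0,
    scorer_factory: ScorerFactory | None = None,
    feature_names: Sequence[str] | None = None,
    max_layers: int = 200,
) -> CascadeModel:
    """Train the full cascade on positive rows PD and the negative pool TND.

    Layer 1's ND is a seeded uniform draw from TND; every later ND is the M
    hardest (lowest-scoring) surviving negatives, tie-broken by stable sample
    index.  Training stops when a round removes fewer than
    ``stop_frac * |TND_original|`` negatives (that round's layer is kept), or
    when the surviving pool can no longer fill a balanced ND (with a warning).
    """
    PD = np.asarray(PD, dtype=float)
    TND = np.asarray(TND, dtype=float)
    M = PD.shape[0]
    n0 = TND.shape[0]
    if M < 2:
        raise ValueError("need at least 2 positive samples")
    if n0 < M:
        raise ValueError(f"negative pool ({n0}) smaller than positive set ({M})")
    if not 0 < stop_frac < 1:
        raise ValueError(f"stop_frac must be in (0, 1), got {stop_frac}")
    factory = scorer_factory or default_scorer_factory(svm_params)
    rng = np.random.default_rng(seed)
    stop_count = stop_frac * n0

    surviving = np.arange(n0)  # indices into TND, ascending (stable identity)
    nd_local = rng.choice(n0, size=M, replace=False)
    ND = TND[np.sort(nd_local)]

    layers: list[CascadeLayer] = []
    log: list[LayerLog] = []
    for i in range(1, max_layers + 1):
        scorer = train_balanced_layer(PD, ND, factory)
        pd_scores = np.asarray(scorer.decision_function(PD), dtype=float)
        tnd_scores = np.asarray(scorer.decision_function(TND[surviving]), dtype=float)
        T = layer_threshold(pd_scores, q)
        keep = tnd_scores >= T
        removed = int((~keep).sum())
        layers.append(CascadeLayer(scorer, T))
        log.append(
            LayerLog(
                layer=i,
                tnd_before=len(surviving),
                tnd_after=len(surviving) - removed,
                removed=removed,
                threshold=T,
            )
        )
        surviving = surviving[keep]
        tnd_scores = tnd_scores[keep]
        if removed < stop_count:
            logger.info(
                "cascade stopped at layer %d: removed %d < %.1f (%.0f%% of %d)",
                i, removed, stop_count, stop_frac * 100, n0,
            )
            break
        if len(surviving) < M:
            logger.warning(
                "cascade terminated at layer %d: surviving negatives (%d) "
                "cannot fill a balanced subset of size %d",
                i, len(surviving), M,
            )
            break
        # hardest negatives: lowest surviving scores, stable index tie-break
        order = np.argsort(tnd_scores, kind="stable")[:M]
        ND = TND[surviving[np.sort(order)]]
    else:
        logger.warning("cascade hit max_layers=%d before the stopping rule", max_layers)

    return CascadeModel(
        layers=layers,
        q=q,
        stop_frac=stop_frac,
        seed=seed,
        feature_names=list(feature_names) if feature_names is not None else None,
        log=log,
    )


@dataclass
class SingleModel:
    """A serialisable wrapper for the single-SVM baselines."""

    scorer: object
    kind: str  # 'single-all' or 'single-balanced'
    feature_names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.scorer.predict(np.asarray(X, dtype=float)), dtype=int)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format": "kascade-single-v1",
                "kind": self.kind,
                "scorer": self.scorer,
                "feature_names": self.feature_names,
            },
            path,
        )


def load_model(path: str | Path) -> "CascadeModel | SingleModel":
    """Load either a cascade archive or a single-SVM baseline archive."""
    blob = joblib.load(path)
    fmt = blob.get("format") if isinstance(blob, dict) else None
    if fmt == "kascade-cascade-v1":
        return CascadeModel.load(path)
    if fmt == "kascade-single-v1":
        return SingleModel(
            scorer=blob["scorer"], kind=blob["kind"], feature_names=blob["feature_names"]
        )
    raise ValueError(f"{path}: unrecognised model archive format {fmt!r}")


def train_single_all(
    PD: np.ndarray, TND: np.ndarray, svm_params: dict | None = None
) -> object:
    """Baseline: one SVM on the full imbalanced pool (PD positive, TND negative)."""
    PD = np.asarray(PD, dtype=float)
    TND = np.asarray(TND, dtype=float)
    scorer = default_scorer_factory(svm_params)()
    X = np.vstack([PD, TND])
    y = np.concatenate([np.ones(len(PD), dtype=int), np.zeros(len(TND), dtype=int)])
    scorer.fit(X, y)
    return scorer


def train_single_balanced(
    PD: np.ndarray,
    TND: np.ndarray,
    svm_params: dict | None = None,
    seed: int = 0,
) -> object:
    """Baseline: one SVM on PD plus a single seeded uniform negative subset."""
    PD = np.asarray(PD, dtype=float)
    TND = np.asarray(TND, dtype=float)
    if len(TND) < len(PD):
        raise ValueError("negative pool smaller than positive set")
    rng = np.random.default_rng(seed)
    nd = TND[np.sort(rng.choice(len(TND), size=len(PD), replace=False))]
    return train_balanced_layer(PD, nd, default_scorer_factory(svm_params))
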