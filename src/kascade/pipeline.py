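"""End-to-end orchestration helpers shared by the CLI, tests and scripts.

These functions wire the stage modules together: encode a bundle into a
feature matrix, run the two-step feature selection, and benchmark the cascade
against the two single-SVM baselines on a held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import cascade_svm, feature_selection
from .evaluation import MetricsReport, evaluate
from .feature_encoding import (
    DEFAULT_ENCODERS,
    FeatureMatrix,
    NormalizedProperty,
    assemble,
    default_property_tables,
    normalize_property,
)
from .synthetic_data import Bundle


def default_normalized_properties() -> list[NormalizedProperty]:
    """The packaged synthetic property tables, standardised."""
    return [normalize_property(t) for t in default_property_tables()]


def encode_bundle(
    bundle: Bundle,
    properties: Sequence[NormalizedProperty] | None = None,
    encoders: Sequence[str] = DEFAULT_ENCODERS,
    flank: int | None = None,
    **assemble_kwargs,
) -> FeatureMatrix:
    """Extract windows from a bundle and assemble the full feature matrix."""
    props = list(properties) if properties is not None else default_normalized_properties()
    return assemble(
        bundle.windows(flank=flank),
        properties=props,
        pssms=bundle.pssms,
        structures=bundle.structures,
        encoders=encoders,
        **assemble_kwargs,
    )


def split_pos_neg(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """PD (positive rows) and TND (negative rows) of a labelled matrix."""
    if fm.labels is None:
        raise ValueError("feature matrix has no labels")
    return fm.X[fm.labels == 1], fm.X[fm.labels == 0]


@dataclass
class BenchmarkResult:
    """Held-out metrics of the cascade and the two single-SVM baselines."""

    cascade: MetricsReport
    single_balanced: MetricsReport
    single_all: MetricsReport
    model: cascade_svm.CascadeModel

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            "cascade": self.cascade.as_dict(percent=True),
            "single_balanced": self.single_balanced.as_dict(percent=True),
            "single_all": self.single_all.as_dict(percent=True),
        }


def benchmark_models(
    train_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    q: float = 0.95,
    stop_frac: float = 0.05,
    svm_params: dict | None = None,
    seed: int = 0,
) -> BenchmarkResult:
    """Train cascade + baselines on ``train_fm`` and evaluate on ``test_fm``."""
    if train_fm.columns != test_fm.columns:
        raise ValueError("train and test matrices have different columns")
    PD, TND = split_pos_neg(train_fm)
    model = cascade_svm.train_cascade(
        PD, TND, q=q, stop_frac=stop_frac, svm_params=svm_params,
        seed=seed, feature_names=train_fm.columns,
    )
    y_true = test_fm.labels
    rep_cascade = evaluate(y_true, model.predict(test_fm.X))

    bal = cascade_svm.train_single_balanced(PD, TND, svm_params=svm_params, seed=seed)
    rep_bal = evaluate(y_true, np.asarray(bal.predict(test_fm.X), dtype=int))

    allm = cascade_svm.train_single_all(PD, TND, svm_params=svm_params)
    rep_all = evaluate(y_true, np.asarray(allm.predict(test_fm.X), dtype=int))
    return BenchmarkResult(
        cascade=rep_cascade, single_balanced=rep_bal, single_all=rep_all, model=model
    )


@dataclass
class SelectionResult:
    ranked: feature_selection.RankedFeatures
    curve: feature_selection.IFSCurve


def select_features(
    train_fm: FeatureMatrix,
    val_fm: FeatureMatrix,
    k: int = 300,
    ranker: str = "mrmr",
    seed: int = 0,
    svm_params: dict | None = None,
) -> SelectionResult:
    """mRMR (or Fisher) ranking on the training matrix, then IFS by
    validation MCC with a balanced-SVM trainer."""
    rank_fn = feature_selection.RANKERS[ranker]
    ranked = rank_fn(train_fm, k=k)
    trainer = feature_selection.balanced_svm_trainer(svm_params=svm_params, seed=seed)
    curve = feature_selection.ifs_select(
        ranked, train_fm.X, train_fm.labels, val_fm.X, val_fm.labels, trainer=trainer
    )
    return SelectionResult(ranked=ranked, curve=curve)
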