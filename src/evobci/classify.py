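"""LDA classification and the outer evaluation harness.

Two-class linear discriminant analysis with pooled covariance is the
classifier throughout: the feature spaces produced here (spatially
projected band amplitudes) are small, LDA is cheap enough to sit inside an
evolutionary fitness loop, and shrinkage toward a scaled identity keeps the
pooled covariance well-conditioned when trials are few.

The harness runs repeated stratified k-fold cross-validation over full
pipelines (any object with ``fit(EpochSet)``/``predict(EpochSet)``),
guaranteeing that all feature optimization happens inside each training
split.  ``pairwise_wincount`` aggregates paired accuracy lists into the
how-often-does-A-beat-B count matrix used to compare configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .preprocess import DataError, EpochSet

__all__ = ["LDAModel", "CVResult", "lda_fit", "cross_validate",
           "pairwise_wincount", "Pipeline"]


class Pipeline(Protocol):
    def fit(self, train: EpochSet) -> "Pipeline": ...
    def predict(self, test: EpochSet) -> np.ndarray: ...


@dataclass
class LDAModel:
    """Fitted two-class LDA with shrunk pooled covariance."""

    estimator: LinearDiscriminantAnalysis

    @property
    def class_means(self) -> np.ndarray:
        return self.estimator.means_

    @property
    def priors(self) -> np.ndarray:
        return self.estimator.priors_

    @property
    def coef(self) -> np.ndarray:
        return self.estimator.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.atleast_2d(X))

    def error_rate(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) != y))


def lda_fit(features: np.ndarray, labels: np.ndarray, shrinkage="auto") -> LDAModel:
    """Fit two-class LDA; shrinkage='auto' uses Ledoit-Wolf conditioning.

    Requires two classes with at least two samples each.  Degenerate
    (zero-variance) features are absorbed by the shrinkage target rather
    than raising, so this is safe inside an optimization loop.
    """
    features = np.atleast_2d(np.asarray(features, float))
    labels = np.asarray(labels)
    cls, counts = np.unique(labels, return_counts=True)
    if len(cls) != 2:
        raise ValueError(f"lda_fit requires exactly 2 classes, got {len(cls)}")
    if np.any(counts < 2):
        raise ValueError("each class needs at least 2 samples")
    est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    est.fit(features, labels)
    return LDAModel(estimator=est)


@dataclass
class CVResult:
    """Fold accuracies plus their mean/std and per-fold predictions."""

    fold_accuracies: np.ndarray
    predictions: list[np.ndarray]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies))


def cross_validate(
    epochs: EpochSet,
    pipeline_factory,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold evaluation of a full pipeline.

    ``pipeline_factory`` is either a zero-argument callable returning a
    fresh pipeline per fold or a pipeline instance exposing ``clone()``.
    The pipeline is fit on each training split only; accuracy comes from
    the untouched held-out split, so any optimization inside ``fit``
    cannot leak test information.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    epochs.require_two_classes()
    _, counts = np.unique(epochs.labels, return_counts=True)
    if np.any(counts < folds):
        raise DataError(
            f"cannot stratify {counts.min()} trials of one class into {folds} folds"
        )
    accs, preds = [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for tr_idx, te_idx in skf.split(np.zeros(epochs.n_trials), epochs.labels):
            pipe = (pipeline_factory() if callable(pipeline_factory)
                    else pipeline_factory.clone())
            pipe.fit(epochs.subset_trials(tr_idx))
            yhat = np.asarray(pipe.predict(epochs.subset_trials(te_idx)))
            accs.append(float(np.mean(yhat == epochs.labels[te_idx])))
            preds.append(yhat)
    return CVResult(fold_accuracies=np.array(accs), predictions=preds)


def pairwise_wincount(results: dict[str, np.ndarray]):
    """Count, for each ordered configuration pair, how often one wins.

    ``results`` maps configuration name -> accuracy list; lists must be
    paired (same runs, same length).  Entry (i, j) of the count matrix is
    the number of runs where configuration i's accuracy strictly exceeds
    configuration j's; ties count for neither side.  Returns
    (names, counts, percentages).
    """
    names = list(results)
    lists = [np.asarray(results[n], float) for n in names]
    total = len(lists[0])
    if any(len(a) != total for a in lists):
        raise ValueError("accuracy lists must have equal length (paired runs)")
    k = len(names)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            if i != j:
                counts[i, j] = int(np.sum(lists[i] > lists[j]))
    return names, counts, 100.0 * counts / total
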