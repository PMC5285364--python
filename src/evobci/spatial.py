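"""Common spatial patterns, Tikhonov-regularized CSP, and pair selection.

CSP finds spatial filters w maximizing the variance ratio between two
classes: w'C1w / w'(C1+C2)w.  The Tikhonov-regularized variant (TRCSP)
penalizes large filter norms,

    max_w  w' C1 w / (w' (C1 + C2) w + alpha ||w||^2),

and symmetrically with C2 in the numerator, which shrinks the filters and
improves out-of-sample robustness on noisy training covariances.  At
alpha = 0 this reduces to classical CSP via a generalized eigendecomposition.

Also provided: the generalization-performance-index procedure for choosing
how many filter pairs to keep — per-subject unity-based normalization of
training accuracies across candidate pair counts, averaged over subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .preprocess import DataError, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "CSPModel",
    "PairSelectionTable",
    "class_covariances",
    "trcsp_fit",
    "apply_filters",
    "select_alpha",
    "generalization_index",
]


@dataclass
class CSPModel:
    """Fitted spatial filters.

    ``filters`` has shape (2*n_pairs, channels); rows alternate
    best-for-class-1 / best-for-class-2, so pair j occupies rows 2j and
    2j+1.  ``objective_values`` holds each row's Rayleigh-quotient value
    under the (regularized) CSP objective.
    """

    filters: np.ndarray
    objective_values: np.ndarray
    alpha: float = 0.0

    @property
    def n_pairs(self) -> int:
        return self.filters.shape[0] // 2


@dataclass
class PairSelectionTable:
    """Training-CV accuracies per subject (rows) per candidate pair count
    (columns)."""

    accuracy: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.accuracy = np.atleast_2d(np.asarray(self.accuracy, dtype=float))
        self.pair_counts = np.asarray(self.pair_counts)
        if self.accuracy.shape[1] != len(self.pair_counts):
            raise ValueError("accuracy columns must match pair_counts")


def class_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Trace-normalized average spatial covariance per class.

    Each trial's channels x channels covariance is normalized by its trace
    before averaging within class, so high-power trials do not dominate.
    Outputs are symmetric PSD with unit trace.
    """
    epochs.require_two_classes()
    c1_lab, c2_lab = epochs.classes
    covs = {c1_lab: [], c2_lab: []}
    for trial, lab in zip(epochs.data, epochs.labels):
        X = trial - trial.mean(axis=1, keepdims=True)
        C = X @ X.T
        tr = np.trace(C)
        if tr <= 0:
            raise DataError("all-zero trial: covariance has zero trace")
        covs[lab].append(C / tr)
    C1 = np.mean(covs[c1_lab], axis=0)
    C2 = np.mean(covs[c2_lab], axis=0)
    return (C1 + C1.T) / 2, (C2 + C2.T) / 2


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Unit norm with the largest-magnitude coefficient positive
    (eigenvectors are sign/scale ambiguous)."""
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def trcsp_fit(
    cov1: np.ndarray, cov2: np.ndarray, n_pairs: int, alpha: float = 0.0
) -> CSPModel:
    """Fit (regularized) CSP filters from two class covariances.

    For each class c the top ``n_pairs`` eigenvectors of the generalized
    problem  C_c w = nu (C1 + C2 + alpha I) w  are extracted; rows are
    interleaved class-1-best, class-2-best, class-1-second, ...  Objective
    values are the corresponding generalized eigenvalues, which for
    alpha = 0 lie in [0, 1] and pair-sum to 1.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    cov1 = np.asarray(cov1, float)
    cov2 = np.asarray(cov2, float)
    M = cov1.shape[0]
    if cov1.shape != cov2.shape or cov1.shape != (M, M):
        raise ValueError("covariances must be square and same-shaped")
    if 2 * n_pairs > M:
        raise ValueError(f"{n_pairs} pairs need {2 * n_pairs} filters but only "
                         f"{M} channels are available")
    denom = cov1 + cov2 + alpha * np.eye(M)
    # tiny jitter guards strictly-singular composite covariances
    denom = denom + 1e-12 * np.trace(denom) / M * np.eye(M)
    filters, values = [], []
    for num in (cov1, cov2):
        vals, vecs = linalg.eigh(num, denom)
        order = np.argsort(vals)[::-1]
        for j in range(n_pairs):
            filters.append((num, _fix_sign(vecs[:, order[j]]), vals[order[j]]))
    rows, objs = [], []
    for j in range(n_pairs):
        for c in range(2):
            _, w, v = filters[c * n_pairs + j]
            rows.append(w)
            objs.append(v)
    return CSPModel(
        filters=np.array(rows), objective_values=np.array(objs), alpha=alpha
    )


def apply_filters(epochs: EpochSet, model: CSPModel) -> EpochSet:
    """Project epochs onto the CSP filters: virtual channels = W @ data."""
    if model.filters.shape[1] != epochs.n_channels:
        raise ValueError("filter width does not match channel count")
    proj = np.einsum("fc,tcs->tfs", model.filters, epochs.data)
    names = [f"csp{i:02d}" for i in range(model.filters.shape[0])]
    return replace(epochs, data=proj, channel_names=names)


def select_alpha(
    train: EpochSet,
    candidates=(0.0, 1e-3, 1e-2, 1e-1, 1.0),
    n_pairs: int = 1,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the Tikhonov weight by inner cross-validation on training data.

    Scores each candidate with the CV accuracy of the full
    TRCSP -> BMFLC -> LDA chain and returns the argmax; ties resolve to the
    smallest alpha (parsimony).
    """
    from .classify import cross_validate  # deferred: avoids import cycle
    from .pipelines import csp_bmflc_pipeline

    candidates = list(candidates)
    if not candidates or any(a < 0 for a in candidates):
        raise ValueError("candidates must be nonempty and nonnegative")
    best_alpha, best_acc = None, -np.inf
    for a in sorted(candidates):
        pipe = csp_bmflc_pipeline(n_pairs=n_pairs, alpha=a)
        res = cross_validate(train, pipe, folds=folds, seed=seed)
        if res.mean > best_acc + 1e-12:
            best_acc, best_alpha = res.mean, a
    return float(best_alpha)


def generalization_index(table: PairSelectionTable) -> np.ndarray:
    """Generalization performance index over candidate pair counts.

    Each subject's accuracy row is unity-normalized (min -> 0, max -> 1) so
    every subject's optimum scores 1 regardless of absolute accuracy; the
    index is the mean normalized accuracy across subjects.  A subject with a
    constant row expresses no preference and is mapped to all ones (logged).
    """
    acc = table.accuracy
    if acc.shape[1] < 2:
        raise ValueError("need at least two candidate pair counts")
    lo = acc.min(axis=1, keepdims=True)
    rng = acc.max(axis=1, keepdims=True) - lo
    flat = rng[:, 0] == 0
    if np.any(flat):
        logger.warning(
            "%d subject(s) have constant accuracy across pair counts; "
            "treated as indifferent (all ones)", int(flat.sum()),
        )
    rng[rng == 0] = 1.0
    norm = (acc - lo) / rng
    norm[flat] = 1.0
    return norm.mean(axis=0)


def optimal_pair_count(table: PairSelectionTable) -> int:
    """Argmax of the generalization index; ties favor fewer pairs."""
    idx = generalization_index(table)
    best = np.flatnonzero(idx >= idx.max() - 1e-12)[0]
    return int(table.pair_counts[best])
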