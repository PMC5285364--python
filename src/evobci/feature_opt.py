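"""Joint optimization of spatial filters and a subject-specific band.

The search space couples two things a motor-imagery classifier needs but
that are usually tuned separately: a bank of P spatial filters over the M
channels, and a narrow frequency window inside the analysis band.  Both are
packed into a single real vector

    sol = [sf_11 .. sf_1M, sf_21 .. sf_2M, ..., FS, BW]

of length P*M + 2, where FS is the window's starting frequency and BW its
bandwidth (at most 3 Hz — empirically the subject-specific reactive band is
no wider).  An evolutionary engine minimizes the cross-validated LDA error
of the features this vector induces:

1. decode: reshape the first P*M entries into the P x M filter bank, snap
   FS to the decomposer's frequency grid, convert BW to a bin count;
2. slice the per-trial amplitude maps to the selected bins, average over
   the trial window, and project through the bank (SF' F_k);
3. score with stratified inner cross-validation of a shrinkage-LDA.

Because both the filters and the band are judged by the same criterion —
held-out classification error — the optimizer can trade spatial against
spectral selectivity directly, unlike CSP whose variance objective is blind
to the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .bmflc import AmplitudeMap, BMFLCConfig, decompose
from .evolution import EvolutionTrace, GLGAConfig, cmaes_run, glga_run
from .preprocess import EpochSet, bandpass

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialFilterBank",
    "OptimizeResult",
    "solution_length",
    "solution_bounds",
    "decode_solution",
    "build_feature_matrix",
    "project_features",
    "trial_features",
    "fitness",
    "optimize",
    "error_improvement",
]

MAX_BW_HZ = 3.0


@dataclass
class SpatialFilterBank:
    """P x M projection applied to the per-instant channel x frequency
    matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("filter bank must be finite")

    @property
    def n_filters(self) -> int:
        return self.matrix.shape[0]


def solution_length(n_channels: int, n_filters: int = 2) -> int:
    return n_filters * n_channels + 2


def solution_bounds(
    n_channels: int, n_filters: int, config: BMFLCConfig
) -> np.ndarray:
    """Engine-facing box: spatial coordinates unbounded (initialized in
    [-1, 1] by the engines), FS in [f1, fn], BW in [Δf, 3]."""
    dim = solution_length(n_channels, n_filters)
    b = np.empty((dim, 2))
    b[:-2] = [-np.inf, np.inf]
    b[-2] = [config.f1_hz, config.fn_hz]
    b[-1] = [config.delta_f_hz, MAX_BW_HZ]
    return b


def decode_solution(
    sol: np.ndarray, config: BMFLCConfig, n_channels: int, n_filters: int = 2
) -> tuple[SpatialFilterBank, tuple[int, int]]:
    """Split a solution vector into (filter bank, [fs, fe] bin indices).

    FS is snapped to the nearest grid point and BW to a whole number of
    grid steps; infeasible FS/BW values are repaired by projection onto
    [f1, fn - BW] x (0, 3] before snapping (and logged), so every decoded
    band is a valid contiguous bin range with fs <= fe.
    """
    sol = np.asarray(sol, float)
    expect = solution_length(n_channels, n_filters)
    if sol.shape != (expect,):
        raise ValueError(f"solution length {sol.shape} != {expect} "
                         f"(= {n_filters}*{n_channels}+2)")
    bank = SpatialFilterBank(sol[:-2].reshape(n_filters, n_channels))
    fs_hz, bw_hz = sol[-2], sol[-1]
    bw_rep = float(np.clip(bw_hz, config.delta_f_hz, MAX_BW_HZ))
    fs_rep = float(np.clip(fs_hz, config.f1_hz, config.fn_hz - bw_rep))
    if bw_rep != bw_hz or fs_rep != fs_hz:
        logger.debug("repaired (FS, BW) = (%.3g, %.3g) -> (%.3g, %.3g)",
                     fs_hz, bw_hz, fs_rep, bw_rep)
    n = config.n_bins
    fs_idx = int(round((fs_rep - config.f1_hz) / config.delta_f_hz))
    fs_idx = min(max(fs_idx, 0), n - 1)
    fe_idx = min(fs_idx + int(round(bw_rep / config.delta_f_hz)), n - 1)
    return bank, (fs_idx, fe_idx)


def build_feature_matrix(
    amp_map: AmplitudeMap, band: tuple[int, int], k: int
) -> np.ndarray:
    """F_k: channels x selected-bins amplitude slice at time instant k."""
    fs, fe = band
    n = amp_map.amplitudes.shape[1]
    if not (0 <= fs <= fe < n):
        raise ValueError(f"band [{fs}, {fe}] outside bin range [0, {n - 1}]")
    return amp_map.amplitudes[:, fs: fe + 1, k]


def project_features(
    amp_map: AmplitudeMap,
    band: tuple[int, int],
    bank: SpatialFilterBank,
    window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Project one trial's map through the bank, averaged over the window.

    Per instant k the product SF' F_k is a P x n_selected matrix; the trial
    feature is the element-wise mean over the window, flattened row-major
    to length P * n_selected.
    """
    fs, fe = band
    n_ch, n, n_samp = amp_map.amplitudes.shape
    if bank.matrix.shape[1] != n_ch:
        raise ValueError(
            f"bank width {bank.matrix.shape[1]} != {n_ch} channels"
        )
    if fs > fe or fs < 0 or fe >= n:
        raise ValueError(f"invalid band [{fs}, {fe}]")
    w0, w1 = window if window is not None else (0, n_samp)
    sliced = amp_map.amplitudes[:, fs: fe + 1, w0:w1]
    per_instant = np.einsum("pc,cfk->pfk", bank.matrix, sliced)
    return per_instant.mean(axis=2).ravel()


def _mean_maps(
    maps: list[AmplitudeMap], window: tuple[int, int] | None
) -> np.ndarray:
    """Stack per-trial window-averaged maps: (trials, channels, bins).

    Projection and mean-over-window commute, so the mean map per trial is
    precomputed once and every fitness call reduces to a small matmul.
    """
    out = []
    for m in maps:
        w0, w1 = window if window is not None else (0, m.amplitudes.shape[2])
        out.append(m.amplitudes[:, :, w0:w1].mean(axis=2))
    return np.stack(out)


def trial_features(
    mean_maps: np.ndarray, bank: SpatialFilterBank, band: tuple[int, int]
) -> np.ndarray:
    """(trials, P * n_selected) features from precomputed mean maps."""
    fs, fe = band
    sliced = mean_maps[:, :, fs: fe + 1]
    proj = np.einsum("pc,tcf->tpf", bank.matrix, sliced)
    return proj.reshape(proj.shape[0], -1)


#: fixed shrinkage of the inner-loop LDA toward scaled identity; keeps the
#: pooled covariance invertible for any band width at small trial counts
INNER_LDA_SHRINKAGE = 0.1


def _fast_lda_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
    gamma: float = INNER_LDA_SHRINKAGE,
) -> np.ndarray:
    """Closed-form two-class shrinkage LDA for the fitness hot path.

    Identical model to ``classify.lda_fit`` with a fixed shrinkage
    intensity (per-class covariances shrunk toward tr(S)/p * I, pooled by
    class priors, linear discriminant with prior-corrected threshold); the
    direct solve is an order of magnitude faster than a full estimator fit,
    which matters when the EA calls it tens of thousands of times.
    Prediction equivalence with the estimator route is pinned by a test.
    """
    cls = np.unique(ytr)
    n, p = Xtr.shape
    means, covs, priors = [], [], []
    for c in cls:
        Xc = Xtr[ytr == c]
        mu = Xc.mean(axis=0)
        Z = Xc - mu
        S = (Z.T @ Z) / len(Xc)
        S = (1 - gamma) * S + gamma * (np.trace(S) / p) * np.eye(p)
        means.append(mu)
        covs.append(S)
        priors.append(len(Xc) / n)
    pooled = priors[0] * covs[0] + priors[1] * covs[1]
    w = np.linalg.solve(pooled, means[1] - means[0])
    thresh = 0.5 * (means[1] + means[0]) @ w - np.log(priors[1] / priors[0])
    return np.where(Xte @ w > thresh, cls[1], cls[0])


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    """Fixed stratified partition reused across all fitness calls."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _cv_error(X: np.ndarray, y: np.ndarray, folds_or_splits, seed: int) -> float:
    """Stratified CV error of shrinkage-LDA on standardized features.

    Features are z-scored with fold-train statistics (zero-variance columns
    get unit std), which makes the error invariant to positive rescaling of
    any filter row and keeps LDA well-posed on degenerate features.
    """
    if isinstance(folds_or_splits, int):
        splits = _stratified_folds(y, folds_or_splits, seed)
    else:
        splits = folds_or_splits
    errs = []
    for tr, te in splits:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        yhat = _fast_lda_predict((X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd)
        errs.append(float(np.mean(yhat != y[te])))
    return float(np.mean(errs))


def fitness(
    sol: np.ndarray,
    train_maps: list[AmplitudeMap] | np.ndarray,
    labels: np.ndarray,
    config: BMFLCConfig,
    n_channels: int,
    n_filters: int = 2,
    cv_folds: int = 10,
    seed: int = 0,
    window: tuple[int, int] | None = None,
    splits=None,
) -> float:
    """Cross-validated LDA error rate of one candidate solution, in [0, 1].

    The CV partition is fixed by ``seed`` (or passed precomputed via
    ``splits``), so the same solution always scores the same error — a
    deterministic fitness for the evolutionary engines.  ``train_maps`` may
    be the raw list of amplitude maps or a precomputed
    (trials, channels, bins) mean-map stack.
    """
    labels = np.asarray(labels)
    if isinstance(train_maps, np.ndarray):
        mean_maps = train_maps
    else:
        mean_maps = _mean_maps(train_maps, window)
    bank, band = decode_solution(sol, config, n_channels, n_filters)
    X = trial_features(mean_maps, bank, band)
    if splits is None:
        _, counts = np.unique(labels, return_counts=True)
        splits = min(cv_folds, int(counts.min()))
    return _cv_error(X, labels, splits, seed)


@dataclass
class OptimizeResult:
    """Best solution found, its decoded parts, and the evolution trace."""

    solution: np.ndarray
    bank: SpatialFilterBank
    band_bins: tuple[int, int]
    band_hz: tuple[float, float]
    best_error: float
    trace: EvolutionTrace
    config: BMFLCConfig


def optimize(
    train: EpochSet,
    engine: str = "cmaes",
    config: BMFLCConfig | None = None,
    n_filters: int | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    window: tuple[int, int] | None = None,
    max_generations: int = 300,
    glga_config: GLGAConfig | None = None,
    assume_filtered: bool = False,
    maps: list[AmplitudeMap] | None = None,
) -> OptimizeResult:
    """Run the full EA feature optimization on a training epoch set.

    The epochs are band-pass filtered to the decomposer band and decomposed
    once; the amplitude maps are cached and reused for every fitness call.
    ``n_filters`` defaults to the number of classes.  ``engine`` selects
    'cmaes' (generation budget ``max_generations``, lambda = 5 x dim) or
    'glga' (evaluation budget from ``glga_config``).
    """
    config = config or BMFLCConfig()
    train.require_two_classes()
    P = n_filters if n_filters is not None else len(train.classes)
    M = train.n_channels
    if maps is None:
        filtered = train if assume_filtered else bandpass(
            train, config.f1_hz, config.fn_hz
        )
        maps = decompose(filtered, config)
    mean_maps = _mean_maps(maps, window)
    labels = train.labels
    dim = solution_length(M, P)
    bounds = solution_bounds(M, P, config)

    _, counts = np.unique(labels, return_counts=True)
    splits = _stratified_folds(labels, min(cv_folds, int(counts.min())), seed)

    def fit_fn(x):
        return fitness(x, mean_maps, labels, config, M, P, seed=seed,
                       splits=splits)

    if engine == "cmaes":
        best, trace = cmaes_run(fit_fn, dim, bounds,
                                max_generations=max_generations, seed=seed)
    elif engine == "glga":
        best, trace = glga_run(fit_fn, dim, bounds,
                               config=glga_config or GLGAConfig(), seed=seed)
    else:
        raise ValueError(f"unknown engine {engine!r}; use 'cmaes' or 'glga'")

    bank, band = decode_solution(best, config, M, P)
    freqs = config.bin_freqs_hz
    return OptimizeResult(
        solution=best,
        bank=bank,
        band_bins=band,
        band_hz=(float(freqs[band[0]]), float(freqs[band[1]])),
        best_error=float(fit_fn(best)),
        trace=trace,
        config=config,
    )


def error_improvement(trace: EvolutionTrace) -> float:
    """Spread of the best-error series over the run: max - min (>= 0).

    Measures how much of the error surface the engine explored between its
    worst and best recorded incumbents.
    """
    series = np.asarray(trace.best_fitness, float)
    if series.size == 0:
        raise ValueError("empty trace")
    return float(series.max() - series.min())
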