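"""The three classifier configurations, as fit/predict pipelines.

1. ``BMFLCPipeline`` — manual channel selection (classically C3/C4),
   BMFLC-KF decomposition of the full analysis band, LDA.  No optimization;
   the baseline every improvement is measured against.
2. ``CSPBMFLCPipeline`` — Tikhonov-regularized CSP fitted on the band-pass
   filtered training trials reduces the montage to a few virtual channels,
   which are then decomposed by BMFLC-KF and classified with LDA.
3. ``EAPipeline`` — BMFLC-KF first, then an evolutionary engine jointly
   optimizes the spatial-filter bank and a narrow sub-band against
   cross-validated LDA error on the training split.

All pipelines implement ``fit(EpochSet) -> self`` and
``predict(EpochSet) -> labels`` so the outer cross-validation harness can
treat them interchangeably; everything learned (filters, band, classifier,
feature scaling) comes from the training split alone.
"""

from __future__ import annotations

import numpy as np

from .bmflc import BMFLCConfig, decompose
from .classify import lda_fit
from .evolution import GLGAConfig
from .feature_opt import optimize, trial_features, _mean_maps
from .preprocess import EpochSet, bandpass
from .spatial import class_covariances, trcsp_fit, apply_filters

__all__ = [
    "BMFLCPipeline",
    "CSPBMFLCPipeline",
    "EAPipeline",
    "bmflc_pipeline",
    "csp_bmflc_pipeline",
    "ea_pipeline",
]


class _Standardizer:
    """Per-feature z-scoring with train statistics; zero-variance -> unit."""

    def fit(self, X):
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.sd[self.sd == 0] = 1.0
        return self

    def __call__(self, X):
        return (X - self.mu) / self.sd


def _band_features(epochs: EpochSet, config: BMFLCConfig) -> np.ndarray:
    """Full-band mean-amplitude features: (trials, channels * bins)."""
    maps = decompose(epochs, config)
    mm = _mean_maps(maps, None)
    return mm.reshape(mm.shape[0], -1)


class BMFLCPipeline:
    """Configuration 1: fixed channel subset, full-band BMFLC features."""

    def __init__(self, channels=(0, 1), config: BMFLCConfig | None = None):
        self.channels = list(channels)
        self.config = config or BMFLCConfig()

    def clone(self):
        return BMFLCPipeline(self.channels, self.config)

    def _features(self, epochs: EpochSet) -> np.ndarray:
        sub = epochs.select_channels(self.channels)
        filt = bandpass(sub, self.config.f1_hz, self.config.fn_hz)
        return _band_features(filt, self.config)

    def fit(self, train: EpochSet):
        X = self._features(train)
        self.scaler = _Standardizer().fit(X)
        self.model = lda_fit(self.scaler(X), train.labels)
        return self

    def predict(self, test: EpochSet) -> np.ndarray:
        return self.model.predict(self.scaler(self._features(test)))


class CSPBMFLCPipeline:
    """Configuration 2: TRCSP spatial reduction, then BMFLC features."""

    def __init__(
        self,
        n_pairs: int = 1,
        alpha: float = 0.0,
        config: BMFLCConfig | None = None,
    ):
        self.n_pairs = n_pairs
        self.alpha = alpha
        self.config = config or BMFLCConfig()

    def clone(self):
        return CSPBMFLCPipeline(self.n_pairs, self.alpha, self.config)

    def fit(self, train: EpochSet):
        filt = bandpass(train, self.config.f1_hz, self.config.fn_hz)
        c1, c2 = class_covariances(filt)
        self.csp = trcsp_fit(c1, c2, self.n_pairs, self.alpha)
        X = _band_features(apply_filters(filt, self.csp), self.config)
        self.scaler = _Standardizer().fit(X)
        self.model = lda_fit(self.scaler(X), train.labels)
        return self

    def predict(self, test: EpochSet) -> np.ndarray:
        filt = bandpass(test, self.config.f1_hz, self.config.fn_hz)
        X = _band_features(apply_filters(filt, self.csp), self.config)
        return self.model.predict(self.scaler(X))


class EAPipeline:
    """Configuration 3: evolutionary joint spatial-filter + band selection."""

    def __init__(
        self,
        engine: str = "cmaes",
        config: BMFLCConfig | None = None,
        seed: int = 0,
        max_generations: int = 50,
        glga_config: GLGAConfig | None = None,
        cv_folds: int = 10,
        n_filters: int | None = None,
    ):
        self.engine = engine
        self.config = config or BMFLCConfig()
        self.seed = seed
        self.max_generations = max_generations
        self.glga_config = glga_config
        self.cv_folds = cv_folds
        self.n_filters = n_filters

    def clone(self):
        return EAPipeline(self.engine, self.config, self.seed,
                          self.max_generations, self.glga_config,
                          self.cv_folds, self.n_filters)

    def fit(self, train: EpochSet):
        self.result = optimize(
            train,
            engine=self.engine,
            config=self.config,
            n_filters=self.n_filters,
            cv_folds=self.cv_folds,
            seed=self.seed,
            max_generations=self.max_generations,
            glga_config=self.glga_config,
        )
        filt = bandpass(train, self.config.f1_hz, self.config.fn_hz)
        mm = _mean_maps(decompose(filt, self.config), None)
        X = trial_features(mm, self.result.bank, self.result.band_bins)
        self.scaler = _Standardizer().fit(X)
        self.model = lda_fit(self.scaler(X), train.labels)
        return self

    def predict(self, test: EpochSet) -> np.ndarray:
        filt = bandpass(test, self.config.f1_hz, self.config.fn_hz)
        mm = _mean_maps(decompose(filt, self.config), None)
        X = trial_features(mm, self.result.bank, self.result.band_bins)
        return self.model.predict(self.scaler(X))


def bmflc_pipeline(channels=(0, 1), config=None):
    """Factory for configuration 1 (fresh pipeline per CV fold)."""
    return lambda: BMFLCPipeline(channels, config)


def csp_bmflc_pipeline(n_pairs=1, alpha=0.0, config=None):
    """Factory for configuration 2."""
    return lambda: CSPBMFLCPipeline(n_pairs, alpha, config)


def ea_pipeline(engine="cmaes", **kwargs):
    """Factory for configuration 3."""
    return lambda: EAPipeline(engine, **kwargs)
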