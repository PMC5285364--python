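"""Synthetic multi-channel motor-imagery EEG with a planted band effect.

The generator emulates the structure of cue-based motor-imagery recordings:
multi-channel epochs in which one latent oscillatory source, confined to a
narrow sub-band of the 6-14 Hz analysis range and projected to the sensors
through a fixed mixing column, is attenuated in one class — the
event-related desynchronization (ERD) that makes left- vs right-hand
imagery separable.  Background sources and 1/f-shaped sensor noise are
class-independent, so the planted source is the only discriminative signal
and its band/mixing column are returned as ground truth for recovery tests.

The oscillation is a narrowband-filtered Gaussian process rather than a
pure sinusoid, so the decomposer sees a band, not a spectral line.  The
noise floor is 1/f-shaped with a small white component: EEG-like in
spectrum without claiming physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import EpochSet

__all__ = ["SynthConfig", "GroundTruth", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generation parameters.

    ``erd_depth`` d scales the discriminative source to (1-d)·A in class 0
    versus A in class 1; d=0 makes the classes identically distributed and
    d=1 silences the source entirely in class 0.  Defaults mirror a typical
    22-channel, 250 Hz competition recording with 72 trials per class of
    4 s each.
    """

    channels: int = 22
    trials_per_class: int = 72
    rate_hz: float = 250.0
    duration_s: float = 4.0
    planted_band_hz: tuple[float, float] = (9.0, 11.0)
    erd_depth: float = 0.8
    source_amp: float = 2.0
    n_background: int = 4
    noise_level: float = 1.0
    mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.planted_band_hz
        if not (6.0 <= lo < hi <= 14.0):
            raise ValueError(
                f"planted band [{lo}, {hi}] must lie inside [6, 14] Hz"
            )
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate_hz * self.duration_s))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    band_hz: tuple[float, float]
    mixing_col: np.ndarray
    disc_channel: int

    def to_dict(self) -> dict:
        return {
            "band_lo_hz": self.band_hz[0],
            "band_hi_hz": self.band_hz[1],
            "disc_channel": self.disc_channel,
            "mixing_col": " ".join(f"{v:.8g}" for v in self.mixing_col),
        }


def _pink(rng: np.random.Generator, n_rows: int, n_samples: int) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise, one row per channel."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband(
    rng: np.random.Generator,
    n_samples: int,
    rate_hz: float,
    lo_hz: float,
    hi_hz: float,
) -> np.ndarray:
    """Unit-variance narrowband Gaussian process (random phase by nature)."""
    pad = n_samples  # generous transient margin for narrow bands
    white = rng.standard_normal(n_samples + 2 * pad)
    sos = signal.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=rate_hz,
                        output="sos")
    x = signal.sosfiltfilt(sos, white)[pad: pad + n_samples]
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def generate_subject(config: SynthConfig) -> tuple[EpochSet, GroundTruth]:
    """One synthetic subject: epochs plus the planted ground truth.

    Each trial is mixing @ sources + noise.  Source 0 is the discriminative
    narrowband oscillation with class-dependent amplitude; the remaining
    sources are class-independent 1/f processes.  Trials of the two classes
    are interleaved in random order.
    """
    rng = np.random.default_rng(config.seed)
    M, K = config.channels, config.n_samples
    S = config.n_background + 1
    if config.mixing is not None:
        A = np.asarray(config.mixing, float)
        if A.shape != (M, S):
            raise ValueError(f"mixing must be ({M}, {S}), got {A.shape}")
    else:
        A = rng.standard_normal((M, S))
        # concentrate the discriminative column on a few sensors so the
        # spatial pattern is localized, as scalp ERD is
        focus = rng.choice(M, size=max(2, M // 6), replace=False)
        col = np.zeros(M)
        col[focus] = rng.uniform(0.5, 1.0, size=len(focus)) * rng.choice(
            [-1, 1], size=len(focus)
        )
        A[:, 0] = col + 0.05 * rng.standard_normal(M)

    lo, hi = config.planted_band_hz
    n_total = 2 * config.trials_per_class
    labels = np.repeat([0, 1], config.trials_per_class)
    labels = labels[rng.permutation(n_total)]
    data = np.empty((n_total, M, K))
    amp = {0: (1.0 - config.erd_depth) * config.source_amp,
           1: config.source_amp}
    for t in range(n_total):
        sources = np.empty((S, K))
        sources[0] = amp[labels[t]] * _narrowband(rng, K, config.rate_hz, lo, hi)
        sources[1:] = _pink(rng, S - 1, K)
        noise = config.noise_level * (
            0.8 * _pink(rng, M, K) + 0.2 * rng.standard_normal((M, K))
        )
        data[t] = A @ sources + noise
    epochs = EpochSet(data=data, labels=labels, rate_hz=config.rate_hz)
    truth = GroundTruth(
        band_hz=(lo, hi),
        mixing_col=A[:, 0].copy(),
        disc_channel=int(np.argmax(np.abs(A[:, 0]))),
    )
    return epochs, truth


def generate_cohort(
    n_subjects: int,
    base_config: SynthConfig | None = None,
    seed: int = 0,
) -> list[tuple[EpochSet, GroundTruth]]:
    """A cohort of subjects with randomized bands and mixing patterns.

    Band centers are drawn from [7.5, 12.5] Hz so that a 3 Hz window always
    fits inside the 6-14 Hz analysis band; each subject gets an independent
    mixing matrix.  Deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_config or SynthConfig()
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        center = rng.uniform(7.5, 12.5)
        width = base.planted_band_hz[1] - base.planted_band_hz[0]
        band = (center - width / 2, center + width / 2)
        sub_seed = int(rng.integers(2**31))
        cfg = SynthConfig(
            channels=base.channels,
            trials_per_class=base.trials_per_class,
            rate_hz=base.rate_hz,
            duration_s=base.duration_s,
            planted_band_hz=(round(band[0], 3), round(band[1], 3)),
            erd_depth=base.erd_depth,
            source_amp=base.source_amp,
            n_background=base.n_background,
            noise_level=base.noise_level,
            seed=sub_seed,
        )
        cohort.append(generate_subject(cfg))
    return cohort
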