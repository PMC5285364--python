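"""Band-limited multiple Fourier linear combiner with Kalman tracking.

The BMFLC models a band-limited signal as a truncated Fourier series on a
fixed frequency grid f_1, f_1+Δf, ..., f_n and tracks the sine/cosine
coefficients over time.  With a random-walk state model

    w_{k+1} = w_k + eta_k,        y_k = x_k' w_k + v_k,

a Kalman filter adapts the 2n coefficients sample by sample; the amplitude
of grid bin i at instant k is sqrt(a_ik^2 + b_ik^2).  Cascading these
amplitude vectors over time yields a time-frequency map with one row per
frequency bin — the raw feature set for classification.

The state transition is the identity, so the Kalman error covariance (and
hence the gain) depends only on the reference vector sequence, the
measurement-noise variance R and the process-noise variance q — not on the
measurements.  :func:`decompose` exploits this: the covariance recursion is
run once per trial and the per-channel weight updates are vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import DataError, EpochSet

__all__ = [
    "BMFLCConfig",
    "WeightState",
    "AmplitudeMap",
    "build_reference",
    "kalman_step",
    "amplitude",
    "decompose",
]


@dataclass(frozen=True)
class BMFLCConfig:
    """Frequency grid and Kalman noise parameters.

    The grid spans ``[f1_hz, fn_hz]`` in steps of ``delta_f_hz``; the span
    must be an integer multiple of the spacing.  ``r_meas`` is the
    measurement-noise variance R, ``q_proc`` the per-coefficient process
    noise q (process covariance Q = q·I).  Defaults follow the common
    BMFLC-KF practice of unit measurement noise with a small random-walk
    drift.
    """

    f1_hz: float = 6.0
    fn_hz: float = 14.0
    delta_f_hz: float = 0.5
    r_meas: float = 1.0
    q_proc: float = 0.01

    def __post_init__(self) -> None:
        if not self.f1_hz < self.fn_hz:
            raise ValueError("f1_hz must be < fn_hz")
        if self.delta_f_hz <= 0:
            raise ValueError("delta_f_hz must be positive")
        ratio = (self.fn_hz - self.f1_hz) / self.delta_f_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"(fn - f1) = {self.fn_hz - self.f1_hz} Hz is not an integer "
                f"multiple of delta_f = {self.delta_f_hz} Hz"
            )
        if self.r_meas <= 0 or self.q_proc < 0:
            raise ValueError("r_meas must be > 0 and q_proc >= 0")

    @property
    def n_bins(self) -> int:
        """Number of frequency bins n = (fn - f1)/Δf + 1."""
        return int(round((self.fn_hz - self.f1_hz) / self.delta_f_hz)) + 1

    @property
    def bin_freqs_hz(self) -> np.ndarray:
        return self.f1_hz + self.delta_f_hz * np.arange(self.n_bins)


@dataclass
class WeightState:
    """Kalman state: 2n coefficients (sine block then cosine block) and the
    posterior error covariance."""

    weights: np.ndarray
    error_cov: np.ndarray

    @classmethod
    def initial(cls, n_bins: int, p0: float = 1.0) -> "WeightState":
        dim = 2 * n_bins
        return cls(weights=np.zeros(dim), error_cov=p0 * np.eye(dim))


@dataclass
class AmplitudeMap:
    """Per-channel, per-bin, per-sample amplitude estimates W_k.

    ``amplitudes`` has shape (channels, n_bins, samples) and is everywhere
    nonnegative; cascading the columns over time gives the time-frequency
    map D = [W_1, ..., W_K].
    """

    amplitudes: np.ndarray
    bin_freqs_hz: np.ndarray
    rate_hz: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 3:
            raise DataError("amplitudes must be (channels, bins, samples)")
        if self.amplitudes.shape[1] != len(self.bin_freqs_hz):
            raise DataError("bin axis does not match bin_freqs_hz")
        if np.any(self.amplitudes < 0):
            raise DataError("amplitudes must be nonnegative")


def build_reference(config: BMFLCConfig, rate_hz: float, k: int | np.ndarray) -> np.ndarray:
    """Reference vector x_k = [sin(2π f_i k / fs)..., cos(2π f_i k / fs)...].

    The grid phase is sample-indexed: bin i contributes sin(2π f_i k / fs)
    at sample k.  Vectorized over k: passing an array of sample indices
    returns an array of shape (len(k), 2n).
    """
    if rate_hz <= 2 * config.fn_hz:
        raise ValueError(
            f"sampling rate {rate_hz} Hz must exceed twice the upper band "
            f"edge ({config.fn_hz} Hz)"
        )
    k = np.asarray(k, dtype=float)
    phase = 2.0 * np.pi * np.multiply.outer(k, config.bin_freqs_hz) / rate_hz
    ref = np.concatenate([np.sin(phase), np.cos(phase)], axis=-1)
    return ref


def kalman_step(
    state: WeightState, x: np.ndarray, y: float, config: BMFLCConfig
) -> WeightState:
    """One predict/update cycle of the random-walk Kalman recursion.

    Predict: w stays, P <- P + qI.  Update: K = Px / (x'Px + R),
    w <- w + K (y - x'w), P <- (I - K x') P, then symmetrized.
    """
    if not np.isfinite(y):
        raise DataError(f"non-finite measurement {y}")
    w, P = state.weights, state.error_cov
    dim = w.shape[0]
    if x.shape[-1] != dim:
        raise ValueError(f"reference length {x.shape[-1]} != state dim {dim}")
    P = P + config.q_proc * np.eye(dim)
    Px = P @ x
    s = float(x @ Px) + config.r_meas
    K = Px / s
    w = w + K * (y - float(x @ w))
    P = P - np.outer(K, Px)
    P = (P + P.T) / 2.0
    return WeightState(weights=w, error_cov=P)


def amplitude(state: WeightState) -> np.ndarray:
    """Per-bin amplitude sqrt(a_i^2 + b_i^2) from a weight state."""
    n = state.weights.shape[0] // 2
    a, b = state.weights[:n], state.weights[n:]
    return np.hypot(a, b)


def _run_channels(
    Y: np.ndarray, refs: np.ndarray, config: BMFLCConfig, p0: float = 1.0
) -> np.ndarray:
    """Run the KF over all channels of one trial at once.

    Y : (channels, samples) measurements; refs : (samples, 2n) reference
    vectors.  Returns amplitudes (channels, n, samples).  The covariance is
    measurement-independent so one recursion serves every channel.
    """
    n = config.n_bins
    dim = 2 * n
    n_ch, n_samp = Y.shape
    W = np.zeros((n_ch, dim))
    P = p0 * np.eye(dim)
    qI = config.q_proc * np.eye(dim)
    out = np.empty((n_ch, n, n_samp))
    for k in range(n_samp):
        x = refs[k]
        P += qI
        Px = P @ x
        s = Px @ x + config.r_meas
        K = Px / s
        innov = Y[:, k] - W @ x
        W += innov[:, None] * K[None, :]
        P -= np.outer(K, Px)
        P = (P + P.T) / 2.0
        out[:, :, k] = np.hypot(W[:, :n], W[:, n:])
    return out


def decompose(
    epochs: EpochSet, config: BMFLCConfig | None = None, p0: float = 1.0
) -> list[AmplitudeMap]:
    """BMFLC-KF decomposition of every trial, one amplitude map per trial.

    The weight state is re-initialized at each trial start: trials are
    independent cue-based epochs, so no state carries over.  Input is
    expected to be band-pass filtered to [f1, fn] beforehand.
    """
    config = config or BMFLCConfig()
    refs = build_reference(config, epochs.rate_hz, np.arange(epochs.n_samples))
    maps = []
    for t in range(epochs.n_trials):
        amps = _run_channels(epochs.data[t], refs, config, p0=p0)
        maps.append(
            AmplitudeMap(
                amplitudes=amps,
                bin_freqs_hz=config.bin_freqs_hz,
                rate_hz=epochs.rate_hz,
            )
        )
    return maps


def least_squares_amplitudes(
    y: np.ndarray, config: BMFLCConfig, rate_hz: float
) -> np.ndarray:
    """Batch least-squares truncated-Fourier fit over a whole window.

    Independent reference oracle for the adaptive tracker: solves
    min_w ||y - X w||^2 with X the stacked reference vectors and returns the
    per-bin amplitudes.  Used for cross-checking steady-state KF estimates
    on stationary signals.
    """
    refs = build_reference(config, rate_hz, np.arange(len(y)))
    w, *_ = np.linalg.lstsq(refs, y, rcond=None)
    n = config.n_bins
    return np.hypot(w[:n], w[n:])
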