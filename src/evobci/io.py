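"""HDF5 epoch container, ground-truth sidecars, and the optional EDF reader.

The canonical on-disk form of an :class:`~evobci.preprocess.EpochSet` is a
small HDF5 file with datasets ``X`` (trials x channels x samples), ``y``
(labels) and ``channels``, plus ``rate_hz`` and arbitrary provenance
metadata as root attributes.  Round-trips are lossless.

The EDF adapter is optional and isolated here so the core pipeline has no
EEG-format dependency; it maps a continuous EDF recording plus its
annotations to cue-locked epochs.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .preprocess import EpochSet

__all__ = [
    "FormatError",
    "write_container",
    "read_container",
    "write_ground_truth",
    "read_ground_truth",
    "read_edf",
]


class FormatError(ValueError):
    """A container file is missing required datasets or attributes."""


def write_container(epochs: EpochSet, path, metadata: dict | None = None) -> None:
    """Write an EpochSet to HDF5 with provenance metadata attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=epochs.data)
        f.create_dataset("y", data=np.asarray(epochs.labels))
        f.create_dataset(
            "channels",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        f.attrs["rate_hz"] = float(epochs.rate_hz)
        for key, val in (metadata or {}).items():
            f.attrs[key] = val if np.isscalar(val) else json.dumps(val)


def read_container(path) -> EpochSet:
    """Read an EpochSet back; raises FormatError naming any missing field."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open container {path}: {exc}") from exc
    with f:
        for name in ("X", "y", "channels"):
            if name not in f:
                raise FormatError(f"container {path} is missing dataset '{name}'")
        if "rate_hz" not in f.attrs:
            raise FormatError(f"container {path} is missing attribute 'rate_hz'")
        return EpochSet(
            data=f["X"][()],
            labels=f["y"][()],
            rate_hz=float(f.attrs["rate_hz"]),
            channel_names=[c.decode() if isinstance(c, bytes) else str(c)
                           for c in f["channels"][()]],
        )


def container_metadata(path) -> dict:
    with h5py.File(path, "r") as f:
        return dict(f.attrs)


def write_ground_truth(truth, path) -> None:
    """Plain-text key-value sidecar recording what a generator planted."""
    with open(path, "w") as fh:
        for key, val in truth.to_dict().items():
            fh.write(f"{key} = {val}\n")


def read_ground_truth(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out


def _check_uniform_rate(path) -> None:
    """Reject EDF files whose signals have per-channel sampling rates.

    Reads the fixed-offset header fields directly: bytes 252-256 hold the
    signal count and the samples-per-record block sits after the
    per-signal label/transducer/unit/range/prefilter fields.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        ns = int(header[252:256].decode("ascii").strip())
        sig = fh.read(ns * 256)
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = {int(sig[off + i * 8: off + (i + 1) * 8].decode().strip())
           for i in range(ns)}
    if len(spr) > 1:
        raise FormatError(
            f"{path}: per-channel sampling rates {sorted(spr)} are unsupported"
        )


def read_edf(path, events: list[tuple[float, float]] | None = None,
             labels=None) -> EpochSet | tuple[np.ndarray, float, list[str]]:
    """Read an EDF recording; epoch it if event windows are supplied.

    Parameters
    ----------
    path : str
        EDF/EDF+ file.
    events : list of (onset_s, duration_s), optional
        Epoch windows.  Without them the continuous signal is returned as
        ``(data, rate_hz, channel_names)`` and epoching is refused.
    labels : array-like, optional
        One class label per event; required together with ``events``.

    Notes
    -----
    Requires the optional ``mne`` dependency.  Recordings with per-channel
    sampling rates are rejected as unsupported.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF support requires the optional 'mne' dependency "
            "(pip install evobci[edf])"
        ) from exc
    _check_uniform_rate(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rate = float(raw.info["sfreq"])
    data = raw.get_data()
    names = list(raw.ch_names)
    if events is None:
        return data, rate, names
    if labels is None or len(labels) != len(events):
        raise ValueError("epoching needs one label per event window")
    n_samp = int(round(events[0][1] * rate))
    trials = []
    for onset, dur in events:
        i0 = int(round(onset * rate))
        i1 = i0 + int(round(dur * rate))
        if int(round(dur * rate)) != n_samp:
            raise ValueError("all event windows must share one duration")
        if i1 > data.shape[1]:
            raise ValueError(f"event at {onset}s extends past the recording")
        trials.append(data[:, i0:i1])
    return EpochSet(
        data=np.stack(trials),
        labels=np.asarray(labels),
        rate_hz=rate,
        channel_names=names,
    )
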