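"""Continuous-signal conditioning and epoching.

The conditioning chain is a zero-phase 4th-order Butterworth band-pass
(0.1-45 Hz by default), common-average re-referencing over the scalp
channels, and cutting fixed windows of -200..+600 ms around each stimulus
event. Blind-source-separation artifact removal is deliberately not part of
this chain; users with cleaned data can epoch it directly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .containers import EpochSet, Recording

__all__ = [
    "bandpass_filter",
    "average_rereference",
    "epoch_signal",
    "read_edf",
]


def bandpass_filter(
    rec: Recording,
    low_hz: float = 0.1,
    high_hz: float = 45.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth response and the
    phase response is zero; the nominal ``order`` refers to a single pass.
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if not (0.0 < low_hz < high_hz < rec.fs / 2.0):
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) must satisfy 0 < low < high < fs/2"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=filtered)


def average_rereference(rec: Recording, exclude: tuple[str, ...] = ()) -> Recording:
    """Subtract the instantaneous mean over scalp channels from each channel.

    ``exclude`` names channels (e.g. EOG leads) left out of the average and
    left untouched in the output; by default any label starting with "EOG"
    is excluded.
    """
    labels = rec.channel_labels
    is_scalp = np.array(
        [not (lab.upper().startswith("EOG") or lab in exclude) for lab in labels]
    )
    if int(is_scalp.sum()) < 2:
        raise ValueError("average reference requires at least 2 scalp channels")
    out = rec.data.copy()
    mean = out[is_scalp].mean(axis=0, keepdims=True)
    out[is_scalp] -= mean
    return rec.copy_with(data=out)


def epoch_signal(
    rec: Recording,
    pre_ms: float = 200.0,
    post_ms: float = 600.0,
) -> EpochSet:
    """Cut one epoch per event over the half-open window around onset.

    The window is ``[onset - floor(pre_ms*fs/1000), onset + floor(post_ms*fs/1000))``
    so every epoch has the same sample count regardless of rounding platform
    (409 samples for 200+600 ms at 512 Hz). Events too close to the
    recording edge are dropped with a warning reporting the count.
    """
    if pre_ms < 0 or post_ms <= 0:
        raise ValueError("pre_ms must be >= 0 and post_ms > 0")
    n_pre = int(np.floor(pre_ms * rec.fs / 1000.0))
    n_post = int(np.floor(post_ms * rec.fs / 1000.0))
    n_samp = rec.n_samples
    epochs, labels = [], []
    n_dropped = 0
    for onset, dataset in rec.events:
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > n_samp:
            n_dropped += 1
            continue
        epochs.append(rec.data[:, start:stop])
        labels.append(dataset)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} of {len(rec.events)} events too close to the "
            "recording edge",
            stacklevel=2,
        )
    if not epochs:
        raise ValueError("no events far enough from the recording edge to epoch")
    return EpochSet(
        data=np.stack(epochs),
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        dataset_labels=np.array(labels, dtype=object),
        t0_offset_ms=-pre_ms,
    )


def read_edf(path: str, event_datasets: list[str] | None = None) -> Recording:
    """Read continuous EEG from a European Data Format file via MNE.

    Annotations are mapped to stimulus events; ``event_datasets`` supplies
    the dataset label (A-D) per annotation in order, otherwise annotation
    descriptions must themselves be dataset labels.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    events: list[tuple[int, str]] = []
    onsets = raw.annotations.onset if raw.annotations is not None else []
    descs = raw.annotations.description if raw.annotations is not None else []
    for i, (onset, desc) in enumerate(zip(onsets, descs)):
        label = event_datasets[i] if event_datasets is not None else str(desc)
        events.append((int(round(onset * fs)), label))
    return Recording(
        data=data, fs=fs, channel_labels=list(raw.ch_names), events=events
    )
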