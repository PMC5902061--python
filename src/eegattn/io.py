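"""Plain-text epochs table format.

The format is a line-oriented, language-neutral table chosen so that a
write -> read -> write round trip is byte-identical and lossless to full
float64 precision:

    eegattn-epochs 1
    fs <float>
    channels <comma-separated labels>
    t0_offset_ms <float>
    n_samples <int>
    <trial_id> <dataset A-D> <time_index> <v_ch0_s0> <v_ch0_s1> ... (C-order)

One data row per trial; values are ``repr(float)`` so they parse back to
the exact same float64.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochSet
from .montage import DATASET_CLASS

__all__ = ["read_epochs_file", "write_epochs_file"]

_MAGIC = "eegattn-epochs 1"


def write_epochs_file(epochs: EpochSet, path) -> None:
    """Write an epoch set to the plain-text epochs table format."""
    n_samples = epochs.n_samples
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"fs {epochs.fs!r}\n")
        fh.write("channels " + ",".join(epochs.channel_labels) + "\n")
        fh.write(f"t0_offset_ms {float(epochs.t0_offset_ms)!r}\n")
        fh.write(f"n_samples {n_samples}\n")
        for t in range(epochs.n_trials):
            flat = epochs.data[t].ravel(order="C")
            fh.write(
                f"{t} {epochs.dataset_labels[t]} {int(epochs.time_index[t])} "
                + " ".join(repr(float(v)) for v in flat)
                + "\n"
            )


def read_epochs_file(path) -> EpochSet:
    """Read an epoch set from the plain-text epochs table format."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise ValueError(f"empty epochs file: {path}")
    if lines[0].strip() != _MAGIC:
        raise ValueError(f"malformed header: expected {_MAGIC!r}, got {lines[0]!r}")

    def header(i: int, key: str) -> str:
        parts = lines[i].split(maxsplit=1)
        if len(parts) != 2 or parts[0] != key:
            raise ValueError(f"malformed header line {i + 1}: expected {key!r}")
        return parts[1]

    fs = float(header(1, "fs"))
    channels = header(2, "channels").split(",")
    t0_offset_ms = float(header(3, "t0_offset_ms"))
    n_samples = int(header(4, "n_samples"))
    n_ch = len(channels)

    data, datasets, time_index = [], [], []
    for ln_no, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3 + n_ch * n_samples:
            raise ValueError(
                f"line {ln_no}: expected {3 + n_ch * n_samples} fields, got {len(parts)}"
            )
        dataset = parts[1]
        if dataset not in DATASET_CLASS:
            raise ValueError(
                f"line {ln_no}: unknown dataset label {dataset!r}; valid labels are "
                + ", ".join(sorted(DATASET_CLASS))
            )
        datasets.append(dataset)
        time_index.append(int(parts[2]))
        data.append(
            np.array(parts[3:], dtype=float).reshape(n_ch, n_samples)
        )
    if not data:
        raise ValueError(f"epochs file has a header but no trials: {path}")
    return EpochSet(
        data=np.stack(data),
        fs=fs,
        channel_labels=channels,
        dataset_labels=np.array(datasets, dtype=object),
        time_index=np.array(time_index),
        t0_offset_ms=t0_offset_ms,
    )
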