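"""In-memory containers for continuous and epoched EEG.

A :class:`Recording` holds a continuous channels x samples signal in
microvolts together with stimulus event markers labelled by dataset
(A/B/C/D).  An :class:`EpochSet` holds the trials x channels x samples
tensor cut around those events, with per-trial class (target/distractor),
task condition (1/2) and acquisition-order index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import DATASET_CLASS, DATASET_CONDITION


@dataclass
class Recording:
    """Continuous multichannel EEG with stimulus event markers.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One 10-20 label per row of ``data``.
    events
        ``(sample_index, dataset_label)`` pairs, strictly increasing sample
        indices, dataset labels in {A, B, C, D}.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        samples = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event sample index out of range")
        bad = sorted({lab for _, lab in self.events} - DATASET_CLASS.keys())
        if bad:
            raise ValueError(
                f"unknown dataset labels {bad}; valid labels are A, B, C, D"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass
class EpochSet:
    """Epoched EEG: one fixed-length window per stimulus event.

    ``class_labels`` and ``condition`` are derived from ``dataset_labels``
    (A, D -> target; B, C -> distractor; A, B -> condition 1; C, D -> 2)
    when not given explicitly. ``time_index`` records acquisition order and
    must be strictly increasing; it drives the time-separated
    cross-validation split.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    dataset_labels: np.ndarray
    class_labels: np.ndarray | None = None
    condition: np.ndarray | None = None
    time_index: np.ndarray | None = None
    t0_offset_ms: float = -200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be 3-D (trials x channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        n_trials, n_ch, _ = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel label count mismatch")
        self.dataset_labels = np.asarray(self.dataset_labels, dtype=object)
        if self.dataset_labels.shape != (n_trials,):
            raise ValueError("one dataset label per trial required")
        bad = sorted(set(self.dataset_labels) - DATASET_CLASS.keys())
        if bad:
            raise ValueError(
                f"unknown dataset labels {bad}; valid labels are A, B, C, D"
            )
        if self.class_labels is None:
            self.class_labels = np.array(
                [DATASET_CLASS[d] for d in self.dataset_labels], dtype=object
            )
        else:
            self.class_labels = np.asarray(self.class_labels, dtype=object)
        if self.condition is None:
            self.condition = np.array(
                [DATASET_CONDITION[d] for d in self.dataset_labels], dtype=int
            )
        else:
            self.condition = np.asarray(self.condition, dtype=int)
        if self.time_index is None:
            self.time_index = np.arange(n_trials)
        else:
            self.time_index = np.asarray(self.time_index, dtype=int)
        if self.time_index.shape != (n_trials,):
            raise ValueError("one time index per trial required")
        if n_trials > 1 and np.any(np.diff(self.time_index) <= 0):
            raise ValueError("time_index must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask or index array, keeping order."""
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            channel_labels=self.channel_labels,
            dataset_labels=self.dataset_labels[mask],
            class_labels=self.class_labels[mask],
            condition=self.condition[mask],
            time_index=self.time_index[mask],
            t0_offset_ms=self.t0_offset_ms,
        )
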