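"""Montage, frequency-band, and dataset-label conventions.

The default montage covers 29 scalp positions of the international 10-20
system (including every channel that the central-parietal analysis can
select); EOG channels are never part of it. Band edges follow the
conventional EEG partition and sit inside the 0.1-45 Hz analysis passband.
"""

from __future__ import annotations

#: 29 scalp channels of the 10-20 system, in montage (tie-break) order.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8",
    "T7", "C3", "CZ", "C4", "T8",
    "TP7", "CP5", "CP1", "CPZ", "CP2", "CP6", "TP8",
    "P3", "PZ", "P4", "O1", "O2",
)

#: Conventional EEG band edges in Hz, half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Datasets A/D hold attended-target trials, B/C ignored-distractor trials.
DATASET_CLASS: dict[str, str] = {
    "A": "target",
    "B": "distractor",
    "C": "distractor",
    "D": "target",
}

#: Task condition 1 compares datasets A vs B, condition 2 compares C vs D.
DATASET_CONDITION: dict[str, int] = {"A": 1, "B": 1, "C": 2, "D": 2}

#: Datasets making up each task condition, (target, distractor).
CONDITION_DATASETS: dict[int, tuple[str, str]] = {1: ("A", "B"), 2: ("C", "D")}

TARGET = "target"
DISTRACTOR = "distractor"
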