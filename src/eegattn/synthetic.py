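"""Synthetic EEG with planted target/distractor effects.

The generator emulates the statistical structure of a lateralized covert
visual attention session: 29-channel 10-20 scalp EEG at 512 Hz, 90
attended-target and 90 ignored-distractor trials per task condition,
epochs of -200..+600 ms around stimulus onset, and stimulus onsets
separated by a 117 ms stimulus plus a 225-1000 ms inter-stimulus
interval.  Trials are scheduled in short same-dataset runs (mini-blocks),
echoing the block design of such recordings.

Each channel is a sum of independent band-limited Gaussian noise
processes (delta, theta, alpha, beta, gamma) over a 1/f ("pink")
background with a white floor.  Class effects are planted as band-power
modulation: on a small set of informative central-parietal channels the
band envelope is scaled while the current trial's stimulus is the active
one, so that the target/distractor band-power ratio equals a configured
effect size — by default targets carry more delta power and distractors
more beta power, the directions observed for this task.  Effect sizes
are applied with per-channel weights so the class effect varies across
the informative channels: the channel x class interaction the downstream
repeated-measures ANOVA tests for.

Stimulus onsets can be closer together than the 800 ms epoch window, so
an epoch's edges fall under the neighbouring trials' envelopes — as they
would in a real block-design session.  Both public generators draw from
one session model: ``generate_recording`` returns the continuous timeline
with event markers, and ``generate_epochset`` returns the -200..+600 ms
windows cut around the same onsets, so epoching a generated recording
reproduces the generated epochs exactly.  Ground truth stays analytically known: every
planted effect is expressed exactly in the band-power features the
analysis measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, Recording
from .montage import BANDS, CONDITION_DATASETS, DATASET_CLASS, DEFAULT_MONTAGE

__all__ = ["SyntheticConfig", "generate_epochset", "generate_recording"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic session.

    ``effect_sizes`` maps band name to the target/distractor band-power
    ratio planted on the informative channels (>1: targets stronger).
    ``channel_effect_weights`` gives per-informative-channel exponents w
    so the ratio realized at channel c is ``ratio ** w_c``; unequal
    weights create the channel-by-class interaction the rANOVA stage
    tests.  ``band_amplitudes_uv`` are baseline RMS amplitudes of the
    band-limited noise processes in microvolts (the class-geometric mean
    on informative channels).
    """

    n_channels: int = 29
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE
    fs: float = 512.0
    n_trials_per_dataset: int = 90
    epoch_pre_ms: float = 200.0
    epoch_post_ms: float = 600.0
    epoch_length_ms: float | None = None  # defaults to pre + post (800 ms)
    informative_channels: tuple[str, ...] = ("CP1", "CP2", "PZ", "P3", "P4")
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"delta": 2.5, "beta": 0.5}
    )
    channel_effect_weights: dict[str, float] = field(
        default_factory=lambda: {
            "CP1": 1.0, "CP2": 0.35, "PZ": 0.85, "P3": 0.25, "P4": 0.7
        }
    )
    band_edges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    band_amplitudes_uv: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 12.0, "theta": 4.0, "alpha": 6.0, "beta": 6.0, "gamma": 2.0
        }
    )
    noise_std_uv: float = 4.0
    pink_exponent: float = 1.0
    pink_floor_hz: float = 1.0  # flatten the 1/f curve below this frequency
    white_noise_std_uv: float = 1.0
    stimulus_ms: float = 117.0
    isi_range_ms: tuple[float, float] = (225.0, 1000.0)
    block_length: int = 10  # consecutive same-dataset trials per mini-block
    amplitude_drift: float = 0.0  # relative band-amplitude change over the session
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.informative_channels = tuple(self.informative_channels)
        if self.n_channels != len(self.channel_labels):
            raise ValueError(
                f"n_channels={self.n_channels} but {len(self.channel_labels)} labels"
            )
        if self.fs <= 0 or self.n_trials_per_dataset < 1:
            raise ValueError("fs and n_trials_per_dataset must be positive")
        if self.epoch_length_ms is None:
            self.epoch_length_ms = self.epoch_pre_ms + self.epoch_post_ms
        if self.epoch_length_ms != self.epoch_pre_ms + self.epoch_post_ms:
            raise ValueError("epoch_pre_ms + epoch_post_ms must equal epoch_length_ms")
        missing = set(self.informative_channels) - set(self.channel_labels)
        if missing:
            raise ValueError(f"informative channels not in montage: {sorted(missing)}")
        for band, ratio in self.effect_sizes.items():
            if band not in self.band_edges:
                raise ValueError(f"effect size for unknown band {band!r}")
            if ratio <= 0:
                raise ValueError(f"effect ratio for {band} must be > 0, got {ratio}")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        lo, hi = self.isi_range_ms
        if not 0 < lo <= hi:
            raise ValueError("invalid inter-stimulus interval range")

    @property
    def n_pre_samples(self) -> int:
        return int(np.floor(self.epoch_pre_ms * self.fs / 1000.0))

    @property
    def n_post_samples(self) -> int:
        return int(np.floor(self.epoch_post_ms * self.fs / 1000.0))

    @property
    def n_epoch_samples(self) -> int:
        return self.n_pre_samples + self.n_post_samples


def _spectral_noise(
    rng: np.random.Generator, shape: tuple, gain: np.ndarray, n: int
) -> np.ndarray:
    """Unit-variance noise with the given rfft gain profile along the last
    axis (normalized by the gain's two-sided energy)."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    w = np.full(gain.shape, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    energy = float(np.sum(w * gain**2))
    if energy <= 0:
        return np.zeros(shape)
    norm = np.sqrt(energy / n)
    return np.fft.irfft(spec * gain, n=n, axis=-1) / norm


def _background_noise(
    rng: np.random.Generator, shape: tuple, cfg: SyntheticConfig
) -> np.ndarray:
    """Pink (1/f^exponent) background of std ``noise_std_uv`` plus a white
    floor; zero DC gain."""
    n = shape[-1]
    f = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    gain = np.maximum(f, cfg.pink_floor_hz) ** (-cfg.pink_exponent / 2.0)
    gain[0] = 0.0
    out = cfg.noise_std_uv * _spectral_noise(rng, shape, gain, n)
    if cfg.white_noise_std_uv > 0:
        out += cfg.white_noise_std_uv * rng.standard_normal(shape)
    return out


def _band_noise(
    rng: np.random.Generator, shape: tuple, band: tuple[float, float], cfg: SyntheticConfig
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi)."""
    n = shape[-1]
    f = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    gain = ((f >= band[0]) & (f < band[1])).astype(float)
    return _spectral_noise(rng, shape, gain, n)


class _Session:
    """One drawn session: block-scheduled trial sequence, inter-onset gaps,
    and per-(band, trial, channel) envelope factors (drift applied)."""

    def __init__(self, rng: np.random.Generator, cfg: SyntheticConfig, condition: int):
        if condition not in CONDITION_DATASETS:
            raise ValueError(f"condition must be 1 or 2, got {condition!r}")
        self.cfg = cfg
        target_ds, distractor_ds = CONDITION_DATASETS[condition]
        blocks: list[list[str]] = []
        for ds in (target_ds, distractor_ds):
            n = cfg.n_trials_per_dataset
            blocks += [
                [ds] * min(cfg.block_length, n - i)
                for i in range(0, n, cfg.block_length)
            ]
        order = rng.permutation(len(blocks))
        self.datasets = np.array(
            [ds for b in order for ds in blocks[b]], dtype=object
        )
        self.n_trials = len(self.datasets)
        self.is_target = np.array(
            [DATASET_CLASS[d] == "target" for d in self.datasets]
        )
        gaps_ms = cfg.stimulus_ms + rng.uniform(
            *cfg.isi_range_ms, size=self.n_trials - 1
        )
        self.gaps = np.round(gaps_ms * cfg.fs / 1000.0).astype(int)

        drift = np.ones(self.n_trials)
        if cfg.amplitude_drift != 0.0 and self.n_trials > 1:
            drift += cfg.amplitude_drift * (
                np.arange(self.n_trials) / (self.n_trials - 1) - 0.5
            )
        # factors[band][i, c]: amplitude envelope while trial i is active
        self.factors: dict[str, np.ndarray] = {}
        for band in cfg.band_edges:
            fac = np.ones((self.n_trials, cfg.n_channels))
            ratio = cfg.effect_sizes.get(band, 1.0)
            if ratio != 1.0:
                for ch in cfg.informative_channels:
                    w = cfg.channel_effect_weights.get(ch, 1.0)
                    j = cfg.channel_labels.index(ch)
                    factor = ratio ** (w / 4.0)
                    fac[:, j] = np.where(self.is_target, factor, 1.0 / factor)
            self.factors[band] = fac * drift[:, None]


def _generate_session(
    config: SyntheticConfig, condition: int, duration_s: float | None = None
) -> Recording:
    """Draw one session and synthesize its continuous signal."""
    rng = np.random.default_rng([config.seed, condition])
    ses = _Session(rng, config, condition)
    onsets = (
        config.n_pre_samples
        + int(round(0.5 * config.fs))
        + np.concatenate([[0], np.cumsum(ses.gaps)])
    )
    n_needed = int(onsets[-1] + config.n_post_samples + round(0.5 * config.fs))
    if duration_s is not None:
        n_total = int(round(duration_s * config.fs))
        if n_total < n_needed:
            raise ValueError(
                f"duration {duration_s} s too short for {ses.n_trials} events "
                f"(needs >= {n_needed / config.fs:.1f} s)"
            )
    else:
        n_total = n_needed
    data = _background_noise(rng, (config.n_channels, n_total), config)
    bounds = np.concatenate([[0], onsets[1:], [n_total]])
    for band, edges in config.band_edges.items():
        amp = config.band_amplitudes_uv.get(band, 0.0)
        if amp <= 0:
            continue
        bn = _band_noise(rng, (config.n_channels, n_total), edges, config)
        fac = ses.factors[band]
        for i in range(ses.n_trials):
            bn[:, bounds[i] : bounds[i + 1]] *= fac[i][:, None]
        data += amp * bn
    events = [(int(s), str(d)) for s, d in zip(onsets, ses.datasets)]
    return Recording(
        data=data, fs=config.fs, channel_labels=list(config.channel_labels), events=events
    )


def generate_recording(
    config: SyntheticConfig, condition: int = 1, duration_s: float | None = None
) -> Recording:
    """Generate a continuous recording with stimulus event markers.

    Consecutive onsets are separated by the stimulus duration plus an
    inter-stimulus interval drawn uniformly from ``isi_range_ms``; each
    event carries its dataset label.  Band envelopes switch to each
    trial's class factor at its onset.  Identical config and seed give
    bit-identical output.
    """
    return _generate_session(config, condition, duration_s)


def generate_epochset(config: SyntheticConfig, condition: int = 1) -> EpochSet:
    """Generate the labelled epochs of one task condition.

    Returns ``2 * n_trials_per_dataset`` epochs (``time_index`` = trial
    order), each ``n_channels x n_epoch_samples``, cut from the same
    continuous session model :func:`generate_recording` produces for this
    config and seed — so epoching a generated recording with
    :func:`eegattn.preprocessing.epoch_signal` reproduces these epochs
    exactly.  Within an epoch, the band envelopes follow the previous
    trial's class before stimulus onset and switch to the next trial's at
    its onset, as they do on the continuous timeline.  Identical config
    and seed give bit-identical output.
    """
    rec = _generate_session(config, condition)
    n_pre, n_post = config.n_pre_samples, config.n_post_samples
    data = np.stack(
        [rec.data[:, s - n_pre : s + n_post] for s, _ in rec.events]
    )
    return EpochSet(
        data=data,
        fs=config.fs,
        channel_labels=list(config.channel_labels),
        dataset_labels=np.array([d for _, d in rec.events], dtype=object),
        t0_offset_ms=-config.epoch_pre_ms,
    )
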