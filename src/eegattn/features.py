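"""Per-epoch, per-channel EEG features and feature-matrix assembly.

Eight features are used in the target/distractor analysis: Hjorth
complexity and mobility, average (zero-crossing) frequency, Lempel-Ziv
(LZ76) complexity of the binarized signal, delta and beta band power, and
the median power (50%) and spectral edge (95%) frequencies of the
periodogram.  ``build_feature_matrix`` evaluates one feature over an
:class:`~eegattn.containers.EpochSet`, yielding the observations x
channels data matrix C_d (180 x 29 for a standard two-dataset condition)
that channel selection and the repeated-measures ANOVA operate on.

Conventions: derivatives are first differences scaled by the sampling
rate; standard deviations use the unbiased (n-1) denominator; the
periodogram is the raw squared DFT magnitude folded to one side, with no
taper, so that the one-sided powers sum to n * sum(x**2); the DC bin is
excluded from the median-power/spectral-edge cumulative sums (after
high-pass filtering and average referencing it is numerical residue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .montage import BANDS

__all__ = [
    "FeatureMatrix",
    "FeatureError",
    "hjorth_mobility",
    "hjorth_complexity",
    "average_frequency",
    "lz76_phrase_count",
    "lz_complexity",
    "power_spectrum",
    "band_power",
    "median_power_frequency",
    "spectral_edge_frequency",
    "build_feature_matrix",
    "FEATURE_NAMES",
]

#: The eight analysis features, in reporting order.
FEATURE_NAMES: tuple[str, ...] = (
    "average_frequency",
    "lz_complexity",
    "hjorth_complexity",
    "hjorth_mobility",
    "median_power_frequency",
    "spectral_edge_frequency",
    "delta_power",
    "beta_power",
)


class FeatureError(ValueError):
    """A feature could not be computed; carries trial/channel coordinates
    when raised from :func:`build_feature_matrix`."""


def _std(x: np.ndarray, axis=-1) -> np.ndarray:
    return np.std(x, axis=axis, ddof=1)


def _is_degenerate(std: np.ndarray, x: np.ndarray) -> bool:
    # constant signals leave float dust in the std; compare to the scale
    tol = 1e-10 * (np.abs(x).max(axis=-1) + 1e-300)
    return bool(np.any(std <= tol))


def hjorth_mobility(x: np.ndarray, fs: float = 1.0) -> float:
    """Hjorth mobility std(dX/dt)/std(X): a measure of mean frequency.

    With the ``fs`` scaling of the first-difference derivative the value is
    in rad/s (a pure sinusoid of frequency f gives ~2*pi*f); with fs=1 it
    is the dimensionless per-sample variant.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise FeatureError("mobility needs at least 3 samples")
    sx = _std(x)
    if _is_degenerate(sx, x):
        raise FeatureError("mobility undefined for a constant signal")
    dx = np.diff(x, axis=-1) * fs
    out = _std(dx) / sx
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def hjorth_complexity(x: np.ndarray, fs: float = 1.0) -> float:
    """Hjorth complexity std(d2X/dt2)*std(X)/std(dX/dt)**2.

    Equals mobility(dX/dt)/mobility(X): the spread of the spectrum.
    Dimensionless -- the fs scaling cancels -- with minimum ~1 attained by
    a pure sinusoid; broadband signals exceed 1.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 4:
        raise FeatureError("complexity needs at least 4 samples")
    sx = _std(x)
    dx = np.diff(x, axis=-1)
    sdx = _std(dx)
    if _is_degenerate(sx, x) or _is_degenerate(sdx, x):
        raise FeatureError("complexity undefined: zero variance in signal or derivative")
    sddx = _std(np.diff(dx, axis=-1))
    out = sddx * sx / sdx**2
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def average_frequency(x: np.ndarray, duration_s: float) -> float:
    """Zero crossings per second.

    A sample exactly at zero inherits the previous nonzero sign (leading
    zeros inherit the first nonzero sign), so a touch of zero is never
    counted twice.
    """
    if duration_s <= 0:
        raise FeatureError("duration must be positive")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise FeatureError("need at least 2 samples")
    s = np.sign(x)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return 0.0
    # forward-fill signs over exact zeros; backfill any leading zeros
    idx = np.maximum.accumulate(np.where(s != 0, np.arange(s.size), -1))
    idx[idx < 0] = nz[0]
    filled = s[idx]
    crossings = int(np.sum(filled[1:] != filled[:-1]))
    return crossings / duration_s


def lz76_phrase_count(bits) -> int:
    """Number of phrases in the Lempel-Ziv 1976 exhaustive-history parse.

    Scans the binary sequence left to right; each phrase is the shortest
    new extension not reproducible from the prior history (a trailing
    still-reproducible fragment counts as a final phrase). Implemented with
    the Kaspar-Schuster pointer recursion.
    """
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    if n == 0:
        raise FeatureError("empty sequence")
    c, m = 0, 0
    while m < n:
        # longest L with s[m:m+L] reproducible, i.e. occurring in s[:m+L-1];
        # reproducibility is monotone in L, so binary-search it
        lo, hi = 0, n - m
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if s[m : m + mid] in s[: m + mid - 1]:
                lo = mid
            else:
                hi = mid - 1
        c += 1
        m += min(lo + 1, n - m)  # shortest new extension (or trailing fragment)
    return c

def lz_complexity(
    x: np.ndarray,
    threshold_rule: str = "median",
    normalization: str = "n",
) -> float:
    """LZ76 complexity of the binarized signal.

    The signal is binarized by its median (default) or mean -- samples
    strictly above the threshold map to 1 -- and parsed by the LZ76
    exhaustive-history procedure. ``normalization="n"`` returns the phrase
    count c divided by the sequence length (the s(n)/n convention used
    here); ``"log"`` returns the asymptotic c*log2(n)/n variant.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise FeatureError("need at least 2 samples")
    if threshold_rule == "median":
        thr = float(np.median(x))
    elif threshold_rule == "mean":
        thr = float(np.mean(x))
    else:
        raise FeatureError(f"unknown threshold rule {threshold_rule!r}")
    c = lz76_phrase_count(x > thr)
    n = x.size
    if normalization == "n":
        return c / n
    if normalization == "log":
        return c * np.log2(n) / n
    raise FeatureError(f"unknown normalization {normalization!r}")


def power_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram X_fft * conj(X_fft), folded to [0, fs/2].

    No taper; powers are normalized so they sum to n * sum(x**2)
    (the raw squared-DFT convention). Frequency grid is k*fs/n. Works on
    the last axis of a stacked array.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise FeatureError("need at least 2 samples")
    spec = np.fft.rfft(x, axis=-1)
    p = (spec * np.conj(spec)).real
    # fold: every bin except DC (and Nyquist for even n) represents two bins
    if n % 2 == 0:
        p[..., 1:-1] *= 2.0
    else:
        p[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, p


def band_power(freqs: np.ndarray, powers: np.ndarray, band: tuple[float, float]) -> float:
    """Sum of periodogram power with frequency in the half-open [lo, hi)."""
    lo, hi = band
    if not lo < hi:
        raise FeatureError(f"inverted band ({lo}, {hi})")
    mask = (freqs >= lo) & (freqs < hi)
    out = powers[..., mask].sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def _cumulative_frequency(freqs, powers, fraction):
    cum = np.cumsum(powers[..., 1:], axis=-1)  # DC bin excluded
    total = np.asarray(cum[..., -1])
    if np.any(total <= 0):
        raise FeatureError("zero total power")
    target = fraction * total
    # first index where the cumulative sum reaches the target fraction;
    # the tiny slack keeps exact ties (e.g. two equal lines) at the lower bin
    reached = cum >= (target - 1e-9 * total)[..., None]
    idx = reached.argmax(axis=-1)
    out = freqs[1:][idx]
    return float(out) if np.ndim(out) == 0 else out


def median_power_frequency(freqs: np.ndarray, powers: np.ndarray) -> float:
    """Smallest grid frequency at which cumulative power reaches 50% of the
    total (DC excluded)."""
    return _cumulative_frequency(freqs, powers, 0.5)


def spectral_edge_frequency(
    freqs: np.ndarray, powers: np.ndarray, fraction: float = 0.95
) -> float:
    """Smallest grid frequency at which cumulative power reaches ``fraction``
    (default 95%) of the total (DC excluded)."""
    if not 0 < fraction <= 1:
        raise FeatureError("fraction must lie in (0, 1]")
    return _cumulative_frequency(freqs, powers, fraction)


@dataclass
class FeatureMatrix:
    """One feature evaluated over all (trial, channel) pairs: the data
    matrix C_d with observations as rows and channels as columns."""

    feature_name: str
    values: np.ndarray
    channel_labels: list[str]
    class_labels: np.ndarray
    condition: np.ndarray
    time_index: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if len(self.channel_labels) != n or len(self.class_labels) != m:
            raise ValueError("label shapes inconsistent with values")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.channel_labels))
        df.insert(0, "time_index", self.time_index)
        df.insert(0, "condition", self.condition)
        df.insert(0, "class", self.class_labels)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_name: str) -> "FeatureMatrix":
        meta = ["class", "condition", "time_index"]
        channels = [c for c in df.columns if c not in meta]
        return cls(
            feature_name=feature_name,
            values=df[channels].to_numpy(float),
            channel_labels=channels,
            class_labels=df["class"].to_numpy(object),
            condition=df["condition"].to_numpy(int),
            time_index=df["time_index"].to_numpy(int),
        )


def _resolve_feature(name: str, params: dict):
    """Return a callable epoch_2d (channels x samples), fs -> vector of
    per-channel values for the named feature."""
    band_names = dict(BANDS)
    band_names.update(params.get("band_edges", {}))

    if name == "hjorth_mobility":
        return lambda ep, fs: hjorth_mobility(ep, fs)
    if name == "hjorth_complexity":
        return lambda ep, fs: hjorth_complexity(ep, fs)
    if name == "average_frequency":
        return lambda ep, fs: np.array(
            [average_frequency(ch, ch.size / fs) for ch in ep]
        )
    if name == "lz_complexity":
        rule = params.get("threshold_rule", "median")
        norm = params.get("normalization", "n")
        return lambda ep, fs: np.array(
            [lz_complexity(ch, rule, norm) for ch in ep]
        )
    if name == "median_power_frequency":
        def _mpf(ep, fs):
            freqs, p = power_spectrum(ep, fs)
            return median_power_frequency(freqs, p)
        return _mpf
    if name == "spectral_edge_frequency":
        frac = params.get("fraction", 0.95)
        def _sef(ep, fs):
            freqs, p = power_spectrum(ep, fs)
            return spectral_edge_frequency(freqs, p, frac)
        return _sef
    if name == "band_power":
        band = params["band"]
        if isinstance(band, str):
            band = band_names[band]
    elif name.endswith("_power") and name[:-6] in band_names:
        band = band_names[name[:-6]]
    else:
        raise FeatureError(f"unknown feature {name!r}")

    def _bp(ep, fs):
        freqs, p = power_spectrum(ep, fs)
        return band_power(freqs, p, band)
    return _bp


def build_feature_matrix(
    epochs: EpochSet, feature_name: str, **params
) -> FeatureMatrix:
    """Evaluate one feature per (trial, channel) over an epoch set.

    Rows follow acquisition order (``time_index``); class and condition
    labels are carried through. A failing feature evaluation is re-raised
    with the offending trial and channel named.
    """
    if epochs.n_trials == 0:
        raise FeatureError("empty epoch set")
    func = _resolve_feature(feature_name, params)
    order = np.argsort(epochs.time_index)
    ep = epochs.select_trials(order)
    values = np.empty((ep.n_trials, ep.n_channels))
    for t in range(ep.n_trials):
        try:
            values[t] = func(ep.data[t], ep.fs)
        except FeatureError:
            # locate the offending channel for the error message
            for j in range(ep.n_channels):
                try:
                    func(ep.data[t, j : j + 1], ep.fs)
                except FeatureError as exc:
                    raise FeatureError(
                        f"{feature_name} failed at trial {int(ep.time_index[t])}, "
                        f"channel {ep.channel_labels[j]}: {exc}"
                    ) from exc
            raise
    return FeatureMatrix(
        feature_name=feature_name,
        values=values,
        channel_labels=list(ep.channel_labels),
        class_labels=ep.class_labels.copy(),
        condition=ep.condition.copy(),
        time_index=ep.time_index.copy(),
    )
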