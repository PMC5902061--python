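"""Stepwise discriminant analysis: Wilks-lambda channel ranking.

For one feature's observations x channels data matrix with two class
labels, channels are entered greedily: at each step the candidate that
minimizes the two-group MANOVA Wilks' lambda of the already-entered set
plus the candidate is added, until a fixed number of channels (three by
default) has been entered.  Wilks' lambda is det(W)/det(T), the ratio of
the pooled within-group to the total scatter determinant; smaller values
mean stronger separation, and adding a variable can never increase it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = ["SelectionResult", "wilks_lambda", "stepwise_select", "DegenerateScatterError"]


class DegenerateScatterError(ValueError):
    """Scatter matrix singular (e.g. collinear channels)."""


def _scatter_matrices(values: np.ndarray, groups: np.ndarray):
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"exactly 2 group levels required, got {levels.size}")
    grand = x.mean(axis=0)
    xc = x - grand
    total = xc.T @ xc
    within = np.zeros_like(total)
    for lev in levels:
        sub = x[g == lev]
        if sub.shape[0] < 2:
            raise ValueError("each group needs at least 2 observations")
        d = sub - sub.mean(axis=0)
        within += d.T @ d
    return within, total


def wilks_lambda(values: np.ndarray, groups: np.ndarray) -> float:
    """Two-group MANOVA Wilks' lambda det(W)/det(T) in (0, 1].

    ``values`` is observations x p (or a vector for p = 1); ``groups`` a
    two-level label vector. Raises :class:`DegenerateScatterError` when the
    total scatter is singular (collinear or constant channels).
    """
    within, total = _scatter_matrices(values, groups)
    det_t = np.linalg.det(total)
    scale = np.trace(total) / max(total.shape[0], 1)
    if not np.isfinite(det_t) or det_t <= (1e-12 * max(scale, 1.0)) ** total.shape[0]:
        raise DegenerateScatterError("total scatter matrix is (near-)singular")
    det_w = np.linalg.det(within)
    lam = det_w / det_t
    return float(min(max(lam, 0.0), 1.0))


@dataclass
class SelectionResult:
    """Channels ordered by discriminating power with the Wilks-lambda trace."""

    feature_name: str
    ordered_channels: list[str]
    lambda_trace: list[float]
    f_to_enter: list[float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_name,
                "rank": np.arange(1, len(self.ordered_channels) + 1),
                "channel": self.ordered_channels,
                "wilks_lambda": self.lambda_trace,
                "F_to_enter": self.f_to_enter,
            }
        )


def stepwise_select(fm: FeatureMatrix, n_select: int = 3) -> SelectionResult:
    """Forward stepwise channel selection by Wilks' lambda.

    At each step every not-yet-entered channel is scored by the Wilks'
    lambda of the entered set plus that channel; the minimizer is entered
    (exact ties broken by montage order, i.e. lower column index). The
    partial F-to-enter at each step is
    ``((N - g - p) / (g - 1)) * (lambda_prev / lambda_new - 1)`` with p the
    number of channels entered before the step. Candidates whose addition
    makes the scatter singular are skipped with a warning.
    """
    n_channels = len(fm.channel_labels)
    if not 1 <= n_select <= n_channels:
        raise ValueError(f"n_select must be in [1, {n_channels}]")
    groups = fm.class_labels
    n_obs = fm.n_observations
    g = 2
    selected: list[int] = []
    trace: list[float] = []
    f_enter: list[float] = []
    lam_prev = 1.0
    while len(selected) < n_select:
        best_lam, best_j = None, None
        for j in range(n_channels):
            if j in selected:
                continue
            cols = selected + [j]
            try:
                lam = wilks_lambda(fm.values[:, cols], groups)
            except DegenerateScatterError:
                warnings.warn(
                    f"channel {fm.channel_labels[j]} skipped: singular scatter "
                    f"with {[fm.channel_labels[i] for i in selected]}",
                    stacklevel=2,
                )
                continue
            if best_lam is None or lam < best_lam:
                best_lam, best_j = lam, j
        if best_j is None:
            raise DegenerateScatterError(
                "no admissible channel left before reaching n_select"
            )
        p = len(selected)
        df2 = n_obs - g - p
        f_enter.append(
            float((df2 / (g - 1)) * (lam_prev / best_lam - 1.0)) if best_lam > 0
            else float("inf")
        )
        selected.append(best_j)
        trace.append(best_lam)
        lam_prev = best_lam
    return SelectionResult(
        feature_name=fm.feature_name,
        ordered_channels=[fm.channel_labels[j] for j in selected],
        lambda_trace=trace,
        f_to_enter=f_enter,
    )
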