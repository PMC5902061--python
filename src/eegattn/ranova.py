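"""Mixed-design (split-plot) repeated-measures ANOVA with sphericity
corrections.

The design has one between-observations grouping factor (target vs
distractor class, g = 2 levels) and one within-observations repeated
factor (the k = 3 selected channel-feature values measured on every
observation).  The tested effect is the channel-feature x class
interaction, F = MS_interaction / MS_within_error with
df_fc = (k-1)(g-1) and df_error = (N-g)(k-1) -- for k = 3 channels and
N = 180 observations this is F(2, 356), the bookkeeping used in the
reported analyses.

Because the k repeated measures are correlated, the uncorrected p-value is
anti-conservative when sphericity (equal variances of all pairwise level
differences) fails.  Three epsilon corrections deflate both degrees of
freedom: Greenhouse-Geisser (from the pooled within-group covariance),
Huynh-Feldt (a less biased rescaling of GG, clamped at 1), and the lower
bound 1/(k-1) (the worst case; the correction the reported analyses
quote).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .selection import SelectionResult

__all__ = ["RanovaResult", "mixed_anova_interaction", "run_ranova_battery"]


@dataclass
class RanovaResult:
    """Interaction test of a split-plot rANOVA with epsilon corrections."""

    F: float
    df_fc: int
    df_error: int
    p_uncorrected: float
    epsilon_gg: float
    epsilon_hf: float
    epsilon_lb: float
    p_gg: float
    p_hf: float
    p_lb: float
    ss_table: pd.DataFrame = field(repr=False, default=None)

    def corrected_p(self, correction: str = "lb") -> float:
        return {"none": self.p_uncorrected, "gg": self.p_gg,
                "hf": self.p_hf, "lb": self.p_lb}[correction]

    def format_report(self, correction: str = "lb") -> str:
        """The conventional 'F(df1,df2) = x, p = y' report string."""
        return (
            f"F({self.df_fc},{self.df_error}) = {self.F:.4g}, "
            f"p = {self.corrected_p(correction):.4g}"
        )


def _gg_epsilon(pooled_cov: np.ndarray) -> float:
    """Box/Greenhouse-Geisser epsilon from a k x k covariance matrix."""
    k = pooled_cov.shape[0]
    c = np.eye(k) - np.full((k, k), 1.0 / k)
    s = c @ pooled_cov @ c
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0 or tr <= 0:
        raise ValueError("degenerate covariance: repeated measures are collinear")
    return float(tr**2 / ((k - 1) * tr2))


def mixed_anova_interaction(
    measures: np.ndarray, groups: np.ndarray
) -> RanovaResult:
    """Split-plot ANOVA interaction test for an N x k measures table.

    ``measures[i, l]`` is observation i at within-factor level l;
    ``groups`` is the two-level between factor. Returns the interaction F,
    its degrees of freedom, and uncorrected plus GG/HF/lower-bound
    corrected p-values.
    """
    x = np.asarray(measures, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("measures must be N x k with k >= 2")
    n_total, k = x.shape
    grp = np.asarray(groups)
    levels = np.unique(grp)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    n_g = {lev: int(np.sum(grp == lev)) for lev in levels}
    if min(n_g.values()) < 2:
        raise ValueError("each group needs at least 2 observations")
    g = 2

    grand = x.mean()
    subj_means = x.mean(axis=1)
    level_means = x.mean(axis=0)
    ss_between_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_group = k * sum(
        n_g[lev] * (x[grp == lev].mean() - grand) ** 2 for lev in levels
    )
    ss_subj_within = ss_between_subj - ss_group

    ss_within_total = float(np.sum((x - subj_means[:, None]) ** 2))
    ss_level = n_total * float(np.sum((level_means - grand) ** 2))
    ss_interaction = 0.0
    for lev in levels:
        cell = x[grp == lev].mean(axis=0)  # per-level means within group
        gmean = x[grp == lev].mean()
        ss_interaction += n_g[lev] * float(
            np.sum((cell - gmean - level_means + grand) ** 2)
        )
    ss_error = ss_within_total - ss_level - ss_interaction

    df_fc = (k - 1) * (g - 1)
    df_error = (n_total - g) * (k - 1)
    ms_interaction = ss_interaction / df_fc
    ms_error = ss_error / df_error
    # relative threshold: identical repeated measures leave only float dust
    ss_total = float(np.sum((x - grand) ** 2))
    if ss_error <= 1e-12 * max(ss_total, 1e-300):
        raise ValueError("degenerate covariance: zero within-error variance")
    f_val = ms_interaction / ms_error
    p_unc = float(stats.f.sf(f_val, df_fc, df_error))

    # pooled within-group covariance of the k measures
    pooled = np.zeros((k, k))
    for lev in levels:
        sub = x[grp == lev]
        pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
    pooled /= n_total - g

    eps_gg = _gg_epsilon(pooled)
    n_w = n_total - g
    num = n_w * (k - 1) * eps_gg - 2.0
    den = (k - 1) * (n_w - 1 - (k - 1) * eps_gg)
    eps_hf = float(min(1.0, num / den)) if den > 0 else 1.0
    eps_lb = 1.0 / (k - 1)

    def p_at(eps: float) -> float:
        return float(stats.f.sf(f_val, eps * df_fc, eps * df_error))

    ss_table = pd.DataFrame(
        {
            "source": ["group", "subjects_within_group", "level",
                       "level_x_group", "within_error"],
            "ss": [ss_group, ss_subj_within, ss_level, ss_interaction, ss_error],
            "df": [g - 1, n_total - g, k - 1, df_fc, df_error],
        }
    )
    return RanovaResult(
        F=float(f_val),
        df_fc=df_fc,
        df_error=df_error,
        p_uncorrected=p_unc,
        epsilon_gg=eps_gg,
        epsilon_hf=eps_hf,
        epsilon_lb=eps_lb,
        p_gg=p_at(eps_gg),
        p_hf=p_at(eps_hf),
        p_lb=p_at(eps_lb),
        ss_table=ss_table,
    )


def run_ranova_battery(selected: SelectionResult, fm: FeatureMatrix) -> RanovaResult:
    """Interaction test on the selected channels of one feature matrix.

    Restricts the matrix to the selected channels (within factor, in
    selection order) with class as the grouping factor.
    """
    missing = [c for c in selected.ordered_channels if c not in fm.channel_labels]
    if missing:
        raise ValueError(f"selected channels missing from feature matrix: {missing}")
    cols = [fm.channel_labels.index(c) for c in selected.ordered_channels]
    return mixed_anova_interaction(fm.values[:, cols], fm.class_labels)
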