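"""Shared fixtures: session-scoped synthetic datasets to avoid regenerating
the default 180-trial condition in every test module."""

import numpy as np
import pytest

import eegattn as ea

PLANTED = {"CP1", "CP2", "PZ", "P3", "P4"}


@pytest.fixture(scope="session")
def default_config():
    return ea.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def epochs_c1(default_config):
    """Default planted-effect epochs, task condition 1, seed 0."""
    return ea.generate_epochset(default_config, 1)


@pytest.fixture(scope="session")
def delta_fm(epochs_c1):
    return ea.build_feature_matrix(epochs_c1, "delta_power")


@pytest.fixture(scope="session")
def null_epochs():
    """Label-exchangeable epochs: every effect ratio is 1."""
    cfg = ea.SyntheticConfig(seed=0, effect_sizes={"delta": 1.0, "beta": 1.0})
    return ea.generate_epochset(cfg, 1)


@pytest.fixture(scope="session")
def small_recording():
    """A short continuous recording (24 trials) for preprocessing tests."""
    cfg = ea.SyntheticConfig(seed=3, n_trials_per_dataset=12)
    return ea.generate_recording(cfg, 1)


@pytest.fixture(scope="session")
def parietal_recovery_hits():
    """Over 20 seeds: how often the 3 stepwise-selected delta-power
    channels fall inside the planted central-parietal set (condition 1,
    default generator)."""
    hits = 0
    for seed in range(20):
        ep = ea.generate_epochset(ea.SyntheticConfig(seed=seed), 1)
        fm = ea.build_feature_matrix(ep, "delta_power")
        sel = ea.stepwise_select(fm, n_select=3)
        hits += set(sel.ordered_channels) <= PLANTED
    return hits


def gaussian_feature_matrix(rng, n_per_class=90, n_channels=29, shift=0.0,
                            shifted_channel=0, labels=None):
    """Feature matrix of i.i.d. standard normals with an optional mean shift
    (Cohen's d = shift) planted on one channel for the target class."""
    if labels is None:
        labels = [f"CH{i:02d}" for i in range(n_channels)]
    values = rng.standard_normal((2 * n_per_class, n_channels))
    values[:n_per_class, shifted_channel] += shift
    classes = np.array(["target"] * n_per_class + ["distractor"] * n_per_class,
                       dtype=object)
    perm = rng.permutation(2 * n_per_class)
    return ea.FeatureMatrix(
        feature_name="test",
        values=values[perm],
        channel_labels=labels,
        class_labels=classes[perm],
        condition=np.ones(2 * n_per_class, dtype=int),
        time_index=np.arange(2 * n_per_class),
    )
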