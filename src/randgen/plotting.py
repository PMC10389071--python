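"""Convenience plots: step/digit profiles, windowed trajectories, recurrence plots."""

from __future__ import annotations

import numpy as np

from .metrics import DIGITS, FOD_DIFFS, first_order_differences, response_frequencies
from .rqa import recurrence_matrix


def plot_group_profiles(cohort, ax_pair=None):
    """Group-mean relative first-order-difference and digit-frequency profiles."""
    import matplotlib.pyplot as plt

    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(10, 4))
    ax_fod, ax_rf = ax_pair
    for group, style in (("ASD", "-o"), ("CTRL", "--s")):
        sequences = cohort.subset(group)
        if not sequences:
            continue
        r_fod = np.mean([first_order_differences(s.responses)[1] for s in sequences], axis=0)
        r_rf = np.mean([response_frequencies(s.responses)[1] for s in sequences], axis=0)
        ax_fod.plot(FOD_DIFFS, r_fod, style, label=group)
        ax_rf.plot(DIGITS, r_rf, style, label=group)
    ax_fod.set_xlabel("first-order difference")
    ax_fod.set_ylabel("relative frequency")
    ax_rf.set_xlabel("digit")
    ax_rf.set_ylabel("relative frequency")
    ax_fod.legend()
    return ax_pair


def plot_trajectory_contrast(contrast, metric: str = "", ax=None):
    """Per-window group means from :func:`randgen.group_trajectory_contrast`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = contrast.index if contrast.index.name == "window" else contrast["window"]
    ax.plot(x, contrast["mean_ASD"], color="0.2", label="ASD")
    ax.plot(x, contrast["mean_CTRL"], color="0.7", label="CTRL")
    ax.set_xlabel("window ordinal")
    ax.set_ylabel(metric or "metric")
    ax.legend()
    return ax


def plot_recurrence(seq, ax=None):
    """Recurrence plot of one digit sequence (main diagonal shown)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    mat = recurrence_matrix(seq)
    ax.imshow(mat, cmap="Greys", origin="lower", interpolation="none")
    ax.set_xlabel("position")
    ax.set_ylabel("position")
    return ax
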