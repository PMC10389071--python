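"""Moving-window trajectories of the randomness metrics.

The study's 20-second window on a ~60-second task is mapped to item counts
as a fraction of sequence length (default 1/3), because per-item timestamps
were not retained and pacing was about one item per second. Windows overlap
maximally by default (step of one item). Trajectories from different
participants are aligned by window ordinal (first window, second window,
...), since sequence lengths differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ResponseSequence
from .metrics import PROFILE_COLUMNS, metrics_profile


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry.

    fraction
        Window length as a proportion of the sequence length (default 1/3,
        the 20 s / 60 s of the task design).
    step
        Window advance in items (default 1: maximal overlap).
    min_window
        Smallest admissible window in items; short sequences fall back to
        this so per-window metrics stay defined.
    """

    fraction: float = 1.0 / 3.0
    step: int = 1
    min_window: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.min_window < 3:
            raise ValueError("min_window must be >= 3 (full profiles need n >= 3)")

    def window_length(self, n: int) -> int:
        w = max(int(round(self.fraction * n)), self.min_window)
        if w > n:
            raise ValueError(
                f"window of {w} items exceeds sequence length {n}; provide a "
                "longer sequence or a smaller fraction/min_window"
            )
        return w


def sliding_windows(seq, spec: WindowSpec = WindowSpec()) -> list[np.ndarray]:
    """Contiguous subsequences of length w at starts 0, step, 2*step, ...

    The number of windows is floor((n - w)/step) + 1; the last window ends
    at or before the end of the sequence.
    """
    x = np.asarray(
        seq.responses if isinstance(seq, ResponseSequence) else seq, dtype=np.int64
    )
    n = x.size
    w = spec.window_length(n)
    starts = range(0, n - w + 1, spec.step)
    return [x[s : s + w] for s in starts]


@dataclass
class WindowTrajectory:
    """Per-window metric profiles for one participant."""

    participant_id: str
    group: str
    window_starts: list[int]
    profiles: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ordinal, (start, prof) in enumerate(
            zip(self.window_starts, self.profiles)
        ):
            row = {
                "participant_id": self.participant_id,
                "group": self.group,
                "window": ordinal,
                "start": start,
            }
            row.update(prof.to_dict())
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["participant_id", "group", "window", "start", *PROFILE_COLUMNS],
        )


def trajectory(seq: ResponseSequence, spec: WindowSpec = WindowSpec()) -> WindowTrajectory:
    """Full metric profile per window along one sequence."""
    windows = sliding_windows(seq, spec)
    starts = list(range(0, len(seq) - len(windows[0]) + 1, spec.step))
    profiles = [metrics_profile(w) for w in windows]
    return WindowTrajectory(seq.participant_id, seq.group, starts, profiles)


def trajectory_table(cohort: Cohort, spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Long-format trajectories for every participant in a cohort."""
    frames = [trajectory(seq, spec).to_frame() for seq in cohort.sequences]
    return pd.concat(frames, ignore_index=True)


def group_trajectory_contrast(
    cohort: Cohort, spec: WindowSpec = WindowSpec(), metric: str = "NSQ"
) -> pd.DataFrame:
    """Per-window-ordinal group means of one metric and their difference.

    Returns a frame indexed by window ordinal with columns ``mean_ASD``,
    ``mean_CTRL``, ``diff`` (ASD minus CTRL) and per-group participant
    counts. Only ordinals present in both groups are kept; participants
    whose trajectory is shorter than an ordinal simply drop out of it.
    """
    if metric not in PROFILE_COLUMNS:
        raise KeyError(
            f"unknown metric {metric!r}; available: {', '.join(PROFILE_COLUMNS)}"
        )
    sizes = cohort.group_sizes()
    if min(sizes.values()) < 1:
        raise ValueError(f"both groups must be non-empty, got sizes {sizes}")
    table = trajectory_table(cohort, spec)
    grouped = (
        table.groupby(["window", "group"])[metric]
        .agg(["mean", "count"])
        .unstack("group")
    )
    out = pd.DataFrame(
        {
            "mean_ASD": grouped[("mean", "ASD")],
            "mean_CTRL": grouped[("mean", "CTRL")],
            "n_ASD": grouped[("count", "ASD")],
            "n_CTRL": grouped[("count", "CTRL")],
        }
    ).dropna(subset=["mean_ASD", "mean_CTRL"])
    out["diff"] = out["mean_ASD"] - out["mean_CTRL"]
    out.index.name = "window"
    return out
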