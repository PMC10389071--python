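"""Categorical recurrence quantification analysis (RQA) of digit sequences.

A recurrence plot of a categorical sequence marks every pair of positions
holding the same digit. For integer categories the canonical parameters are
fixed: embedding dimension 1, delay 1, radius 0 (exact match); the main
diagonal (line of identity) is excluded from every count and no wider
Theiler window is applied.

From the plot we derive:

* RR       — recurrence rate: recurrent off-diagonal cells / n(n-1);
* DET      — determinism: fraction of recurrent points on diagonal lines of
             length >= 2 (repeated subsequences);
* LAM_hl   — laminarity: same for vertical lines (digits repeated
             monotonously); vertical and horizontal are mirror images, so
             vertical lines carry the "_hl" measures;
* MEAN_dl  — mean diagonal line length (lines >= 2);
* ENTrel_dl — Shannon entropy of the diagonal line-length distribution,
             normalised by log(number of distinct observed lengths);
* TT_hl    — trapping time: mean vertical line length (lines >= 2).

RR coincides exactly with the relative correlation-function index r_Cf:
both count the fraction of unordered position pairs holding the same digit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, fields

import numpy as np

from .metrics import _digits

#: Minimum line length for diagonal and vertical structures.
MIN_LINE = 2


def recurrence_matrix(seq) -> np.ndarray:
    """n x n boolean matrix with cell (i, j) = True iff seq[i] == seq[j].

    The main diagonal is returned True (trivially recurrent) but excluded
    from every downstream count.
    """
    x = _digits(seq)
    if x.size < 2:
        raise ValueError("a recurrence matrix needs n >= 2")
    return x[:, None] == x[None, :]


def _run_lengths(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a 1-D boolean vector."""
    runs: list[int] = []
    count = 0
    for v in mask:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def line_length_distribution(mat: np.ndarray, orientation: str) -> Counter:
    """Histogram {length: count} of maximal recurrent lines.

    diagonal
        Runs along every diagonal except the main one (both triangles, so
        each structure appears twice; ratios, means and entropies are
        unaffected).
    vertical
        Runs down each column over the off-diagonal cells; the excluded
        main-diagonal cell is removed, not treated as an interruption, so a
        constant sequence of length n yields one run of n-1 per column.
    """
    n = mat.shape[0]
    hist: Counter = Counter()
    if orientation == "diagonal":
        for offset in range(1, n):
            diag = np.diagonal(mat, offset)
            for length in _run_lengths(diag):
                hist[length] += 2  # the mirrored diagonal is identical
    elif orientation == "vertical":
        keep = ~np.eye(n, dtype=bool)
        for j in range(n):
            column = mat[:, j][keep[:, j]]
            for length in _run_lengths(column):
                hist[length] += 1
    else:
        raise ValueError(f"orientation must be 'diagonal' or 'vertical', got {orientation!r}")
    return hist


def _line_stats(hist: Counter) -> tuple[float, float, float]:
    """(points on lines >= MIN_LINE, mean length, relative entropy)."""
    lengths = np.array([l for l in hist if l >= MIN_LINE], dtype=float)
    if lengths.size == 0:
        return 0.0, 0.0, 0.0
    counts = np.array([hist[int(l)] for l in lengths], dtype=float)
    points = float(np.sum(lengths * counts))
    mean = float(np.sum(lengths * counts) / np.sum(counts))
    if lengths.size == 1:
        ent_rel = 0.0
    else:
        p = counts / counts.sum()
        ent = -float(np.sum(p * np.log(p)))
        ent_rel = ent / float(np.log(lengths.size))
    return points, mean, ent_rel


@dataclass(frozen=True)
class RQAProfile:
    """The six recurrence measures for one sequence."""

    RR: float
    DET: float
    LAM_hl: float
    MEAN_dl: float
    ENTrel_dl: float
    TT_hl: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


RQA_COLUMNS = tuple(f.name for f in fields(RQAProfile))


def rqa_profile(seq) -> RQAProfile:
    """All six RQA measures; measures over empty line sets are 0."""
    x = _digits(seq)
    n = x.size
    mat = recurrence_matrix(x)
    recurrent = int(mat.sum()) - n  # off-diagonal recurrent points
    rr = recurrent / (n * (n - 1))

    diag_hist = line_length_distribution(mat, "diagonal")
    vert_hist = line_length_distribution(mat, "vertical")
    diag_points, mean_dl, ent_rel = _line_stats(diag_hist)
    vert_points, tt, _ = _line_stats(vert_hist)

    # Border correction: corner diagonals shorter than MIN_LINE can never
    # hold a countable line, so recurrent points on them are excluded from
    # the determinism denominator (a fully recurrent plot then has DET = 1).
    border = 0
    for offset in range(max(1, n - MIN_LINE + 1), n):
        border += 2 * int(np.sum(np.diagonal(mat, offset)))
    det_denom = recurrent - border

    det = diag_points / det_denom if det_denom else 0.0
    lam = vert_points / recurrent if recurrent else 0.0
    return RQAProfile(
        RR=rr, DET=det, LAM_hl=lam, MEAN_dl=mean_dl, ENTrel_dl=ent_rel, TT_hl=tt
    )


def rqa_table(sequences):
    """Participants x RQA-measures DataFrame."""
    import pandas as pd

    rows = []
    for seq in sequences:
        row = {"participant_id": seq.participant_id, "group": seq.group}
        row.update(rqa_profile(seq.responses).to_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "group", *RQA_COLUMNS])
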