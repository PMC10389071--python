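"""Randomness indices and sequence descriptors for digit sequences.

Implements the classical random-number-generation (RNG) task variables for
a single sequence of digits 1-10:

* redundancy (R) — entropy shortfall of digit usage, in percent;
* Evans RNG index at lag 1 and lag 2 (RNG, RNG2) — digram stereotypy;
* null-score quotient (NSQ) — share of the 100 possible digrams never used;
* adjacency — percentage of +/-1 steps (ascending, descending, combined);
* turning point index (TPI) — observed local extrema relative to the
  (2/3)(n-2) expected for a random series;
* response frequencies (RF, r_RF), first-order differences (FOD, r_FOD)
  and the correlation-function index (Cf, r_Cf).

Relative descriptors divide by the sequence length n ("per sequence
length"); for r_FOD this means the 19 relative bins sum to (n-1)/n, not 1.
A metric whose denominator vanishes is reported as NaN (missing), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .cohort import ResponseSequence

DIGITS = np.arange(1, 11)
#: First-order differences observable between digits 1..10.
FOD_DIFFS = np.arange(-9, 10)

#: log2(10): the maximum digit-usage entropy over 10 alternatives.
_HMAX = np.log2(10.0)


class UndefinedMetricError(ValueError):
    """A metric's precondition on sequence length is not met."""


def _digits(seq) -> np.ndarray:
    if isinstance(seq, ResponseSequence):
        arr = np.asarray(seq.responses, dtype=np.int64)
    else:
        arr = np.asarray(seq, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("a digit sequence must be one-dimensional")
    if arr.size and (arr.min() < 1 or arr.max() > 10):
        raise ValueError("responses must lie in [1,10]")
    return arr


def digram_counts(seq, lag: int = 1) -> np.ndarray:
    """10x10 matrix of ordered digit pairs at the given lag.

    Cell (i, j) counts positions t with seq[t] = i and seq[t+lag] = j
    (1-based digits on 0-based axes). The cells sum to n - lag.
    """
    x = _digits(seq)
    n = x.size
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if n <= lag:
        raise UndefinedMetricError(
            f"digram counts at lag {lag} need n > {lag}, got n = {n}"
        )
    counts = np.zeros((10, 10), dtype=np.int64)
    np.add.at(counts, (x[:-lag] - 1, x[lag:] - 1), 1)
    return counts


def redundancy(seq) -> float:
    """Percent shortfall of digit-usage entropy relative to uniform usage.

    R = 100 (1 - H / log2 10) with H = log2 n - (1/n) sum_i n_i log2 n_i
    over the digit counts n_i. 0 for perfectly balanced usage, 100 for a
    constant sequence. Clipped to [0, 100].
    """
    x = _digits(seq)
    n = x.size
    if n < 1:
        raise UndefinedMetricError("redundancy needs n >= 1")
    counts = np.bincount(x, minlength=11)[1:]
    nz = counts[counts > 0].astype(float)
    h = np.log2(n) - float(np.sum(nz * np.log2(nz))) / n
    return float(np.clip(100.0 * (1.0 - h / _HMAX), 0.0, 100.0))


def evans_rng(seq, lag: int = 1) -> float:
    """Evans' RNG index on digrams at the given lag, scaled to [0, 100].

    RNG = 100 * (sum_ij n_ij log n_ij) / (sum_i m_i log m_i) where n_ij are
    the digram counts and m_i their row sums (first-member counts), with
    0 log 0 = 0. Base-invariant. High values mean stereotyped successor
    choice. NaN when the denominator vanishes (every first member used at
    most once) — the index is then undefined, not zero.
    """
    counts = digram_counts(seq, lag).astype(float)
    rows = counts.sum(axis=1)

    def _xlogx(a: np.ndarray) -> float:
        nz = a[a > 1]  # 1*log(1) = 0 and 0*log(0) := 0
        return float(np.sum(nz * np.log(nz)))

    denom = _xlogx(rows)
    if denom == 0.0:
        return float("nan")
    return 100.0 * _xlogx(counts.ravel()) / denom


def null_score_quotient(seq) -> float:
    """Percent of the 100 possible lag-1 digrams never used, out of the
    maximum 99 (at least one digram cell is always occupied)."""
    counts = digram_counts(seq, lag=1)
    ns = int(np.sum(counts == 0))
    return 100.0 * ns / 99.0


def adjacency(seq) -> tuple[float, float, float]:
    """Percent of successive pairs stepping by +1 (ascending), -1
    (descending), and their sum (combined). No wrap-around between 10 and 1."""
    x = _digits(seq)
    if x.size < 2:
        raise UndefinedMetricError("adjacency needs n >= 2")
    d = np.diff(x)
    denom = float(d.size)
    asc = 100.0 * float(np.sum(d == 1)) / denom
    desc = 100.0 * float(np.sum(d == -1)) / denom
    return asc, desc, asc + desc


def turning_point_index(seq) -> float:
    """Observed turning points as a percent of the (2/3)(n-2) expected for
    a random series.

    Runs of equal values are collapsed before detecting strict local
    maxima/minima; n in the expectation is the original length. Ranges over
    [0, 150].
    """
    x = _digits(seq)
    n = x.size
    if n < 3:
        raise UndefinedMetricError("turning point index needs n >= 3")
    collapsed = x[np.insert(np.diff(x) != 0, 0, True)]
    if collapsed.size < 3:
        tp = 0
    else:
        left = np.sign(np.diff(collapsed[:-1]))
        right = np.sign(np.diff(collapsed[1:]))
        tp = int(np.sum(left != right))
    expected = (2.0 / 3.0) * (n - 2)
    return 100.0 * tp / expected


def response_frequencies(seq) -> tuple[np.ndarray, np.ndarray]:
    """Counts of each digit 1..10 (RF) and their share of the sequence
    length (r_RF = RF / n)."""
    x = _digits(seq)
    if x.size < 1:
        raise UndefinedMetricError("response frequencies need n >= 1")
    rf = np.bincount(x, minlength=11)[1:].astype(np.int64)
    return rf, rf / x.size


def first_order_differences(seq) -> tuple[np.ndarray, np.ndarray]:
    """Histogram over differences seq[t+1]-seq[t] in -9..+9 (FOD) and the
    relative form r_FOD = FOD / n (per sequence length, so the 19 bins sum
    to (n-1)/n)."""
    x = _digits(seq)
    if x.size < 2:
        raise UndefinedMetricError("first-order differences need n >= 2")
    d = np.diff(x)
    fod = np.bincount(d + 9, minlength=19).astype(np.int64)
    return fod, fod / x.size


def correlation_function(seq) -> tuple[float, float]:
    """Aggregate same-digit repetition across all distances.

    With match_d = #{t : seq[t] = seq[t+d]} for d = 1..n-1:
    Cf = (sum_d match_d) / (n-1) and r_Cf = (sum_d match_d) / (n(n-1)/2) —
    the fraction of all unordered position pairs holding the same digit,
    equivalently Cf divided by its maximum n/2. For IID uniform digits
    r_Cf has expectation 0.1.
    """
    x = _digits(seq)
    n = x.size
    if n < 2:
        raise UndefinedMetricError("correlation function needs n >= 2")
    rf = np.bincount(x, minlength=11)[1:]
    total_matches = float(np.sum(rf * (rf - 1) // 2))
    cf = total_matches / (n - 1)
    r_cf = total_matches / (n * (n - 1) / 2.0)
    return cf, r_cf


@dataclass(frozen=True)
class MetricsProfile:
    """All whole-sequence variables for one participant."""

    R: float
    RNG: float
    RNG2: float
    NSQ: float
    adjacency_asc: float
    adjacency_desc: float
    adjacency_combined: float
    TPI: float
    RF: np.ndarray
    r_RF: np.ndarray
    FOD: np.ndarray
    r_FOD: np.ndarray
    Cf: float
    r_Cf: float

    def to_dict(self) -> dict[str, float]:
        """Flatten into named scalar features (RF_1.., r_RF_1.., FOD_-9..)."""
        out: dict[str, float] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name in ("RF", "r_RF"):
                for k, v in zip(DIGITS, value):
                    out[f"{f.name}_{k}"] = float(v)
            elif f.name in ("FOD", "r_FOD"):
                for d, v in zip(FOD_DIFFS, value):
                    out[f"{f.name}_{d}"] = float(v)
            else:
                out[f.name] = float(value)
        return out


#: Stable order of the flattened feature columns.
PROFILE_COLUMNS = tuple(
    ["R", "RNG", "RNG2", "NSQ", "adjacency_asc", "adjacency_desc",
     "adjacency_combined", "TPI"]
    + [f"RF_{k}" for k in DIGITS]
    + [f"r_RF_{k}" for k in DIGITS]
    + [f"FOD_{d}" for d in FOD_DIFFS]
    + [f"r_FOD_{d}" for d in FOD_DIFFS]
    + ["Cf", "r_Cf"]
)


def metrics_profile(seq) -> MetricsProfile:
    """Compute every whole-sequence variable; needs n >= 3 (RNG2 and TPI are
    the shortest-supported metrics). Undefined metrics propagate as NaN."""
    x = _digits(seq)
    if x.size < 3:
        raise UndefinedMetricError(
            "a full metrics profile needs n >= 3 (RNG2 and the turning "
            "point index are undefined below that)"
        )
    asc, desc, comb = adjacency(x)
    rf, r_rf = response_frequencies(x)
    fod, r_fod = first_order_differences(x)
    cf, r_cf = correlation_function(x)
    return MetricsProfile(
        R=redundancy(x),
        RNG=evans_rng(x, lag=1),
        RNG2=evans_rng(x, lag=2),
        NSQ=null_score_quotient(x),
        adjacency_asc=asc,
        adjacency_desc=desc,
        adjacency_combined=comb,
        TPI=turning_point_index(x),
        RF=rf,
        r_RF=r_rf,
        FOD=fod,
        r_FOD=r_fod,
        Cf=cf,
        r_Cf=r_cf,
    )


def profile_row(seq: ResponseSequence) -> dict[str, float]:
    """One flat feature row for a participant, id and group included."""
    row: dict[str, float] = {
        "participant_id": seq.participant_id,
        "group": seq.group,
    }
    row.update(metrics_profile(seq).to_dict())
    return row


def feature_table(sequences: Sequence[ResponseSequence]):
    """Participants x features DataFrame with all profile variables, plus
    the sequence length as feature ``n``."""
    import pandas as pd

    rows = []
    for seq in sequences:
        row = profile_row(seq)
        row["n"] = len(seq)
        rows.append(row)
    columns = ["participant_id", "group", "n", *PROFILE_COLUMNS]
    return pd.DataFrame(rows, columns=columns)
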