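"""Independent brute-force reference implementations.

Everything here is written directly from the metric definitions with plain
Python loops and the math module — deliberately sharing no code or numpy
idioms with the package — so agreement is a genuine two-route check.
"""

from __future__ import annotations

import math
from collections import Counter


def oracle_digram_counts(seq, lag):
    counts = [[0] * 10 for _ in range(10)]
    for t in range(len(seq) - lag):
        counts[seq[t] - 1][seq[t + lag] - 1] += 1
    return counts


def oracle_redundancy(seq):
    n = len(seq)
    freq = Counter(seq)
    h = math.log2(n) - sum(c * math.log2(c) for c in freq.values()) / n
    r = 100.0 * (1.0 - h / math.log2(10))
    return min(max(r, 0.0), 100.0)


def oracle_evans_rng(seq, lag, log=math.log2):
    """Literal formula; the log base is a parameter to check base invariance."""
    counts = oracle_digram_counts(seq, lag)
    num = sum(
        c * log(c) for row in counts for c in row if c > 0
    )
    den = sum(
        s * log(s) for s in (sum(row) for row in counts) if s > 0
    )
    if den == 0:
        return float("nan")
    return 100.0 * num / den


def oracle_nsq(seq):
    counts = oracle_digram_counts(seq, 1)
    ns = sum(1 for row in counts for c in row if c == 0)
    return 100.0 * ns / 99.0


def oracle_adjacency(seq):
    n = len(seq)
    asc = sum(1 for t in range(n - 1) if seq[t + 1] == seq[t] + 1)
    desc = sum(1 for t in range(n - 1) if seq[t + 1] == seq[t] - 1)
    return (100.0 * asc / (n - 1), 100.0 * desc / (n - 1),
            100.0 * (asc + desc) / (n - 1))


def oracle_tpi(seq):
    n = len(seq)
    collapsed = [seq[0]]
    for v in seq[1:]:
        if v != collapsed[-1]:
            collapsed.append(v)
    turns = 0
    for i in range(1, len(collapsed) - 1):
        a, b, c = collapsed[i - 1], collapsed[i], collapsed[i + 1]
        if (b > a and b > c) or (b < a and b < c):
            turns += 1
    return 100.0 * turns / ((2.0 / 3.0) * (n - 2))


def oracle_rf(seq):
    rf = [seq.count(k) for k in range(1, 11)]
    return rf, [c / len(seq) for c in rf]


def oracle_fod(seq):
    fod = [0] * 19
    for t in range(len(seq) - 1):
        fod[seq[t + 1] - seq[t] + 9] += 1
    return fod, [c / len(seq) for c in fod]


def oracle_cf(seq):
    n = len(seq)
    total = 0
    for d in range(1, n):
        total += sum(1 for t in range(n - d) if seq[t] == seq[t + d])
    return total / (n - 1), total / (n * (n - 1) / 2.0)


def _runs(bits):
    runs, current = [], 0
    for b in bits:
        if b:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def oracle_rqa(seq, min_line=2):
    """All six RQA measures by direct enumeration of the recurrence plot.

    Conventions (pinned by the package and mirrored here from the written
    definitions): exact categorical match; main diagonal excluded; vertical
    columns skip the main-diagonal cell without breaking the run; diagonals
    too short to hold a countable line are excluded from the determinism
    denominator.
    """
    n = len(seq)
    mat = [[seq[i] == seq[j] for j in range(n)] for i in range(n)]
    recurrent = sum(
        1 for i in range(n) for j in range(n) if i != j and mat[i][j]
    )
    rr = recurrent / (n * (n - 1))

    diag_lines = []
    border_points = 0
    for off in range(1, n):
        bits = [mat[i][i + off] for i in range(n - off)]
        if n - off < min_line:
            border_points += 2 * sum(bits)
            continue
        for run in _runs(bits):
            diag_lines.extend([run, run])  # both triangles
    vert_lines = []
    for j in range(n):
        bits = [mat[i][j] for i in range(n) if i != j]
        vert_lines.extend(_runs(bits))

    def stats(lines):
        kept = [l for l in lines if l >= min_line]
        if not kept:
            return 0, 0.0, 0.0
        points = sum(kept)
        mean = points / len(kept)
        hist = Counter(kept)
        if len(hist) <= 1:
            ent_rel = 0.0
        else:
            total = sum(hist.values())
            ent = -sum((c / total) * math.log(c / total) for c in hist.values())
            ent_rel = ent / math.log(len(hist))
        return points, mean, ent_rel

    dpoints, mean_dl, ent_rel = stats(diag_lines)
    vpoints, tt, _ = stats(vert_lines)
    # note: border diagonals (length < min_line) also appear in diag_lines
    # as short runs only when the diagonal is long enough; the truly short
    # diagonals were skipped above and their points tallied separately
    det_denom = recurrent - border_points
    return {
        "RR": rr,
        "DET": dpoints / det_denom if det_denom else 0.0,
        "LAM_hl": vpoints / recurrent if recurrent else 0.0,
        "MEAN_dl": mean_dl,
        "ENTrel_dl": ent_rel,
        "TT_hl": tt,
    }


def de_bruijn_digits(k=10, order=2):
    """A cyclic de Bruijn sequence over k symbols covering every length-
    ``order`` word once; returned as digits 1..k."""
    a = [0] * k * order
    sequence = []

    def db(t, p):
        if t > order:
            if order % p == 0:
                sequence.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return [d + 1 for d in sequence]
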