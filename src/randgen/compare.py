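"""Normality-gated two-group comparisons over a feature table.

Each continuous feature is tested with one-way ANOVA when normality cannot
be rejected in either group (Shapiro-Wilk at alpha 0.05 per group), and
with the Mann-Whitney U test otherwise ("Mann-Whitney U when non-normality
could not be excluded"). Categorical margins (e.g., gender balance) use the
Pearson chi-square test without continuity correction.

Raw p-values are reported by default, matching the study convention of
per-feature tests over ~70 variables; an optional Benjamini-Hochberg column
flags the multiplicity issue without changing the primary output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MANN_WHITNEY_U = "mann_whitney_u"
ANOVA_ONEWAY = "anova_oneway"
CHI_SQUARE = "chi_square"

#: Per-group Shapiro-Wilk significance level for the normality gate.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One feature's two-group comparison."""

    feature: str
    test: str
    statistic: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    n_per_group: tuple[int, int]
    warnings: tuple[str, ...] = field(default=())

    def summary(self) -> str:
        (ma, mb), (sa, sb) = self.group_means, self.group_sds
        return (
            f"{self.feature}: {ma:.3f} ({sa:.2f}) vs {mb:.3f} ({sb:.2f}), "
            f"{self.test} p = {self.p_value:.3g}"
        )


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def normality_gate(values_a, values_b, alpha: float = DEFAULT_ALPHA) -> str:
    """Choose the two-sample test for a continuous feature.

    Returns ``mann_whitney_u`` if Shapiro-Wilk rejects normality (p < alpha)
    in either group, or if either group is too small or degenerate for the
    test; otherwise ``anova_oneway``.
    """
    for values in (values_a, values_b):
        v = _clean(values)
        if v.size < 3:
            logger.warning(
                "normality gate: group of size %d (< 3); forcing Mann-Whitney U",
                v.size,
            )
            return MANN_WHITNEY_U
        if np.ptp(v) == 0:
            return MANN_WHITNEY_U  # constant input: the gate is degenerate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(v).pvalue < alpha:
                return MANN_WHITNEY_U
    return ANOVA_ONEWAY


def compare_feature(
    values_a,
    values_b,
    test: str | None = None,
    feature: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Two-sided two-group test of one continuous feature.

    ``test`` defaults to the :func:`normality_gate` choice. NaNs are
    excluded pairwise (per feature).
    """
    a, b = _clean(values_a), _clean(values_b)
    if test is None:
        test = normality_gate(a, b, alpha)
    notes: list[str] = []
    if test == MANN_WHITNEY_U:
        if np.ptp(np.concatenate([a, b])) == 0:
            statistic, p = float(a.size * b.size / 2.0), 1.0
            notes.append("all values tied; p set to 1")
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            statistic, p = float(res.statistic), float(res.pvalue)
    elif test == ANOVA_ONEWAY:
        res = stats.f_oneway(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(
        feature=feature,
        test=test,
        statistic=statistic,
        p_value=p,
        group_means=(float(np.mean(a)), float(np.mean(b))),
        group_sds=(float(np.std(a, ddof=1)), float(np.std(b, ddof=1))),
        n_per_group=(int(a.size), int(b.size)),
        warnings=tuple(notes),
    )


def compare_categorical(counts_a, counts_b, feature: str = "") -> TestResult:
    """Pearson chi-square (no Yates correction) on a 2 x k count table.

    Categories empty in both groups are dropped with a warning. Group
    "means" report the first category's proportion per group.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts_a and counts_b must be 1-D and equal length")
    notes: list[str] = []
    keep = (a + b) > 0
    if not keep.all():
        notes.append(f"dropped {int((~keep).sum())} zero-margin categories")
        logger.warning("chi-square: %s", notes[-1])
        a, b = a[keep], b[keep]
    table = np.vstack([a, b])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        feature=feature,
        test=CHI_SQUARE,
        statistic=float(chi2),
        p_value=float(p),
        group_means=(float(a[0] / a.sum()), float(b[0] / b.sum())),
        group_sds=(float("nan"), float("nan")),
        n_per_group=(int(a.sum()), int(b.sum())),
        warnings=tuple(notes),
    )


def compare_all(
    features: pd.DataFrame,
    group_col: str = "group",
    alpha: float = DEFAULT_ALPHA,
    adjust: bool = False,
) -> pd.DataFrame:
    """Gated test of every numeric feature column between the two groups.

    Parameters
    ----------
    features
        Participants x features table with a group label column; all other
        numeric columns are tested. Missing values are excluded pairwise
        with a logged count.
    adjust
        Add a Benjamini-Hochberg adjusted p-value column (off by default,
        mirroring raw per-feature reporting).

    Returns
    -------
    DataFrame with one row per feature: per-group mean (std), n, the test
    used, statistic and p-value, sorted in input column order.
    """
    groups = sorted(features[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    ga, gb = groups[0], groups[1]
    if "ASD" in groups:  # keep the clinical group first for readability
        ga, gb = "ASD", [g for g in groups if g != "ASD"][0]
    mask_a = features[group_col] == ga

    rows = []
    feature_cols = [
        c
        for c in features.columns
        if c != group_col and pd.api.types.is_numeric_dtype(features[c])
    ]
    for col in feature_cols:
        a = features.loc[mask_a, col].to_numpy(dtype=float)
        b = features.loc[~mask_a, col].to_numpy(dtype=float)
        n_missing = int(np.isnan(a).sum() + np.isnan(b).sum())
        if n_missing:
            logger.info("feature %s: %d missing values excluded", col, n_missing)
        result = compare_feature(a, b, feature=col, alpha=alpha)
        rows.append(
            {
                "feature": col,
                f"mean_{ga}": result.group_means[0],
                f"sd_{ga}": result.group_sds[0],
                f"mean_{gb}": result.group_means[1],
                f"sd_{gb}": result.group_sds[1],
                f"n_{ga}": result.n_per_group[0],
                f"n_{gb}": result.n_per_group[1],
                "test": result.test,
                "statistic": result.statistic,
                "p_value": result.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
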