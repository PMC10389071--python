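"""Exhaustive feature-subset decision-tree discrimination with
leave-one-out cross-validation.

Every subset of up to three features is scored by fitting a CART decision
tree (Gini impurity) per leave-one-out fold and predicting the held-out
participant. The tree hyperparameters default to the published final
configuration: max_depth 5, max_features 1 (one randomly chosen candidate
feature per split, seeded), min_samples_split 7, min_samples_leaf 1,
random_state 1. With max_features = 1 the induction is stochastic, so
accuracy — not tree identity — is the comparable quantity.

Subset enumeration, fold handling and ranking are owned here; the tree
itself is scikit-learn's ``DecisionTreeClassifier``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, export_graphviz

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreeSpec:
    """Decision-tree hyperparameters (defaults: the published final set)."""

    max_depth: int = 5
    max_features: int = 1
    min_samples_split: int = 7
    min_samples_leaf: int = 1
    criterion: str = "gini"
    seed: int = 1

    def build(self) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion=self.criterion,
            max_depth=self.max_depth,
            max_features=self.max_features,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
        )


@dataclass(frozen=True)
class SearchResult:
    """LOO score of one feature subset."""

    feature_subset: tuple[str, ...]
    spec: TreeSpec
    loo_accuracy: float
    per_fold_predictions: tuple[tuple[str, str, str], ...] = field(repr=False)


def _validate_table(
    table: pd.DataFrame, label_col: str
) -> tuple[pd.DataFrame, list[str]]:
    if table[label_col].isna().any():
        raise ValueError("missing group labels are not allowed")
    usable: list[str] = []
    for col in table.columns:
        if col == label_col or not pd.api.types.is_numeric_dtype(table[col]):
            continue
        if table[col].isna().any():
            logger.warning("feature %s has missing values; excluded from search", col)
            continue
        usable.append(col)
    return table, usable


def fit_tree(
    table: pd.DataFrame,
    subset,
    spec: TreeSpec = TreeSpec(),
    label_col: str = "group",
) -> DecisionTreeClassifier:
    """Fit one tree on the given feature subset."""
    subset = list(subset)
    missing = [c for c in subset if c not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    x = table[subset].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    tree = spec.build()
    tree.fit(x, y)
    return tree


def loo_accuracy(
    table: pd.DataFrame,
    subset,
    spec: TreeSpec = TreeSpec(),
    label_col: str = "group",
    id_col: str | None = "participant_id",
) -> SearchResult:
    """Leave-one-out accuracy of one feature subset.

    Each participant is predicted by a tree fitted on all the others; folds
    whose training rows collapse to a single class fall back to majority
    prediction (logged).
    """
    subset = tuple(subset)
    x = table[list(subset)].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    if x.shape[0] < 3:
        raise ValueError("leave-one-out needs at least 3 rows")
    ids = (
        table[id_col].astype(str).to_numpy()
        if id_col and id_col in table.columns
        else np.arange(len(y)).astype(str)
    )
    predictions: list[tuple[str, str, str]] = []
    correct = 0
    for i in range(x.shape[0]):
        mask = np.ones(x.shape[0], dtype=bool)
        mask[i] = False
        y_train = y[mask]
        classes = np.unique(y_train)
        if classes.size < 2:
            logger.warning("fold %d: single-class training data; majority vote", i)
            pred = classes[0]
        else:
            tree = spec.build()
            tree.fit(x[mask], y_train)
            pred = tree.predict(x[i : i + 1])[0]
        predictions.append((ids[i], str(pred), str(y[i])))
        correct += int(pred == y[i])
    return SearchResult(
        feature_subset=subset,
        spec=spec,
        loo_accuracy=correct / x.shape[0],
        per_fold_predictions=tuple(predictions),
    )


def exhaustive_search(
    table: pd.DataFrame,
    max_subset_size: int = 3,
    spec: TreeSpec = TreeSpec(),
    label_col: str = "group",
    id_col: str | None = "participant_id",
    feature_cols=None,
    budget: int = 200_000,
    force: bool = False,
) -> list[SearchResult]:
    """Score every feature subset of size 1..max_subset_size by LOO accuracy.

    Results are sorted by accuracy descending; ties break toward smaller
    subsets, then lexicographic feature names. Refuses to start when the
    subset count exceeds ``budget`` unless ``force`` is set.
    """
    table, usable = _validate_table(table, label_col)
    if feature_cols is not None:
        unknown = [c for c in feature_cols if c not in usable]
        if unknown:
            raise KeyError(f"requested features unusable or absent: {unknown}")
        usable = list(feature_cols)
    if id_col and id_col in usable:
        usable.remove(id_col)
    if not usable:
        raise ValueError("no usable features")
    p = len(usable)
    n_subsets = sum(comb(p, k) for k in range(1, max_subset_size + 1))
    if n_subsets > budget and not force:
        raise ValueError(
            f"{n_subsets} subsets exceed the budget of {budget}; "
            "pass force=True to run anyway"
        )
    results = []
    for k in range(1, max_subset_size + 1):
        for subset in combinations(sorted(usable), k):
            results.append(
                loo_accuracy(table, subset, spec, label_col=label_col, id_col=id_col)
            )
    results.sort(
        key=lambda r: (-r.loo_accuracy, len(r.feature_subset), r.feature_subset)
    )
    return results


def ranking_frame(results) -> pd.DataFrame:
    """Flatten search results into a ranking table."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(results) + 1),
            "features": [" + ".join(r.feature_subset) for r in results],
            "k": [len(r.feature_subset) for r in results],
            "loo_accuracy": [r.loo_accuracy for r in results],
        }
    )


def export_tree_dot(
    table: pd.DataFrame,
    subset,
    spec: TreeSpec = TreeSpec(),
    label_col: str = "group",
) -> str:
    """DOT description of the tree fitted on the full table (figure analogue)."""
    tree = fit_tree(table, subset, spec, label_col=label_col)
    return export_graphviz(
        tree,
        feature_names=list(subset),
        class_names=[str(c) for c in tree.classes_],
        filled=False,
        impurity=True,
    )
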