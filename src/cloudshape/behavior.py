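"""Behavioral-comparison statistics.

Model predictions and human responses are compared on two surfaces:

* **error patterns** — Pearson correlation between the off-diagonal
  (misclassification) cells of two confusion matrices, after row-normalizing
  each matrix to proportions so unequal trial counts do not confound the
  comparison (raw-count mode is available);
* **accuracy patterns** — Pearson correlation between per-condition mean
  accuracies pooled across experiments, with Steiger's z for comparing two
  such correlations that share the human profile.

Human data enter only as externally supplied delimited tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix", "AccuracyProfile",
    "confusion_from_predictions", "offdiag_correlation",
    "accuracy_pattern_correlation", "compare_dependent_correlations",
    "profile_from_predictions", "load_human_table",
    "write_confusion", "write_profile",
]


@dataclass
class ConfusionMatrix:
    """C×C counts; rows are true categories, columns predicted."""

    categories: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        c = len(self.categories)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts must be {c}x{c}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        out = np.divide(self.counts, sums, where=sums > 0,
                        out=np.zeros(self.counts.shape, dtype=np.float64))
        return out


@dataclass
class AccuracyProfile:
    """Ordered per-condition mean accuracies."""

    conditions: list
    accuracies: np.ndarray
    n_trials: np.ndarray | None = None

    def __post_init__(self):
        self.accuracies = np.asarray(self.accuracies, dtype=np.float64)
        if len(self.conditions) != len(self.accuracies):
            raise ValueError("one accuracy per condition required")
        if len(set(map(str, self.conditions))) != len(self.conditions):
            raise ValueError("condition ids must be unique")
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")


def confusion_from_predictions(table: pd.DataFrame, categories) -> ConfusionMatrix:
    """Tally a predictions table (columns ``true`` and ``predicted``)."""
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for t, p in zip(table["true"], table["predicted"]):
        if t not in index or p not in index:
            raise ValueError(f"label outside category list: {t!r} -> {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(categories, counts)


def _offdiag_vector(cm: ConfusionMatrix, normalize: bool) -> np.ndarray:
    mat = cm.row_normalized() if normalize else cm.counts.astype(np.float64)
    c = len(cm.categories)
    mask = ~np.eye(c, dtype=bool)
    return mat[mask]                 # row-major order of the C(C−1) cells


def offdiag_correlation(cm_a: ConfusionMatrix, cm_b: ConfusionMatrix,
                        normalize: bool = True):
    """Pearson correlation of misclassification patterns.

    Both matrices are (by default) row-normalized, diagonals removed, and
    the remaining C(C−1) cells flattened row-major. The two-sided p-value
    comes from the t transform with C(C−1)−2 degrees of freedom.
    """
    if cm_a.categories != cm_b.categories:
        raise ValueError("confusion matrices must share the category ordering")
    if len(cm_a.categories) < 3:
        raise ValueError("need at least 3 categories for off-diagonal correlation")
    x = _offdiag_vector(cm_a, normalize)
    y = _offdiag_vector(cm_b, normalize)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("off-diagonal correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def accuracy_pattern_correlation(profile_a: AccuracyProfile,
                                 profile_b: AccuracyProfile):
    """Pearson correlation between two aligned accuracy profiles."""
    if list(map(str, profile_a.conditions)) != list(map(str, profile_b.conditions)):
        raise ValueError("profiles must list identical conditions in identical order")
    if len(profile_a.conditions) < 3:
        raise ValueError("need at least 3 conditions")
    if np.ptp(profile_a.accuracies) == 0 or np.ptp(profile_b.accuracies) == 0:
        raise ValueError("accuracy correlation undefined: zero variance")
    r, p = stats.pearsonr(profile_a.accuracies, profile_b.accuracies)
    return float(r), float(p)


def compare_dependent_correlations(r1: float, r2: float, r12: float, n: int):
    """Steiger's z for two correlations sharing one variable.

    ``r1`` and ``r2`` each correlate a model profile with the shared human
    profile; ``r12`` is the correlation between the two model profiles; n is
    the number of paired observations. Negative z means r1 < r2. Returns
    (z, two-sided p).
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (−1, 1), got {r}")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = 0.5 * (r1 + r2)
    # covariance of the two dependent correlations (shared-variable form)
    num = r12 * (1.0 - 2.0 * rbar ** 2) - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r12 ** 2)
    cov = num / (1.0 - rbar ** 2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def profile_from_predictions(table: pd.DataFrame, condition_cols) -> AccuracyProfile:
    """Mean accuracy per condition from a predictions table."""
    condition_cols = list(condition_cols)
    correct = (table["true"] == table["predicted"]).astype(float)
    grouped = table.assign(_correct=correct).groupby(condition_cols, sort=True)
    acc = grouped["_correct"].mean()
    n = grouped["_correct"].size()
    conditions = [c if isinstance(c, tuple) else (c,) for c in acc.index]
    return AccuracyProfile([str(c) for c in conditions], acc.to_numpy(),
                           n.to_numpy())


# -- human-data interchange ---------------------------------------------------


def write_profile(profile: AccuracyProfile, path) -> None:
    df = pd.DataFrame({"condition": [str(c) for c in profile.conditions],
                       "accuracy": profile.accuracies})
    if profile.n_trials is not None:
        df["n"] = profile.n_trials
    df.to_csv(path, index=False)


def write_confusion(cm: ConfusionMatrix, path) -> None:
    pd.DataFrame(cm.counts, index=cm.categories,
                 columns=cm.categories).to_csv(path, index_label="category")


def load_human_table(path):
    """Load an externally supplied human table.

    Two schemas are recognized: an accuracy profile (columns ``condition``,
    ``accuracy``, optional ``n``) and a square confusion matrix (first
    column ``category``, remaining columns one per category). Anything else
    raises with the offending column names.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if {"condition", "accuracy"} <= set(cols):
        extra = [c for c in cols if c not in ("condition", "accuracy", "n")]
        if extra:
            raise ValueError(f"unexpected profile columns: {extra}")
        n = df["n"].to_numpy() if "n" in cols else None
        return AccuracyProfile(list(df["condition"]), df["accuracy"].to_numpy(), n)
    if cols and cols[0] == "category":
        cats = list(df["category"])
        if list(cols[1:]) != [str(c) for c in cats]:
            raise ValueError(
                f"confusion table columns {cols[1:]} do not match rows {cats}")
        return ConfusionMatrix(cats, df[cols[1:]].to_numpy())
    raise ValueError(
        f"unrecognized human-table schema; columns: {cols} "
        "(expected condition/accuracy[/n] or category + one column per category)")
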