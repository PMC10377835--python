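"""Wrapper feature selection driven by the amended competitive search.

A candidate feature subset is scored by a two-term minimization cost

    C = w1 * (1 - ACC) + w2 * (sum of selected F-scores / sum of all F-scores)

where ACC is the cross-validated accuracy of a fixed default SVM on the
selected columns and the F-score of a feature is the Fisher-style ratio of
between-class mean separation to within-class variance.  Accuracy carries
the larger weight (w1 = 0.6, w2 = 0.4); the F-score ratio term discourages
keeping redundant discriminative mass.  Subsets are encoded as points of
the continuous unit box and decoded by thresholding at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .optimizer import CSOConfig, SearchSpace, optimize

logger = logging.getLogger(__name__)

#: Variance floor that caps the F-score of perfectly separated features.
VARIANCE_FLOOR = 1e-12


@dataclass
class LabeledFeatureTable:
    """Sample-by-feature matrix with binary class labels in {-1, +1}."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be a 2-D matrix with >= 1 feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (no missing data)")
        if set(np.unique(self.labels)) != {-1, 1}:
            raise ValueError("labels must contain both classes, coded -1/+1")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match the column count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx) -> "LabeledFeatureTable":
        return LabeledFeatureTable(
            self.values[idx], self.labels[idx], self.feature_names
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "label"
    ) -> "LabeledFeatureTable":
        names = tuple(c for c in df.columns if c != label_column)
        return cls(df[list(names)].to_numpy(), df[label_column].to_numpy(), names)

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df[label_column] = self.labels
        return df


@dataclass
class SelectionMask:
    """Binary feature-subset indicator."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.ndim != 1 or not self.bits.any():
            raise ValueError("a selection mask must select at least one feature")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def total(self) -> int:
        return self.bits.size

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class SelectionCost:
    """Decomposed value of the selection objective."""

    total: float
    accuracy: float
    fscore_ratio: float
    w1: float = 0.6
    w2: float = 0.4


def feature_fscore(column: np.ndarray, labels: np.ndarray) -> float:
    """Fisher-style F-score of one feature column for binary labels.

    F = [(m+ - m)^2 + (m- - m)^2] / [s+^2 + s-^2], where m is the overall
    mean, m+/- the class means, and s+/-^2 the unbiased class variances.
    The denominator is floored at a tiny epsilon, so perfectly separated
    features score large but finite; identical class distributions score 0.
    """
    x = np.asarray(column, dtype=np.float64)
    y = np.asarray(labels)
    pos, neg = x[y == 1], x[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 samples for the F-score")
    m, mp, mn = x.mean(), pos.mean(), neg.mean()
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(ddof=1) + neg.var(ddof=1)
    if num == 0.0:
        return 0.0
    return float(num / max(den, VARIANCE_FLOOR))


def feature_fscore_multigroup(column: np.ndarray, labels: np.ndarray) -> float:
    """Secondary F-score variant generalized to any number of classes.

    Between-class scatter of the group means over the pooled within-class
    variance; reduces to the same ordering as :func:`feature_fscore` for
    two balanced classes.  Exposed as a descriptive statistic only — the
    selection cost uses :func:`feature_fscore`.
    """
    x = np.asarray(column, dtype=np.float64)
    y = np.asarray(labels)
    m = x.mean()
    num = 0.0
    den = 0.0
    for cls in np.unique(y):
        g = x[y == cls]
        if len(g) < 2:
            raise ValueError("each class needs at least 2 samples")
        num += (g.mean() - m) ** 2
        den += g.var(ddof=1)
    if num == 0.0:
        return 0.0
    return float(num / max(den, VARIANCE_FLOOR))


def _default_classifier() -> object:
    # Fixed default hyperparameters: the wrapper objective stays cheap and
    # well-defined (no nested tuning inside the selection loop).
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))


def subset_accuracy(
    table: LabeledFeatureTable,
    mask: SelectionMask,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold cross-validated accuracy of the default SVM."""
    counts = np.bincount((table.labels == 1).astype(int), minlength=2)
    usable = int(min(folds, counts.min()))
    if usable < folds:
        logger.warning("reducing folds from %d to %d (small class)", folds, usable)
    if usable < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    cv = StratifiedKFold(n_splits=usable, shuffle=True, random_state=seed)
    scores = cross_val_score(
        _default_classifier(),
        table.values[:, mask.indices],
        table.labels,
        cv=cv,
        scoring="accuracy",
    )
    return float(scores.mean())


def selection_cost(
    table: LabeledFeatureTable,
    mask: SelectionMask,
    w1: float = 0.6,
    w2: float = 0.4,
    folds: int = 5,
    seed: int = 0,
    fscores: np.ndarray | None = None,
    accuracy: float | None = None,
) -> SelectionCost:
    """Evaluate the two-term selection objective for one mask.

    ``fscores`` (all features) and ``accuracy`` may be passed in to avoid
    recomputation inside optimization loops.
    """
    if fscores is None:
        fscores = np.array(
            [feature_fscore(table.values[:, j], table.labels) for j in range(table.n_features)]
        )
    if accuracy is None:
        accuracy = subset_accuracy(table, mask, folds=folds, seed=seed)
    total_f = float(fscores.sum())
    if total_f > 0:
        ratio = float(fscores[mask.indices].sum() / total_f)
    else:
        ratio = mask.selected_count / mask.total
        logger.warning("all F-scores are zero; ratio term falls back to Mb/Nb")
    total = w1 * (1.0 - accuracy) + w2 * ratio
    return SelectionCost(
        total=total, accuracy=accuracy, fscore_ratio=ratio, w1=w1, w2=w2
    )


def decode_mask(position: np.ndarray, threshold: float = 0.5) -> SelectionMask:
    """Threshold a continuous position into a mask; repair empty decodes.

    An all-below-threshold position selects the single feature with the
    highest coordinate value.
    """
    bits = (np.asarray(position) > threshold).astype(np.int8)
    if not bits.any():
        bits[int(np.argmax(position))] = 1
    return SelectionMask(bits)


def select_features(
    table: LabeledFeatureTable,
    cfg: CSOConfig | None = None,
    threshold: float = 0.5,
    w1: float = 0.6,
    w2: float = 0.4,
    folds: int = 5,
    seed: int | None = None,
    mode: str = "ACSO",
) -> tuple[SelectionMask, SelectionCost]:
    """Search the feature-subset space with the amended competitive search.

    The optimizer works on the continuous unit box; positions decode to
    masks at the given threshold.  Costs are cached per decoded mask, so
    the expensive cross-validation runs once per distinct subset.
    """
    cfg = cfg or CSOConfig(n=30, iterations=60)
    fscores = np.array(
        [feature_fscore(table.values[:, j], table.labels) for j in range(table.n_features)]
    )
    acc_seed = 0 if seed is None else int(seed) % (2**31)
    cache: dict[bytes, SelectionCost] = {}

    def cost_of(mask: SelectionMask) -> SelectionCost:
        key = mask.bits.tobytes()
        if key not in cache:
            cache[key] = selection_cost(
                table, mask, w1=w1, w2=w2, folds=folds, seed=acc_seed, fscores=fscores
            )
        return cache[key]

    def objective(position: np.ndarray) -> float:
        return cost_of(decode_mask(position, threshold)).total

    space = SearchSpace.cube(table.n_features, 0.0, 1.0)
    result = optimize(objective, space, cfg, mode=mode, seed=seed)
    best_mask = decode_mask(result.best_position, threshold)
    return best_mask, cost_of(best_mask)
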