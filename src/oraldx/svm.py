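"""Soft-margin RBF SVM classification with competitive-search tuning.

The decision function is the kernel expansion

    z = sgn( sum_i y_i alpha_i K(x, x_i) + beta )

over the support vectors.  Hyperparameters (the regularization constant C
and the RBF width gamma) are tuned by the amended competitive search,
minimizing the half-sum-of-squares error between true and predicted labels
on stratified validation folds.  Features are standardized with statistics
computed on the training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .optimizer import CSOConfig, OptimizationResult, SearchSpace, optimize
from .selection import LabeledFeatureTable, SelectionMask

#: Hyperparameter search box: log10 C and log10 gamma.
LOG10_C_BOUNDS = (-2.0, 3.0)
LOG10_GAMMA_BOUNDS = (-4.0, 1.0)


class TrainingError(ValueError):
    """Training input is unusable (e.g. a single class)."""


@dataclass
class SVMModel:
    """A fitted SVM plus the preprocessing needed to apply it."""

    svc: SVC
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_indices: np.ndarray
    C: float
    gamma: float

    def _transform(self, samples: np.ndarray) -> np.ndarray:
        x = np.asarray(samples, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] == len(self.scaler_mean):
            pass  # already masked columns
        elif x.shape[1] > len(self.scaler_mean):
            x = x[:, self.feature_indices]
        else:
            raise ValueError(
                f"expected {len(self.scaler_mean)} (or full-table) columns, got {x.shape[1]}"
            )
        return (x - self.scaler_mean) / self.scaler_scale

    def decision_function(self, samples: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._transform(samples))


def train_svm(
    table: LabeledFeatureTable,
    mask: SelectionMask | None = None,
    C: float = 1.0,
    gamma: float | str = "scale",
) -> SVMModel:
    """Fit a soft-margin RBF SVM on the masked, standardized columns."""
    if len(np.unique(table.labels)) < 2:
        raise TrainingError("training requires both classes")
    idx = mask.indices if mask is not None else np.arange(table.n_features)
    x = table.values[:, idx]
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    if gamma == "scale":
        var = xs.var()
        g = 1.0 / (xs.shape[1] * var) if var > 0 else 1.0
    elif gamma == "auto":
        g = 1.0 / xs.shape[1]
    else:
        g = float(gamma)
    svc = SVC(kernel="rbf", C=C, gamma=g)
    svc.fit(xs, table.labels)
    return SVMModel(
        svc=svc,
        scaler_mean=mean,
        scaler_scale=scale,
        feature_indices=idx,
        C=float(C),
        gamma=g,
    )


def predict(model: SVMModel, samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values; a decision value of 0 maps to +1."""
    dec = model.decision_function(samples)
    labels = np.where(dec >= 0, 1, -1)
    return labels, dec


def decision_kernel_sum(model: SVMModel, samples: np.ndarray) -> np.ndarray:
    """Explicit kernel-sum form of the decision function.

    Recomputes z = sum_i y_i alpha_i K(x, x_i) + beta by a direct loop over
    the stored support vectors; used as an independent oracle against the
    library decision values.
    """
    xs = model._transform(samples)
    sv = model.svc.support_vectors_
    coef = model.svc.dual_coef_[0]  # already y_i * alpha_i
    beta = model.svc.intercept_[0]
    out = np.empty(len(xs))
    for r, x in enumerate(xs):
        acc = 0.0
        for i in range(len(sv)):
            diff = x - sv[i]
            acc += coef[i] * np.exp(-model.gamma * float(diff @ diff))
        out[r] = acc + beta
    return out


def mse_objective(model: SVMModel, samples: np.ndarray, labels: np.ndarray) -> float:
    """Half-sum-of-squares error between true and predicted labels.

    MSE = 1/2 sum (z* - z)^2 with z the predicted label in {-1, +1}; each
    misclassified sample contributes (±2)^2 / 2 = 2.
    """
    if len(labels) == 0:
        raise ValueError("validation set must be non-empty")
    pred, _ = predict(model, samples)
    return 0.5 * float(np.sum((np.asarray(labels) - pred) ** 2))


@dataclass
class TuningResult:
    C: float
    gamma: float
    mse: float
    model: SVMModel
    optimization: OptimizationResult


def _default_log_point(n_features: int) -> np.ndarray:
    # C=1, gamma='scale' ~ 1/n_features on standardized data
    return np.array([0.0, -np.log10(n_features)])


def cv_mse(
    table: LabeledFeatureTable,
    mask: SelectionMask | None,
    C: float,
    gamma: float,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean tuning objective over stratified folds (leak-free scaling)."""
    counts = np.bincount((table.labels == 1).astype(int), minlength=2)
    usable = int(min(folds, counts.min()))
    if usable < 2:
        raise TrainingError("need at least 2 samples per class to tune")
    cv = StratifiedKFold(n_splits=usable, shuffle=True, random_state=seed)
    total = 0.0
    for train_idx, val_idx in cv.split(table.values, table.labels):
        model = train_svm(table.subset_rows(train_idx), mask, C=C, gamma=gamma)
        total += mse_objective(
            model, table.values[val_idx], table.labels[val_idx]
        )
    return total / usable


def acso_tune(
    table: LabeledFeatureTable,
    mask: SelectionMask | None = None,
    cfg: CSOConfig | None = None,
    folds: int = 5,
    seed: int | None = None,
    mode: str = "ACSO",
) -> TuningResult:
    """Tune (C, gamma) by minimizing the cross-validated MSE with ACSO.

    The search runs over log10 C in [-2, 3] and log10 gamma in [-4, 1].
    The default hyperparameter point is injected into the initial
    population, so tuning can never end worse than the default on the
    tuning objective.
    """
    cfg = cfg or CSOConfig(n=20, iterations=30)
    n_feat = mask.selected_count if mask is not None else table.n_features
    cv_seed = 0 if seed is None else int(seed) % (2**31)
    cache: dict[tuple[float, float], float] = {}

    def objective(position: np.ndarray) -> float:
        key = (round(float(position[0]), 12), round(float(position[1]), 12))
        if key not in cache:
            cache[key] = cv_mse(
                table, mask, C=10.0 ** key[0], gamma=10.0 ** key[1],
                folds=folds, seed=cv_seed,
            )
        return cache[key]

    space = SearchSpace(
        lb=np.array([LOG10_C_BOUNDS[0], LOG10_GAMMA_BOUNDS[0]]),
        ub=np.array([LOG10_C_BOUNDS[1], LOG10_GAMMA_BOUNDS[1]]),
    )
    result = optimize(
        objective,
        space,
        cfg,
        mode=mode,
        seed=seed,
        initial_positions=_default_log_point(n_feat)[None, :],
    )
    c_best = 10.0 ** float(result.best_position[0])
    g_best = 10.0 ** float(result.best_position[1])
    model = train_svm(table, mask, C=c_best, gamma=g_best)
    return TuningResult(
        C=c_best, gamma=g_best, mse=result.best_cost, model=model, optimization=result
    )
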