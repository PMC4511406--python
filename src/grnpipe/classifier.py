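"""Per-relation-type soft-margin classifier with asymmetric regularisation.

The decision function solves

    min_{w,b,xi}  1/2 ||w||^2  +  C+ sum_{x in X+} xi_x  +  C- sum_{x in X-} xi_x

subject to the usual margin constraints with slack xi_x >= 0, in the feature
space induced by a Gaussian RBF kernel.  Distant-supervision noise lives in
the positive class only (distant positives may be spurious), so C+ < C-
softens the margin for positives while keeping negatives firmly penalised.
With C+ = C- the problem reduces to the standard single-C formulation.

The quadratic program is delegated to libsvm via scikit-learn; this module
owns the objective configuration (per-class penalties), determinism and
model-selection bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["TrainConfig", "DecisionModel", "train", "predict", "grid_search"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters: per-class penalties C+ / C- and RBF width gamma."""

    c_pos: float = 10.0
    c_neg: float = 10.0
    kernel_gamma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_pos <= 0 or self.c_neg <= 0 or self.kernel_gamma <= 0:
            raise ValueError("c_pos, c_neg and kernel_gamma must be > 0")


@dataclass
class DecisionModel:
    """Fitted decision function; score > 0 predicts the positive class."""

    svc: SVC
    config: TrainConfig

    def score(self, X) -> np.ndarray:
        return self.svc.decision_function(X)

    def predict(self, X) -> np.ndarray:
        return (self.score(X) > 0).astype(int)


class DegenerateTrainingError(ValueError):
    """Training set contains a single class."""


def train(X, y: Sequence[int], cfg: TrainConfig | None = None) -> DecisionModel:
    """Fit the asymmetric soft-margin RBF machine.

    Per-class penalties are realised as class weights on a base C of 1, so
    the effective penalty of class k is exactly ``cfg.c_pos`` / ``cfg.c_neg``.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(y)
    classes = set(np.unique(y))
    if not classes.issubset({0, 1}):
        raise ValueError("labels must be 0/1")
    if len(classes) < 2:
        raise DegenerateTrainingError(
            "training requires at least one point of each class"
        )
    svc = SVC(
        C=1.0,
        kernel="rbf",
        gamma=cfg.kernel_gamma,
        class_weight={1: cfg.c_pos, 0: cfg.c_neg},
        tol=1e-7,
        random_state=cfg.seed,
    )
    svc.fit(X, y)
    return DecisionModel(svc=svc, config=cfg)


def predict(model: DecisionModel, X) -> np.ndarray:
    """Binary labels from the sign of the decision score; deterministic."""
    n_fit = model.svc.shape_fit_[1]
    if X.shape[1] != n_fit:
        raise ValueError(f"dimension mismatch: model has {n_fit}, points have {X.shape[1]}")
    return model.predict(X)


def _binary_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, fn


def _criterion_value(name: str, y_true, y_pred, beta: float = 1.0) -> float:
    """Selection criteria; larger is better (SER is negated)."""
    tp, fp, fn = _binary_counts(np.asarray(y_true), np.asarray(y_pred))
    if name == "ser":
        # local slot error rate of a binary task: no substitutions, so
        # SER = (FP + FN) / #positives
        npos = tp + fn
        return -((fp + fn) / npos) if npos else -np.inf
    b2 = 1.0 if name == "f1" else beta**2
    denom = (1 + b2) * tp + b2 * fn + fp
    return (1 + b2) * tp / denom if denom else 0.0


def grid_search(
    X,
    y: Sequence[int],
    grid: Sequence[TrainConfig],
    folds: int = 25,
    criterion: str = "f1",
    beta: float = 1.0,
    seed: int = 0,
) -> tuple[TrainConfig, dict[TrainConfig, list[float]]]:
    """Cross-validated hyperparameter selection over a config lattice.

    Fold assignment is deterministic in ``seed``.  Folds whose training part
    lacks a class are skipped with a warning.  Ties are broken by the
    lexicographically smallest (c_pos, c_neg, gamma).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not grid:
        raise ValueError("empty grid")
    y = np.asarray(y)
    n_splits = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    if n_splits < folds:
        warnings.warn(
            f"reducing folds from {folds} to {n_splits} (class sizes)", stacklevel=2
        )
    skf = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed)
    fold_scores: dict[TrainConfig, list[float]] = {cfg: [] for cfg in grid}
    for tr, te in skf.split(np.zeros(len(y)), y):
        if len(set(y[tr])) < 2:
            warnings.warn("skipping fold without both classes", stacklevel=2)
            continue
        for cfg in grid:
            model = train(X[tr], y[tr], cfg)
            y_hat = model.predict(X[te])
            fold_scores[cfg].append(_criterion_value(criterion, y[te], y_hat, beta))
    def sort_key(cfg: TrainConfig):
        mean = float(np.mean(fold_scores[cfg])) if fold_scores[cfg] else -np.inf
        return (-mean, cfg.c_pos, cfg.c_neg, cfg.kernel_gamma)
    best = min(grid, key=sort_key)
    return best, fold_scores


#: overridable default lattice for model selection
DEFAULT_GRID = tuple(
    TrainConfig(c_pos=cp, c_neg=cn, kernel_gamma=g)
    for cp in (0.1, 1.0, 10.0, 100.0)
    for cn in (0.1, 1.0, 10.0, 100.0)
    for g in (0.01, 0.1, 1.0)
)
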