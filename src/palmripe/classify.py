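"""SVM grid-search cross-validation protocol for ripeness grading.

Three feature sets are compared on the same fruit cohort: the fruit-battery
load voltage V_L alone, the computer-vision color feature R_ave/G_ave alone,
and their combination.  For each, a grid of SVM hyperparameters (cost 1, 10,
100; gamma 1, 0.1, 0.01; kernel linear or RBF — 18 configurations) is scored
by stratified k-fold cross validation (8 folds by default): per fold the
features are standardized on the training portion, the SVM is trained, and
held-out accuracy is recorded.  The winning configuration maximizes mean
accuracy; ties are broken by the smaller fold-to-fold standard deviation,
then by grid order.  Gamma is carried for linear-kernel rows for a complete
table but does not affect a linear SVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .moisture import RipenessLabel

__all__ = [
    "FeatureKind",
    "FeatureSet",
    "GridConfig",
    "GridResult",
    "enumerate_grid",
    "cv_accuracy",
    "grid_search",
    "best_config",
    "DEFAULT_COSTS",
    "DEFAULT_GAMMAS",
    "DEFAULT_KERNELS",
    "DEFAULT_FOLDS",
]

DEFAULT_COSTS: tuple[float, ...] = (1.0, 10.0, 100.0)
DEFAULT_GAMMAS: tuple[float, ...] = (1.0, 0.1, 0.01)
DEFAULT_KERNELS: tuple[str, ...] = ("linear", "rbf")
DEFAULT_FOLDS = 8

#: Feature-set names, as used in reports.
FeatureKind = str  # "battery" | "vision" | "combined"


@dataclass(frozen=True)
class GridConfig:
    """One SVM hyperparameter combination."""

    cost: float
    gamma: float
    kernel: str

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")


@dataclass(frozen=True)
class GridResult:
    """Cross-validated score of one configuration."""

    cost: float
    gamma: float
    kernel: str
    accuracy: float
    std: float


@dataclass
class FeatureSet:
    """Feature matrix and labels for one modality.

    ``kind`` is "battery" (V_L), "vision" (R_ave/G_ave) or "combined";
    ``matrix`` is (n, d) with d = 1 or 2; ``labels`` holds one ripeness
    grade per sample.
    """

    kind: FeatureKind
    matrix: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] == 1 and len(self.labels) > 1:
            self.matrix = self.matrix.T
        self.labels = np.asarray(
            [l.value if isinstance(l, RipenessLabel) else str(l) for l in self.labels]
        )
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("feature matrix and labels disagree on sample count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def enumerate_grid(
    costs: Sequence[float] = DEFAULT_COSTS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
    kernels: Sequence[str] = DEFAULT_KERNELS,
) -> list[GridConfig]:
    """Cartesian hyperparameter grid, cost-major then gamma then kernel.

    The default axes yield 18 configurations.
    """
    if not costs or not gammas or not kernels:
        raise ValueError("every grid axis must be non-empty")
    return [
        GridConfig(cost=float(c), gamma=float(g), kernel=str(k))
        for c in costs
        for g in gammas
        for k in kernels
    ]


def cv_accuracy(
    features: FeatureSet,
    config: GridConfig,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    std_ddof: int = 0,
) -> tuple[float, float]:
    """Stratified k-fold cross-validated accuracy of one configuration.

    Per fold, features are standardized on the training split only, the SVM
    is trained with ``config`` and scored on the held-out fold.  Returns the
    mean and the standard deviation of the fold accuracies (population
    convention by default; ``std_ddof=1`` switches to the sample convention).
    """
    if features.n < k:
        raise ValueError(f"need at least k={k} samples, got {features.n}")
    n_classes = len(np.unique(features.labels))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(features.matrix, features.labels):
        x_train, y_train = features.matrix[train], features.labels[train]
        if len(np.unique(y_train)) < n_classes:
            warnings.warn(
                "a fold's training split is missing a class; fitting on available classes",
                stacklevel=2,
            )
        scaler = StandardScaler().fit(x_train)
        clf = SVC(C=config.cost, kernel=config.kernel, gamma=config.gamma)
        clf.fit(scaler.transform(x_train), y_train)
        accs.append(clf.score(scaler.transform(features.matrix[test]), features.labels[test]))
    return float(np.mean(accs)), float(np.std(accs, ddof=std_ddof))


def grid_search(
    features: FeatureSet,
    grid: Iterable[GridConfig] | None = None,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    std_ddof: int = 0,
) -> list[GridResult]:
    """Score every grid configuration; rows follow grid order."""
    if grid is None:
        grid = enumerate_grid()
    results = []
    for cfg in grid:
        acc, std = cv_accuracy(features, cfg, k=k, seed=seed, std_ddof=std_ddof)
        results.append(
            GridResult(cost=cfg.cost, gamma=cfg.gamma, kernel=cfg.kernel, accuracy=acc, std=std)
        )
    return results


def best_config(results: Sequence[GridResult]) -> GridResult:
    """Best row: maximum accuracy, ties by minimum std, then grid order."""
    if not results:
        raise ValueError("no grid results to choose from")
    best = results[0]
    for row in results[1:]:
        if row.accuracy > best.accuracy or (
            row.accuracy == best.accuracy and row.std < best.std
        ):
            best = row
    return best
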