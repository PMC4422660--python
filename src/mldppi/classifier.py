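"""Random-forest classification of protein-pair feature vectors.

The forest follows the classical recipe: N unpruned decision trees, each
fit on a bootstrap resample of the training set (on average ~63.2% unique
examples in-bag), with a fresh random subset of M candidate features at
every split, chosen by the maximum decrease in Gini impurity. Prediction
aggregates the trees by majority vote; the score is the fraction of trees
voting "interacting". Out-of-bag (OOB) votes give an internal accuracy
estimate without a held-out set.

The ensemble itself is delegated to scikit-learn's
:class:`~sklearn.ensemble.RandomForestClassifier`, which implements exactly
this contract; :class:`ReferenceGiniTree` is a small self-contained CART
used to cross-check single-tree behaviour in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .metrics import METRIC_NAMES, ConfusionCounts, MetricReport, confusion, metrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters: ensemble size N and feature-subset size M.

    Defaults N=60, M=10 are the standard operating point for the 1134-dim
    pair features; performance is insensitive to M over a wide range and
    saturates in N beyond a few tens of trees. Trees are unpruned and split
    on Gini impurity.
    """

    n_trees: int = 60
    features_per_split: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.features_per_split < 1:
            raise ValueError(
                f"features_per_split must be >= 1, got {self.features_per_split}"
            )


@dataclass
class TrainedForest:
    """A fitted forest plus its configuration and OOB accuracy estimate."""

    estimator: RandomForestClassifier
    config: ForestConfig
    feature_dimension: int
    oob_accuracy: float | None = None


@dataclass(frozen=True)
class FoldResult:
    """Confusion counts and metrics for one cross-validation fold."""

    fold_index: int
    confusion: ConfusionCounts
    metrics: MetricReport


@dataclass
class CVReport:
    """Per-fold results with per-metric mean and (sample) std across folds."""

    folds: list[FoldResult]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            values = {
                name: np.array([getattr(f.metrics, name) for f in self.folds])
                for name in METRIC_NAMES
            }
            self.mean = {k: float(v.mean()) for k, v in values.items()}
            self.std = {
                k: float(v.std(ddof=1)) if len(v) > 1 else 0.0
                for k, v in values.items()
            }

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        """Tabular report: one row per fold plus mean/std rows."""
        scale = 100.0 if percent else 1.0
        rows = []
        for f in self.folds:
            c = f.confusion
            rows.append(
                {"fold": f.fold_index, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                | {k: round(scale * v, 2) for k, v in f.metrics.as_dict().items()}
            )
        blank = {"tp": "", "fp": "", "tn": "", "fn": ""}
        rows.append({"fold": "mean"} | blank | {k: round(scale * v, 2) for k, v in self.mean.items()})
        rows.append({"fold": "std"} | blank | {k: round(scale * v, 2) for k, v in self.std.items()})
        return pd.DataFrame(rows)


def bootstrap_indices(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """One bootstrap resample: n draws with replacement from 0..n−1."""
    return rng.integers(0, n_samples, size=n_samples)


def _check_training_input(X: np.ndarray, y: np.ndarray, config: ForestConfig) -> None:
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"feature rows ({X.shape[0]}) != labels ({y.shape[0]})")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class; need both 0 and 1")
    if config.features_per_split > X.shape[1]:
        raise ValueError(
            f"features_per_split={config.features_per_split} exceeds "
            f"feature dimension {X.shape[1]}"
        )


def train(X, y, config: ForestConfig = ForestConfig()) -> TrainedForest:
    """Fit a seeded random forest of unpruned Gini trees on pair features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_training_input(X, y, config)
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.features_per_split,
        max_depth=None,  # unpruned
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # with few trees some samples are never out-of-bag; OOB is then unusable
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    oob = float(est.oob_score_) if np.isfinite(est.oob_score_) else None
    return TrainedForest(est, config, X.shape[1], oob)


def predict(model: TrainedForest, X) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and vote-fraction scores in [0, 1].

    The score is the fraction of trees voting class 1; the label is 1 iff
    score >= 0.5 (exact ties go to the positive class).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_dimension:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match model dimension {model.feature_dimension}"
        )
    votes = np.zeros(X.shape[0])
    for tree in model.estimator.estimators_:
        votes += tree.predict(X)
    scores = votes / len(model.estimator.estimators_)
    return (scores >= 0.5).astype(int), scores


def cross_validate(
    X,
    y,
    config: ForestConfig = ForestConfig(),
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of the forest on pair features.

    Each fold acts once as an independent held-out test set for a forest
    trained on the remaining folds. Metrics are computed on each fold's
    confusion counts and then averaged (mean ± sample std across folds).
    Fold assignment, bootstraps and splits are deterministic given *seed*
    and ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    class_counts = np.bincount(y, minlength=2)
    if k > class_counts.min():
        raise ValueError(
            f"k={k} exceeds the smaller class count ({class_counts.min()}); "
            "every stratified fold needs both classes"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        model = train(X[train_idx], y[train_idx], config)
        y_pred, _ = predict(model, X[test_idx])
        c = confusion(y[test_idx], y_pred)
        folds.append(FoldResult(i, c, metrics(c)))
    return CVReport(folds)


def parameter_sweep(
    X,
    y,
    m_values: Sequence[int],
    n_values: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate every (M, N) combination; one aggregate row each.

    Columns: ``M``, ``N``, then ``<metric>_mean`` / ``<metric>_std`` as
    fractions for each of the seven metrics.
    """
    rows = []
    for m in m_values:
        for n in n_values:
            report = cross_validate(
                X, y, ForestConfig(n_trees=n, features_per_split=m, seed=seed), k, seed
            )
            row: dict[str, float] = {"M": m, "N": n}
            for name in METRIC_NAMES:
                row[f"{name}_mean"] = report.mean[name]
                row[f"{name}_std"] = report.std[name]
            rows.append(row)
            logger.info("sweep M=%d N=%d: acc=%.4f", m, n, row["acc_mean"])
    return pd.DataFrame(rows)


class ReferenceGiniTree:
    """Minimal from-scratch unpruned CART with per-node random feature subsets.

    Used as an independent check of the tree contract (Gini splits, purity
    stopping, optional M-feature sampling); not optimised for large data.
    """

    def __init__(self, max_features: int | None = None, seed: int = 0):
        self.max_features = max_features
        self.seed = seed
        self._tree: tuple | None = None

    @staticmethod
    def _gini(y: np.ndarray) -> float:
        if y.size == 0:
            return 0.0
        p = np.bincount(y, minlength=2) / y.size
        return 1.0 - float((p ** 2).sum())

    def _best_split(self, X, y, rng) -> tuple[int, float] | None:
        n_feat = X.shape[1]
        m = self.max_features or n_feat
        candidates = rng.choice(n_feat, size=min(m, n_feat), replace=False)
        parent = self._gini(y)
        best, best_drop = None, 1e-12
        for j in candidates:
            values = np.unique(X[:, j])
            for lo, hi in zip(values[:-1], values[1:]):
                thr = (lo + hi) / 2.0
                left = X[:, j] <= thr
                wl = left.mean()
                drop = parent - wl * self._gini(y[left]) - (1 - wl) * self._gini(y[~left])
                if drop > best_drop:
                    best, best_drop = (int(j), float(thr)), drop
        return best

    def _grow(self, X, y, rng):
        if np.unique(y).size == 1:
            return ("leaf", int(y[0]))
        split = self._best_split(X, y, rng)
        if split is None:
            return ("leaf", int(np.bincount(y, minlength=2).argmax()))
        j, thr = split
        left = X[:, j] <= thr
        return (
            "node", j, thr,
            self._grow(X[left], y[left], rng),
            self._grow(X[~left], y[~left], rng),
        )

    def fit(self, X, y) -> "ReferenceGiniTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self._tree = self._grow(X, y, np.random.default_rng(self.seed))
        return self

    def _predict_one(self, x, node):
        while node[0] == "node":
            _, j, thr, left, right = node
            node = left if x[j] <= thr else right
        return node[1]

    def predict(self, X) -> np.ndarray:
        if self._tree is None:
            raise RuntimeError("tree is not fitted")
        X = np.asarray(X, dtype=float)
        return np.array([self._predict_one(x, self._tree) for x in X], dtype=int)
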