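"""The four classifier configurations and subject-grouped cross-validation.

- LR: plain (unpenalized) binomial logistic regression.
- NB: naive Bayes with Gaussian-kernel-smoothed class-conditional densities
  per feature (normal-reference bandwidth), evaluated on a grid.
- SVM: RBF kernel, kernel scale 1.7 (gamma = 1/1.7^2), box constraint C = 1.
- RF: random-subspace ensemble of 30 decision trees (attribute bagging with
  ceil(sqrt(d)) features per learner, all training rows).

RBF-SVM training cost grows quadratically with the number of epochs, so
``ModelSpec.max_train_samples`` can cap training at a stratified,
seed-controlled subsample; the default model set uses this for the SVM only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "default_model_specs",
    "train",
    "predict_proba",
    "predict_label",
    "cross_validate",
]

ALGORITHMS = ("LR", "NB", "SVM", "RF")


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration on the selected feature set."""

    algorithm: str
    threshold: float = 0.5
    seed: int = 0
    max_train_samples: int | None = None
    svm_kernel_scale: float = 1.7
    svm_box_constraint: float = 1.0
    rf_n_learners: int = 30

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def default_model_specs(seed: int = 0, svm_max_train: int | None = 8000) -> list[ModelSpec]:
    """The four standard configurations; only the SVM caps its training size."""
    return [
        ModelSpec("LR", seed=seed),
        ModelSpec("NB", seed=seed),
        ModelSpec("SVM", seed=seed, max_train_samples=svm_max_train),
        ModelSpec("RF", seed=seed),
    ]


class _KernelNaiveBayes:
    """Per-feature Gaussian-KDE class-conditional densities on a grid.

    Bandwidth per feature and class follows the normal reference rule
    (Silverman). Densities are evaluated on a 512-point grid and
    interpolated at predict time, flooring at a small positive value so a
    single out-of-range feature cannot veto the posterior.
    """

    _GRID_SIZE = 512
    _FLOOR = 1e-12

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KernelNaiveBayes":
        self.classes_ = np.unique(y)
        self.log_priors_ = np.log(
            np.array([(y == c).mean() for c in self.classes_])
        )
        self.grids_: list[list[np.ndarray]] = []
        self.log_dens_: list[list[np.ndarray]] = []
        for c in self.classes_:
            Xc = X[y == c]
            grids, dens = [], []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                lo, hi = col.min(), col.max()
                pad = 0.5 * (hi - lo) + 1e-6
                grid = np.linspace(lo - pad, hi + pad, self._GRID_SIZE)
                if col.std() == 0:
                    d = np.full(grid.size, self._FLOOR)
                    d[np.argmin(np.abs(grid - col[0]))] = 1.0
                else:
                    d = stats.gaussian_kde(col, bw_method="silverman")(grid)
                grids.append(grid)
                dens.append(np.log(np.maximum(d, self._FLOOR)))
            self.grids_.append(grids)
            self.log_dens_.append(dens)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        log_post = np.tile(self.log_priors_, (X.shape[0], 1))
        for ci in range(self.classes_.size):
            for j in range(X.shape[1]):
                log_post[:, ci] += np.interp(
                    X[:, j], self.grids_[ci][j], self.log_dens_[ci][j],
                    left=np.log(self._FLOOR), right=np.log(self._FLOOR),
                )
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


@dataclass
class TrainedModel:
    """A fitted classifier bound to its feature schema and training subjects."""

    spec: ModelSpec
    feature_names: tuple[str, ...]
    estimator: Any
    train_subjects: frozenset = field(default_factory=frozenset)

    def _matrix(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise KeyError(
                    f"feature schema mismatch: missing columns {missing}; "
                    f"model was trained on {list(self.feature_names)}"
                )
            return X.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature schema mismatch: expected {len(self.feature_names)} columns, "
                f"got {X.shape[1]}"
            )
        return X


def _subsample(y: np.ndarray, size: int, seed: int) -> np.ndarray:
    """Label-stratified row subsample without replacement."""
    rng = np.random.default_rng(seed)
    chosen = []
    for c in np.unique(y):
        pool = np.flatnonzero(y == c)
        quota = max(1, int(round(size * pool.size / y.size)))
        chosen.append(rng.choice(pool, size=min(quota, pool.size), replace=False))
    idx = np.concatenate(chosen)
    idx.sort()
    return idx


def train(
    spec: ModelSpec,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray | None = None,
) -> TrainedModel:
    """Fit one configuration; reproducible given ``spec.seed``."""
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_names = tuple(f"f{i}" for i in range(Xa.shape[1]))
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")

    train_subjects = frozenset(np.unique(subjects)) if subjects is not None else frozenset()
    if spec.max_train_samples is not None and Xa.shape[0] > spec.max_train_samples:
        idx = _subsample(y, spec.max_train_samples, spec.seed)
        Xa, y = Xa[idx], y[idx]

    if spec.algorithm == "LR":
        # unpenalized binomial GLM (C=inf disables regularization)
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    elif spec.algorithm == "NB":
        est = _KernelNaiveBayes()
    elif spec.algorithm == "SVM":
        est = SVC(
            kernel="rbf",
            gamma=1.0 / spec.svm_kernel_scale**2,
            C=spec.svm_box_constraint,
            random_state=spec.seed,
        )
    else:  # RF
        d = Xa.shape[1]
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=spec.seed),
            n_estimators=spec.rf_n_learners,
            max_features=int(np.ceil(np.sqrt(d))),
            bootstrap=False,
            bootstrap_features=False,
            random_state=spec.seed,
            n_jobs=1,
        )
    est.fit(Xa, y)
    return TrainedModel(spec, feature_names, est, train_subjects)


def predict_proba(model: TrainedModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Class-1 score in [0, 1] per row."""
    Xa = model._matrix(X)
    est = model.estimator
    if model.spec.algorithm == "SVM":
        # logistic squash of the margin: monotone, in (0, 1), 0.5 at the
        # boundary; slope 3 so points beyond the support vectors (|f| >= 1)
        # score decisively (>0.9 / <0.1)
        return 1.0 / (1.0 + np.exp(-3.0 * est.decision_function(Xa)))
    proba = est.predict_proba(Xa)
    classes = list(est.classes_)
    return proba[:, classes.index(1)]


def predict_label(model: TrainedModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    return (predict_proba(model, X) >= model.spec.threshold).astype(int)


def _partition_groups(groups: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    unique = np.unique(groups)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > unique.size:
        raise ValueError(f"k={k} exceeds the number of groups ({unique.size})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique)
    return [np.sort(chunk) for chunk in np.array_split(order, k)]


def cross_validate(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray | None,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-wise k-fold CV: folds partition subjects, never epochs.

    Fold sizes (in groups) differ by at most one. Returns one row per fold
    with confusion counts and AUC. Passing ``groups=None`` falls back to
    epoch-level folds (each row its own group), which leaks within-subject
    correlation across folds and is provided for comparison only.
    """
    from .evaluation import roc_auc  # local import to avoid a cycle

    y = np.asarray(y)
    groups = np.arange(y.size) if groups is None else np.asarray(groups)
    folds = _partition_groups(groups, k, seed)
    rows = []
    for fold_idx, held_out in enumerate(folds):
        test_mask = np.isin(groups, held_out)
        model = train(spec, X[~test_mask], y[~test_mask], subjects=groups[~test_mask])
        scores = predict_proba(model, X[test_mask])
        labels = predict_label(model, X[test_mask])
        yt = y[test_mask]
        _, _, auc = roc_auc(scores, yt)
        rows.append(
            {
                "fold": fold_idx,
                "n_groups": held_out.size,
                "n_epochs": int(test_mask.sum()),
                "tp": int(((labels == 1) & (yt == 1)).sum()),
                "fp": int(((labels == 1) & (yt == 0)).sum()),
                "tn": int(((labels == 0) & (yt == 0)).sum()),
                "fn": int(((labels == 0) & (yt == 1)).sum()),
                "auc": auc,
            }
        )
    return pd.DataFrame(rows)
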