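"""Feature normalization and selection: min-max scaling, diagonal
neighborhood component analysis (NCA) ranking, two-sample t-test filtering,
and top-k adoption.

The NCA here is the feature-weighting variant for classification: it learns
one non-negative weight per feature by maximizing the expected leave-one-out
soft classification accuracy

    F(w) = (1/n) sum_i p_i  -  lambda * sum_r w_r^2,
    p_i   = sum_{j != i, y_j = y_i} p_ij,
    p_ij  = exp(-d_ij / sigma) / sum_{k != i} exp(-d_ik / sigma),
    d_ij  = sum_r w_r^2 |x_ir - x_jr|          (weighted L1 distance)

via monotone backtracking gradient ascent. Regularization shrinks weights of
uninformative features toward zero, so the learned weights rank features.
Fitting is O(n^2) in the number of epochs, so a stratified, seed-controlled
subsample caps n.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qeeg_features import FEATURE_REGISTRY

__all__ = [
    "NormalizationParams",
    "NCAConfig",
    "SelectionResult",
    "fit_minmax",
    "apply_minmax",
    "nca_objective",
    "nca_feature_weights",
    "ttest_pvalues",
    "select_features",
    "fit_selection",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max learned on the derivation split only."""

    feature_names: tuple[str, ...]
    minima: np.ndarray
    maxima: np.ndarray

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Map derivation min->0 and max->1; values outside extrapolate
        (no clipping); constant columns map to 0."""
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns {missing}")
        span = self.maxima - self.minima
        out = {}
        for i, name in enumerate(self.feature_names):
            col = X[name].to_numpy(dtype=float)
            out[name] = (col - self.minima[i]) / span[i] if span[i] > 0 else np.zeros(col.size)
        return pd.DataFrame(out, index=X.index)


def fit_minmax(X: pd.DataFrame, feature_names: tuple[str, ...] | None = None) -> NormalizationParams:
    if len(X) < 2:
        raise ValueError("need at least 2 rows to fit min-max normalization")
    if feature_names is None:
        feature_names = tuple(X.columns)
    vals = X.loc[:, list(feature_names)].to_numpy(dtype=float)
    minima, maxima = vals.min(axis=0), vals.max(axis=0)
    constant = maxima <= minima
    if constant.any():
        names = [feature_names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant feature columns map to 0: {names}", stacklevel=2)
    return NormalizationParams(tuple(feature_names), minima, maxima)


def apply_minmax(params: NormalizationParams, X: pd.DataFrame) -> pd.DataFrame:
    return params.transform(X)


@dataclass(frozen=True)
class NCAConfig:
    """Hyperparameters of the NCA ranking stage.

    ``regularization`` of None means 1/n after subsampling; ``sigma`` is the
    kernel length scale (1.0 is appropriate on min-max-normalized features).
    """

    regularization: float | None = None
    sigma: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6
    subsample: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regularization is not None and self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def _pairwise_abs_diff(X: np.ndarray) -> np.ndarray:
    """|x_ir - x_jr| as an (n, n, d) float32 tensor."""
    return np.abs(X[:, None, :] - X[None, :, :]).astype(np.float32)


def nca_objective(
    w: np.ndarray, Z: np.ndarray, same: np.ndarray, sigma: float, lam: float,
    need_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Objective F(w) and (optionally) its analytic gradient.

    ``Z`` is the pairwise |x_ir - x_jr| tensor, ``same`` the boolean
    same-class matrix with a False diagonal. A float32 ``Z`` takes fast BLAS
    paths; a float64 ``Z`` is accumulated exactly (used by gradient checks).
    """
    n, _, d = Z.shape
    w2 = w * w
    fast = Z.dtype == np.float32
    if fast:
        D = (Z.reshape(n * n, d) @ w2.astype(np.float32)).astype(float).reshape(n, n)
    else:
        D = np.zeros((n, n))
        for r in range(d):
            D += w2[r] * Z[:, :, r]
    np.fill_diagonal(D, np.inf)  # excludes i from its own neighbor sum
    K = np.exp(-(D - D.min(axis=1, keepdims=True)) / sigma)
    P = K / K.sum(axis=1, keepdims=True)
    p_i = (P * same).sum(axis=1)
    value = float(p_i.mean() - lam * np.sum(w * w))
    if not need_grad:
        return value, None

    # E[i, r] = sum_k P_ik Z_ikr ; G[r] = sum_{ij in same} P_ij Z_ijr
    Ps = P * same
    if fast:
        E = np.matmul(P[:, None, :].astype(np.float32), Z)[:, 0, :].astype(float)
        G = np.matmul(Ps[:, None, :].astype(np.float32), Z)[:, 0, :].sum(axis=0).astype(float)
    else:
        E = np.empty((n, d))
        G = np.empty(d)
        for r in range(d):
            Zr = Z[:, :, r]
            E[:, r] = (P * Zr).sum(axis=1)
            G[r] = (Ps * Zr).sum()
    grad = (2.0 * w / sigma) * ((p_i @ E - G) / n) - 2.0 * lam * w
    value = float(p_i.mean() - lam * np.sum(w * w))
    return value, grad.astype(float)


def nca_feature_weights(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cfg: NCAConfig = NCAConfig(),
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Per-feature NCA weights (non-negative), deterministic given the seed.

    If the input exceeds ``cfg.subsample`` rows, a label-stratified (and,
    when ``groups`` is given, group-spread) subsample is drawn first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one label per row")
    if np.unique(y).size < 2:
        raise ValueError("NCA needs at least two classes")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    if n > cfg.subsample:
        idx = _stratified_subsample(y, groups, cfg.subsample, rng)
        X, y = X[idx], y[idx]
        n = X.shape[0]

    lam = (1.0 / n) if cfg.regularization is None else cfg.regularization
    Z = _pairwise_abs_diff(X)
    same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)

    w = np.ones(X.shape[1])
    value, grad = nca_objective(w, Z, same, cfg.sigma, lam)
    step = 1.0
    for _ in range(cfg.max_iter):
        improved = False
        for _ in range(40):  # backtracking line search (value-only trials)
            w_new = w + step * grad
            v_new, _ = nca_objective(w_new, Z, same, cfg.sigma, lam, need_grad=False)
            if v_new > value:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        delta = v_new - value
        w = w_new
        value, grad = nca_objective(w, Z, same, cfg.sigma, lam)
        step *= 1.2
        if delta < cfg.tol:
            break
    return np.abs(w)


def _stratified_subsample(
    y: np.ndarray, groups: np.ndarray | None, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Label-stratified subsample; within a label, spread across groups."""
    chosen: list[np.ndarray] = []
    labels, counts = np.unique(y, return_counts=True)
    quotas = np.maximum(1, np.round(size * counts / y.size).astype(int))
    for label, quota in zip(labels, quotas):
        pool = np.flatnonzero(y == label)
        if groups is not None:
            # round-robin across groups so every subject contributes
            order = np.lexsort((rng.random(pool.size), groups[pool]))
            pool = pool[order]
            ranks = np.empty(pool.size, dtype=int)
            g = groups[pool]
            for grp in np.unique(g):
                members = np.flatnonzero(g == grp)
                ranks[members] = np.arange(members.size)
            pool = pool[np.argsort(ranks, kind="stable")]
            chosen.append(pool[: min(quota, pool.size)])
        else:
            chosen.append(rng.choice(pool, size=min(quota, pool.size), replace=False))
    idx = np.concatenate(chosen)
    rng.shuffle(idx)
    return idx


def ttest_pvalues(X: pd.DataFrame | np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance (Student) two-sample t-test per feature.

    Zero variance in both classes yields p = 1 when the means agree (with a
    warning) and p = 0 when they differ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("t-test requires exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both classes need at least 2 rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if degenerate.any():
        same_mean = np.abs(a.mean(axis=0) - b.mean(axis=0)) == 0
        p[degenerate & same_mean] = 1.0
        p[degenerate & ~same_mean] = 0.0
        if (degenerate & same_mean).any():
            warnings.warn("features with zero variance in both classes report p = 1",
                          stacklevel=2)
    return p


@dataclass
class SelectionResult:
    """NCA weights, t-test p-values and the adopted feature subset."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    p_values: np.ndarray
    selected: tuple[str, ...]

    def to_json(self, config_echo: dict | None = None) -> str:
        rank = {name: r for r, name in enumerate(self.selected)}
        payload = {
            "features": {
                name: {
                    "weight": float(self.weights[i]),
                    "p_value": float(self.p_values[i]),
                    "selected": name in rank,
                    "rank": rank.get(name),
                }
                for i, name in enumerate(self.feature_names)
            },
            "selected": list(self.selected),
            "config": config_echo or {},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        payload = json.loads(text)
        names = tuple(payload["features"])
        return cls(
            feature_names=names,
            weights=np.array([payload["features"][n]["weight"] for n in names]),
            p_values=np.array([payload["features"][n]["p_value"] for n in names]),
            selected=tuple(payload["selected"]),
        )


def select_features(
    feature_names: tuple[str, ...],
    weights: np.ndarray,
    p_values: np.ndarray,
    k: int = 10,
    alpha: float = 0.05,
) -> SelectionResult:
    """Adopt the k highest-NCA-weight features among those with p < alpha.

    Ties in weight are broken by feature-registry order. Fewer than k
    survivors are allowed (with a warning); zero survivors is an error.
    """
    weights = np.asarray(weights, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if not (len(feature_names) == weights.size == p_values.size):
        raise ValueError("feature_names, weights and p_values must be aligned")
    surviving = np.flatnonzero(p_values < alpha)
    if surviving.size == 0:
        raise ValueError(f"no feature passes the p < {alpha} filter")
    registry_rank = {name: i for i, name in enumerate(FEATURE_REGISTRY)}
    order = sorted(
        surviving,
        key=lambda i: (-weights[i], registry_rank.get(feature_names[i], len(registry_rank)), i),
    )
    if surviving.size < k:
        warnings.warn(
            f"only {surviving.size} features pass p < {alpha}; selecting all of them",
            stacklevel=2,
        )
    selected = tuple(feature_names[i] for i in order[:k])
    return SelectionResult(tuple(feature_names), weights, p_values, selected)


def fit_selection(
    features: pd.DataFrame,
    feature_names: tuple[str, ...],
    label_col: str = "iicp_label",
    group_col: str = "subject_id",
    cfg: NCAConfig = NCAConfig(),
    k: int = 10,
    alpha: float = 0.05,
) -> tuple[NormalizationParams, SelectionResult]:
    """Normalize -> NCA -> t-test -> top-k, on a derivation feature table."""
    params = fit_minmax(features, feature_names)
    Xn = params.transform(features)
    y = features[label_col].to_numpy()
    groups = features[group_col].to_numpy() if group_col in features.columns else None
    weights = nca_feature_weights(Xn, y, cfg, groups=groups)
    p_values = ttest_pvalues(Xn, y)
    result = select_features(feature_names, weights, p_values, k=k, alpha=alpha)
    return params, result
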