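"""Holdout evaluation: confusion-matrix metrics, ROC/AUC, subject-cluster
bootstrap confidence intervals, and the four-model comparison table.

Epochs from one animal are strongly dependent, so confidence intervals come
from a cluster bootstrap that resamples whole subjects with replacement
(percentile intervals, 1000 draws by default). A leakage guard refuses to
evaluate a model on any subject that contributed to its fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .classifiers import TrainedModel, predict_label, predict_proba
from .feature_select import NormalizationParams, SelectionResult

__all__ = [
    "SplitPlan",
    "EvalReport",
    "confusion_metrics",
    "roc_auc",
    "bootstrap_ci",
    "evaluate_predictions",
    "evaluate_holdout",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "mcc", "auc")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint subject-level derivation/validation split."""

    derivation: tuple[str, ...]
    validation: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.derivation) & set(self.validation)
        if overlap:
            raise ValueError(f"subjects in both groups: {sorted(overlap)}")
        if not self.derivation or not self.validation:
            raise ValueError("both groups must be non-empty")

    @classmethod
    def by_cohort_order(cls, subject_ids, n_validation: int = 9) -> "SplitPlan":
        """First subjects derive the model, the last ``n_validation`` validate it."""
        ids = list(dict.fromkeys(subject_ids))  # preserve order, drop duplicates
        if not 0 < n_validation < len(ids):
            raise ValueError("n_validation must leave both groups non-empty")
        return cls(tuple(ids[:-n_validation]), tuple(ids[-n_validation:]))


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, F1 and MCC.

    A ratio with a zero denominator is reported as 0 and the result carries
    ``degenerate=True``.
    """
    counts = np.array([tp, fp, tn, fn], dtype=float)
    if np.any(counts < 0):
        raise ValueError("confusion counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all confusion counts are zero")

    degenerate = False

    def ratio(num: float, den: float) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / float(np.sqrt(mcc_den))
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "mcc": mcc,
        "degenerate": degenerate,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC (midrank tie handling, i.e. the Mann-Whitney form).

    Returns ``(fpr, tpr, auc)``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(roc_auc_score(labels, scores))


def bootstrap_ci(
    metric_fn,
    frame: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    subject_col: str = "subject_id",
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile CI from a cluster bootstrap resampling subjects.

    ``metric_fn`` maps a resampled frame to a float; a resample on which it
    raises or returns NaN is redrawn (up to ``max_retries`` extra draws in
    total, then an error).
    """
    subjects = frame[subject_col].unique()
    if subjects.size < 2:
        raise ValueError("cluster bootstrap needs at least 2 subjects")
    by_subject = {s: frame[frame[subject_col] == s] for s in subjects}
    rng = np.random.default_rng(seed)
    values = []
    retries = 0
    while len(values) < n_boot:
        draw = rng.choice(subjects, size=subjects.size, replace=True)
        resample = pd.concat([by_subject[s] for s in draw], ignore_index=True)
        try:
            v = float(metric_fn(resample))
        except ValueError:
            v = np.nan
        if np.isnan(v):
            retries += 1
            if retries > max_retries:
                raise ValueError("metric undefined on too many bootstrap resamples")
            continue
        values.append(v)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(values, [alpha, 1.0 - alpha])
    return float(low), float(high)


@dataclass
class EvalReport:
    """Confusion counts, the seven metrics with 95% CIs, and the ROC curve."""

    model: str
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, float]
    ci: dict[str, tuple[float, float]]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_epochs: int
    n_subjects: int

    def to_json(self, metadata: dict | None = None) -> str:
        payload = {
            "model": self.model,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "metrics": {
                m: {
                    "value": self.metrics[m],
                    "ci95_low": self.ci[m][0],
                    "ci95_high": self.ci[m][1],
                }
                for m in METRIC_NAMES
            },
            "n_epochs": self.n_epochs,
            "n_subjects": self.n_subjects,
            "metadata": metadata or {},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _all_metrics(frame: pd.DataFrame) -> dict[str, float]:
    yt = frame["y_true"].to_numpy()
    yp = frame["y_pred"].to_numpy()
    tp = int(((yp == 1) & (yt == 1)).sum())
    fp = int(((yp == 1) & (yt == 0)).sum())
    tn = int(((yp == 0) & (yt == 0)).sum())
    fn = int(((yp == 0) & (yt == 1)).sum())
    out = confusion_metrics(tp, fp, tn, fn)
    out.pop("degenerate")
    if np.unique(yt).size < 2:
        raise ValueError("single-class resample")
    out["auc"] = float(roc_auc_score(yt, frame["y_score"].to_numpy()))
    return out


def evaluate_predictions(
    pred_frame: pd.DataFrame,
    model_name: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """EvalReport from a frame with subject_id, y_true, y_pred, y_score."""
    point = _all_metrics(pred_frame)
    yt = pred_frame["y_true"].to_numpy()
    yp = pred_frame["y_pred"].to_numpy()
    fpr, tpr, _ = roc_auc(pred_frame["y_score"].to_numpy(), yt)

    subjects = pred_frame["subject_id"].unique()
    by_subject = [pred_frame[pred_frame["subject_id"] == s] for s in subjects]
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    got, retries = 0, 0
    while got < n_boot:
        idx = rng.integers(0, subjects.size, size=subjects.size)
        resample = pd.concat([by_subject[i] for i in idx], ignore_index=True)
        try:
            vals = _all_metrics(resample)
        except ValueError:
            retries += 1
            if retries > 100:
                raise ValueError("metrics undefined on too many bootstrap resamples")
            continue
        for m in METRIC_NAMES:
            draws[m].append(vals[m])
        got += 1
    ci = {
        m: tuple(float(q) for q in np.quantile(draws[m], [0.025, 0.975]))
        for m in METRIC_NAMES
    }
    return EvalReport(
        model=model_name,
        tp=int(((yp == 1) & (yt == 1)).sum()),
        fp=int(((yp == 1) & (yt == 0)).sum()),
        tn=int(((yp == 0) & (yt == 0)).sum()),
        fn=int(((yp == 0) & (yt == 1)).sum()),
        metrics=point,
        ci=ci,
        roc_fpr=fpr,
        roc_tpr=tpr,
        n_epochs=len(pred_frame),
        n_subjects=subjects.size,
    )


def evaluate_holdout(
    models: list[TrainedModel],
    feature_table: pd.DataFrame,
    plan: SplitPlan,
    norm_params: NormalizationParams,
    selection: SelectionResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, EvalReport], pd.DataFrame]:
    """Evaluate frozen models on the validation subjects.

    Returns per-model reports and a comparison table (one row per model, the
    seven metrics with CI bounds). Raises if any validation subject took part
    in model fitting (leakage guard).
    """
    val_mask = feature_table["subject_id"].isin(plan.validation)
    val = feature_table.loc[val_mask]
    if val.empty:
        raise ValueError("no epochs from validation subjects in the feature table")
    Xv = norm_params.transform(val)[list(selection.selected)]
    yv = val["iicp_label"].to_numpy()

    reports: dict[str, EvalReport] = {}
    rows = []
    for model in models:
        leaked = model.train_subjects & set(plan.validation)
        if leaked:
            raise ValueError(
                f"leakage: model {model.spec.algorithm} was fitted on validation "
                f"subjects {sorted(leaked)}"
            )
        pred = pd.DataFrame(
            {
                "subject_id": val["subject_id"].to_numpy(),
                "y_true": yv,
                "y_score": predict_proba(model, Xv),
            }
        )
        pred["y_pred"] = (pred["y_score"] >= model.spec.threshold).astype(int)
        report = evaluate_predictions(pred, model.spec.algorithm, n_boot=n_boot, seed=seed)
        reports[model.spec.algorithm] = report
        row = {"model": model.spec.algorithm}
        for m in METRIC_NAMES:
            row[m] = report.metrics[m]
            row[f"{m}_ci_low"], row[f"{m}_ci_high"] = report.ci[m]
        rows.append(row)
    return reports, pd.DataFrame(rows)
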