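"""Confusion metrics, ROC/AUC, cluster bootstrap and the holdout evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qeegicp import (
    SplitPlan,
    bootstrap_ci,
    confusion_metrics,
    evaluate_predictions,
    roc_auc,
)


def _closed_form(tp, fp, tn, fn):
    """Independent recomputation of the six confusion metrics."""
    total = tp + fp + tn + fn
    out = {"accuracy": (tp + tn) / total}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else 0.0
    out["specificity"] = tn / (tn + fp) if tn + fp else 0.0
    out["precision"] = tp / (tp + fp) if tp + fp else 0.0
    out["f1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = (tp * tn - fp * fn) / np.sqrt(den) if den else 0.0
    return out


def _brute_force_auc(scores, labels):
    """Concordant-pair counting with midrank ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(30, 10, 50, 10)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.8333, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.80)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["mcc"] == pytest.approx(0.5833, abs=1e-4)

    def test_perfect_prediction(self):
        m = confusion_metrics(40, 0, 60, 0)
        for k in ("accuracy", "sensitivity", "specificity", "precision", "f1", "mcc"):
            assert m[k] == 1.0
        assert not m["degenerate"]

    def test_all_negative_predictor_degenerate(self):
        m = confusion_metrics(0, 0, 50, 50)
        assert m["sensitivity"] == 0.0
        assert m["mcc"] == 0.0
        assert m["degenerate"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)

    def test_matches_closed_form_on_random_grid(self, rng):
        """1000 random count vectors agree with an independent closed form
        to 1e-12."""
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 200, 4)
            if tp + fp + tn + fn == 0:
                continue
            m = confusion_metrics(tp, fp, tn, fn)
            ref = _closed_form(tp, fp, tn, fn)
            for k, v in ref.items():
                assert abs(m[k] - v) < 1e-12


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        _, _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_three_of_four_concordant(self):
        scores = np.array([0.6, 0.4, 0.5, 0.3])
        labels = np.array([1, 1, 0, 0])
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_null_scores_near_half(self, rng):
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        _, _, auc = roc_auc(scores, labels)
        assert 0.48 <= auc <= 0.52

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_pair_counting(self, seed):
        """AUC equals exhaustive concordant-pair counting for n <= 50,
        including tied scores."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 51)
        labels = np.zeros(n, dtype=int)
        labels[: rng.integers(1, n)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            return
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # many ties
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            return
        _, _, auc = roc_auc(scores, labels)
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s**3):
            _, _, auc_t = roc_auc(f(scores), labels)
            assert auc_t == pytest.approx(auc, abs=1e-12)


def _pred_frame(n_subjects, per_subject, seed, p_correct=0.8):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        y = rng.integers(0, 2, per_subject)
        score = np.where(rng.random(per_subject) < p_correct, y, 1 - y) * 0.8 + 0.1
        rows.append(pd.DataFrame({
            "subject_id": f"s{s}",
            "y_true": y,
            "y_score": score + rng.normal(0, 0.01, per_subject),
        }))
    frame = pd.concat(rows, ignore_index=True)
    frame["y_pred"] = (frame["y_score"] >= 0.5).astype(int)
    return frame


class TestBootstrap:
    def test_same_seed_identical_interval(self):
        frame = _pred_frame(6, 50, seed=1)
        acc = lambda f: (f["y_true"] == f["y_pred"]).mean()
        a = bootstrap_ci(acc, frame, n_boot=100, seed=5)
        b = bootstrap_ci(acc, frame, n_boot=100, seed=5)
        assert a == b

    def test_single_subject_duplicated_zero_width(self):
        one = _pred_frame(1, 50, seed=2)
        dup = pd.concat(
            [one.assign(subject_id=f"c{i}") for i in range(4)], ignore_index=True
        )
        acc = lambda f: (f["y_true"] == f["y_pred"]).mean()
        low, high = bootstrap_ci(acc, dup, n_boot=50, seed=0)
        assert low == high

    def test_interval_contains_point_estimate(self):
        frame = _pred_frame(8, 100, seed=3)
        acc = lambda f: (f["y_true"] == f["y_pred"]).mean()
        low, high = bootstrap_ci(acc, frame, n_boot=200, seed=1)
        point = acc(frame)
        assert low <= point <= high

    def test_coverage_of_chance_accuracy(self):
        """Constant predictor on Bernoulli(0.5) labels: the 95% cluster
        bootstrap CI covers 0.5 in most replications."""
        covered = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            frame = pd.DataFrame(
                {
                    "subject_id": np.repeat([f"s{i}" for i in range(9)], 200),
                    "y_true": rng.integers(0, 2, 1800),
                    "y_pred": 1,
                }
            )
            acc = lambda f: (f["y_true"] == f["y_pred"]).mean()
            low, high = bootstrap_ci(acc, frame, n_boot=200, seed=rep)
            covered += low <= 0.5 <= high
        assert covered >= 0.9 * reps

    def test_fewer_than_two_subjects_rejected(self):
        frame = _pred_frame(1, 20, seed=0)
        with pytest.raises(ValueError, match="2 subjects"):
            bootstrap_ci(lambda f: 0.0, frame, n_boot=10, seed=0)


class TestSplitPlanAndHoldout:
    def test_by_cohort_order(self):
        ids = [f"pig{i:02d}" for i in range(1, 31)]
        plan = SplitPlan.by_cohort_order(ids, n_validation=9)
        assert len(plan.derivation) == 21
        assert len(plan.validation) == 9
        assert plan.validation[0] == "pig22"

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="both groups"):
            SplitPlan(("a", "b"), ("b", "c"))

    def test_report_invariants(self):
        frame = _pred_frame(5, 80, seed=7)
        report = evaluate_predictions(frame, "LR", n_boot=50, seed=2)
        assert report.tp + report.fp + report.tn + report.fn == report.n_epochs
        for m, (lo, hi) in report.ci.items():
            assert lo <= report.metrics[m] <= hi
        assert 0 <= report.metrics["accuracy"] <= 1
        assert -1 <= report.metrics["mcc"] <= 1

    def test_leakage_guard(self, tiny_features):
        """A model fitted on a validation subject's epochs is refused."""
        from qeegicp import NCAConfig, evaluate_holdout, fit_selection, train, ModelSpec

        names = ("gammapr", "sd_beta", "thetapr")
        norm, selection = fit_selection(
            tiny_features, names, cfg=NCAConfig(subsample=300, seed=0), k=3
        )
        plan = SplitPlan.by_cohort_order(tiny_features["subject_id"], n_validation=1)
        Xn = norm.transform(tiny_features)[list(selection.selected)]
        model = train(ModelSpec("LR"), Xn, tiny_features["iicp_label"].to_numpy(),
                      subjects=tiny_features["subject_id"].to_numpy())
        with pytest.raises(ValueError, match="leakage"):
            evaluate_holdout([model], tiny_features, plan, norm, selection,
                             n_boot=10, seed=0)
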