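"""Normalization, NCA ranking, t-test filtering and top-k selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qeegicp import (
    NCAConfig,
    SelectionResult,
    fit_minmax,
    nca_feature_weights,
    select_features,
    ttest_pvalues,
)
from qeegicp.feature_select import nca_objective


class TestMinMax:
    def test_affine_map(self):
        X = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        params = fit_minmax(X)
        np.testing.assert_allclose(params.transform(X)["a"], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero_with_warning(self):
        X = pd.DataFrame({"a": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            params = fit_minmax(X)
        np.testing.assert_array_equal(params.transform(X)["a"], 0.0)

    def test_no_clipping_outside_derivation_range(self):
        train = pd.DataFrame({"a": [0.0, 10.0]})
        params = fit_minmax(train)
        out = params.transform(pd.DataFrame({"a": [15.0, -5.0]}))
        assert out["a"].iloc[0] == pytest.approx(1.5)
        assert out["a"].iloc[1] == pytest.approx(-0.5)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_minmax(pd.DataFrame({"a": [1.0]}))


def _instance(seed, n=20, d=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = rng.integers(0, 2, n)
    Z = np.abs(X[:, None, :] - X[None, :, :])  # float64 for exact checks
    same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)
    return X, y, Z, same


class TestNCA:
    def test_gradient_matches_finite_differences(self):
        """Analytic gradient vs central differences on random 20x4 instances."""
        for seed in range(5):
            _, _, Z, same = _instance(seed)
            rng = np.random.default_rng(100 + seed)
            w = rng.uniform(0.5, 1.5, 4)
            _, grad = nca_objective(w, Z, same, 1.0, 0.05)
            h = 1e-5
            for r in range(4):
                wp, wm = w.copy(), w.copy()
                wp[r] += h
                wm[r] -= h
                fd = (
                    nca_objective(wp, Z, same, 1.0, 0.05, need_grad=False)[0]
                    - nca_objective(wm, Z, same, 1.0, 0.05, need_grad=False)[0]
                ) / (2 * h)
                assert abs(grad[r] - fd) / max(abs(fd), 1e-8) < 1e-4

    def test_huge_regularization_kills_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, 50)
        w = nca_feature_weights(X, y, NCAConfig(regularization=1e6, seed=0))
        assert w.max() < 1e-3

    def test_planted_features_recovered(self):
        """Two informative features (class-mean shift 2.0) among eight noise
        features receive the top-2 weights in >= 95% of 20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            y = rng.integers(0, 2, n)
            X = rng.normal(size=(n, 10))
            X[:, 0] += 2.0 * y
            X[:, 1] += 2.0 * y
            w = nca_feature_weights(X, y, NCAConfig(seed=seed))
            hits += set(np.argsort(w)[-2:]) == {0, 1}
        assert hits >= 19

    def test_objective_monotone_over_iterations(self):
        """Backtracking ascent never decreases the objective."""
        rng = np.random.default_rng(3)
        n = 60
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 5))
        X[:, 0] += 1.5 * y
        Z = np.abs(X[:, None, :] - X[None, :, :])
        same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)
        lam = 1.0 / n
        w = np.ones(5)
        value, grad = nca_objective(w, Z, same, 1.0, lam)
        values = [value]
        step = 1.0
        for _ in range(30):
            for _ in range(40):
                v_new, _ = nca_objective(w + step * grad, Z, same, 1.0, lam,
                                         need_grad=False)
                if v_new > value:
                    break
                step *= 0.5
            else:
                break
            w = w + step * grad
            value, grad = nca_objective(w, Z, same, 1.0, lam)
            values.append(value)
            step *= 1.2
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] > values[0]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3000, 5))
        y = rng.integers(0, 2, 3000)
        cfg = NCAConfig(subsample=300, seed=9)
        np.testing.assert_array_equal(
            nca_feature_weights(X, y, cfg), nca_feature_weights(X, y, cfg)
        )

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="class"):
            nca_feature_weights(X, np.zeros(10))

    def test_weights_nonnegative(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        assert (nca_feature_weights(X, y, NCAConfig(seed=2)) >= 0).all()


class TestTTest:
    def test_identical_classes_p_one(self):
        X = np.tile([[1.0], [1.0]], (10, 1))
        y = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning, match="zero variance"):
            p = ttest_pvalues(X, y)
        assert p[0] == 1.0

    def test_separated_means_tiny_p(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])[:, None]
        y = np.repeat([0, 1], 100)
        assert ttest_pvalues(X, y)[0] < 1e-6

    def test_matches_scipy_student_form(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, 60)
        p = ttest_pvalues(X, y)
        ref = stats.ttest_ind(X[y == 0], X[y == 1], equal_var=True).pvalue
        np.testing.assert_allclose(p, ref)

    def test_null_pvalues_uniform(self):
        """Permuting labels of a null feature gives U(0,1) p-values."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)[:, None]
        pvals = []
        for _ in range(1000):
            y = rng.permutation(np.repeat([0, 1], 100))
            pvals.append(ttest_pvalues(x, y)[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestSelection:
    def test_top_k_by_weight(self):
        names = tuple(f"f{i}" for i in range(12))
        weights = np.arange(12, dtype=float)
        p = np.full(12, 0.01)
        res = select_features(names, weights, p, k=10)
        assert res.selected == tuple(f"f{i}" for i in range(11, 1, -1))

    def test_high_weight_high_p_excluded(self):
        names = ("best", "good", "ok")
        res = select_features(names, np.array([10.0, 2.0, 1.0]),
                              np.array([0.2, 0.01, 0.01]), k=2)
        assert "best" not in res.selected
        assert res.selected == ("good", "ok")

    def test_shortfall_warns(self):
        names = tuple(f"f{i}" for i in range(8))
        p = np.array([0.01] * 6 + [0.5, 0.5])
        with pytest.warns(UserWarning, match="only 6"):
            res = select_features(names, np.ones(8), p, k=10)
        assert len(res.selected) == 6

    def test_zero_survivors_rejected(self):
        with pytest.raises(ValueError, match="no feature"):
            select_features(("a",), np.ones(1), np.array([0.9]))

    def test_ties_broken_by_registry_order(self):
        names = ("sd_beta", "gammapr")  # gammapr precedes sd_beta in registry
        res = select_features(names, np.array([1.0, 1.0]),
                              np.array([0.01, 0.01]), k=1)
        assert res.selected == ("gammapr",)

    def test_json_roundtrip(self):
        res = select_features(("a", "b"), np.array([2.0, 1.0]),
                              np.array([0.01, 0.02]), k=2)
        back = SelectionResult.from_json(res.to_json())
        assert back.selected == res.selected
        np.testing.assert_allclose(back.weights, res.weights)

    def test_selection_invariant_to_affine_feature_rescaling(self):
        """Min-max precedes ranking, so scaling a raw feature column cannot
        change the outcome."""
        from qeegicp.feature_select import fit_selection

        rng = np.random.default_rng(5)
        n = 300
        y = rng.integers(0, 2, n)
        base = pd.DataFrame(
            {
                "gammapr": rng.normal(size=n) + 1.2 * y,
                "thetapr": rng.normal(size=n) - 0.8 * y,
                "sd_beta": rng.normal(size=n),
                "iicp_label": y,
            }
        )
        scaled = base.copy()
        scaled["gammapr"] = 1000.0 * scaled["gammapr"] - 37.0
        cfg = NCAConfig(seed=3)
        names = ("gammapr", "thetapr", "sd_beta")
        _, res_a = fit_selection(base, names, cfg=cfg, k=2)
        _, res_b = fit_selection(scaled, names, cfg=cfg, k=2)
        assert res_a.selected == res_b.selected
        np.testing.assert_allclose(res_a.weights, res_b.weights, rtol=1e-6)
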