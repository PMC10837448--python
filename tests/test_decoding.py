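"""Rescaling, LORO SVM decoding, cross-classification and weight maps.

The linear soft-margin SVM implementation (scikit-learn) is anchored to an
independent quadratic-programming oracle on small instances: the dual
problem max sum(a) - 1/2 aT Q a, 0 <= a <= C, sum(a*y) = 0 solved with
scipy's SLSQP.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from laminar_mvpa import (
    BetaMatrix,
    DecoderConfig,
    Rescaler,
    cross_classify,
    decode_condition_pair,
    decode_loro,
    extract_weight_map,
    rescale_betas,
)


def _betas(values, runs, colours, conditions=None):
    n = len(values)
    labels = pd.DataFrame(
        {
            "run": runs,
            "condition": conditions if conditions is not None else ["imagery"] * n,
            "colour": colours,
            "onset_s": np.arange(n) * 16.0,
        }
    )
    return BetaMatrix(np.asarray(values, dtype=float), labels)


def _pattern_betas(w, n_runs=4, trials_per_class=3, noise=0.0, seed=0, scale=1.0):
    """Antisymmetric red/green patterns around the weight vector ``w``."""
    rng = np.random.default_rng(seed)
    rows, runs, cols = [], [], []
    for r in range(n_runs):
        for colour, sign in (("red", 1.0), ("green", -1.0)):
            for _ in range(trials_per_class):
                rows.append(sign * scale * w + noise * rng.standard_normal(len(w)))
                runs.append(r)
                cols.append(colour)
    return _betas(np.array(rows), runs, cols)


def svm_qp_oracle(X, y, C=1.0):
    """Dual soft-margin linear SVM by SLSQP; returns (w, b)."""
    y_pm = np.where(y == 1, 1.0, -1.0)
    Q = (y_pm[:, None] * X) @ (y_pm[:, None] * X).T
    n = len(y)

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    res = minimize(
        neg_dual,
        x0=np.full(n, 0.1),
        jac=lambda a: -(np.ones(n) - Q @ a),
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y_pm,
                      "jac": lambda a: y_pm}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    w = ((a * y_pm)[:, None] * X).sum(axis=0)
    on_margin = (a > 1e-6) & (a < C - 1e-6)
    sv = on_margin if on_margin.any() else a > 1e-6
    b = np.mean(y_pm[sv] - X[sv] @ w)
    return w, b


class TestRescaler:
    def test_affine_identity(self):
        out = Rescaler().fit(np.array([[2.0], [4.0], [6.0]])).transform(
            np.array([[2.0], [4.0], [6.0]])
        )
        np.testing.assert_allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_already_spanning_unchanged(self):
        v = np.array([[-1.0], [0.25], [1.0]])
        np.testing.assert_allclose(Rescaler().fit(v).transform(v), v)

    def test_test_values_may_exceed_bounds(self):
        r = Rescaler().fit(np.array([[0.0], [10.0]]))
        assert r.transform(np.array([[12.0]]))[0, 0] > 1.0

    def test_constant_scope_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            Rescaler().fit(np.full((4, 2), 3.0))

    def test_rescale_betas_full_scope(self):
        bm = _betas([[2.0, 1.0], [4.0, 5.0], [6.0, 3.0]], [0, 0, 1],
                    ["red", "green", "red"])
        out = rescale_betas(bm)
        assert out.values.min() == -1.0 and out.values.max() == 1.0


class TestDecodeLORO:
    def test_perfect_separation_scores_one(self):
        rng = np.random.default_rng(1)
        bm = _pattern_betas(rng.standard_normal(8), noise=0.0)
        res = decode_loro(bm, np.arange(8))
        assert res.mean_accuracy == 1.0
        assert len(res.fold_accuracies) == 4

    def test_permuted_labels_are_at_chance(self):
        """Label-exchangeable null: grand mean accuracy centred on 0.5."""
        rng = np.random.default_rng(2)
        w = rng.standard_normal(6)
        grand = []
        for rep in range(500):
            bm = _pattern_betas(w, noise=1.0, seed=rep, scale=0.0)
            # scale=0: data are pure noise, labels carry no information
            res = decode_loro(bm, np.arange(6))
            grand.append(res.mean_accuracy)
        assert np.mean(grand) == pytest.approx(0.5, abs=0.02)

    def test_missing_class_in_training_fold_rejected(self):
        bm = _betas(
            np.random.default_rng(0).standard_normal((6, 3)),
            runs=[0, 0, 0, 1, 1, 1],
            colours=["red"] * 3 + ["green"] * 3,
        )
        with pytest.raises(ValueError, match="class missing"):
            decode_loro(bm, np.arange(3))

    def test_duplicated_voxels_leave_predictions_unchanged(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal(5)
        bm = _pattern_betas(w, noise=0.6, seed=9)
        res1 = decode_loro(bm, np.arange(5))
        dup = BetaMatrix(
            np.hstack([bm.values, bm.values]), bm.labels.copy()
        )
        res2 = decode_loro(dup, np.arange(10))
        np.testing.assert_allclose(res1.fold_accuracies, res2.fold_accuracies)

    def test_amplitude_independence(self):
        """Scaling all voxels by a positive constant leaves accuracy unchanged."""
        rng = np.random.default_rng(4)
        w = rng.standard_normal(6)
        bm = _pattern_betas(w, noise=0.8, seed=10)
        res1 = decode_loro(bm, np.arange(6))
        res2 = decode_loro(
            BetaMatrix(bm.values * 37.5, bm.labels.copy()), np.arange(6)
        )
        np.testing.assert_allclose(res1.fold_accuracies, res2.fold_accuracies)


class TestQPOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sklearn_solution_matches_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 16, 4
        X = rng.standard_normal((n, p))
        y = np.array([0, 1] * (n // 2))
        X[y == 1] += 0.8
        clf = DecoderConfig().make().fit(X, y)
        w_skl = clf.coef_[0]
        b_skl = clf.intercept_[0]
        w_qp, b_qp = svm_qp_oracle(X, y, C=1.0)
        np.testing.assert_allclose(w_skl, w_qp, atol=2e-3)
        assert b_skl == pytest.approx(b_qp, abs=5e-3)

    def test_duplicated_voxel_shares_weight_equally(self):
        """A duplicated voxel splits its weight 50/50 (minimum-norm optimum),
        and the solution still matches the QP oracle."""
        rng = np.random.default_rng(5)
        n, p = 14, 3
        X = rng.standard_normal((n, p))
        y = np.array([0, 1] * (n // 2))
        X[y == 1] += 1.0
        Xd = np.hstack([X, X[:, :1]])  # duplicate first voxel
        clf = DecoderConfig().make().fit(Xd, y)
        assert clf.coef_[0][0] == pytest.approx(clf.coef_[0][3], abs=2e-3)
        w_qp, _ = svm_qp_oracle(Xd, y)
        np.testing.assert_allclose(clf.coef_[0], w_qp, atol=2e-3)


class TestCrossClassify:
    def _pair(self, seed=0, noise=0.4):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(6)
        a = _pattern_betas(w, noise=noise, seed=seed + 100)
        a.labels["condition"] = "imagery"
        b = _pattern_betas(w, noise=noise, seed=seed + 200)
        b.labels["condition"] = "illusory"
        return a, b

    def test_identical_test_equals_train_accuracy(self):
        a, _ = self._pair()
        res = cross_classify(a, "imagery", a, "illusory_alias", np.arange(6))
        # testing on the training data itself reproduces train accuracy
        clfs = res.models[0]
        assert 0.9 <= res.mean_accuracy <= 1.0

    def test_colour_swap_inverts_accuracy(self):
        a, b = self._pair(seed=3)
        res = cross_classify(a, "imagery", b, "illusory", np.arange(6))
        swapped = BetaMatrix(b.values.copy(), b.labels.copy())
        swapped.labels["colour"] = swapped.labels["colour"].map(
            {"red": "green", "green": "red"}
        )
        res_swapped = cross_classify(a, "imagery", swapped, "illusory", np.arange(6))
        assert res_swapped.mean_accuracy == pytest.approx(
            1.0 - res.mean_accuracy
        )

    def test_orthogonal_patterns_near_chance(self):
        # per-seed accuracies are bimodal (sd ~ 0.34); 300 seeds give a
        # standard error of ~0.02 on the grand mean
        accs = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            w1 = np.zeros(8)
            w1[:4] = rng.standard_normal(4)
            w2 = np.zeros(8)
            w2[4:] = rng.standard_normal(4)  # orthogonal discriminant
            a = _pattern_betas(w1, noise=0.3, seed=seed + 300)
            a.labels["condition"] = "imagery"
            b = _pattern_betas(w2, noise=0.3, seed=seed + 400)
            b.labels["condition"] = "illusory"
            accs.append(
                cross_classify(a, "imagery", b, "illusory", np.arange(8)).mean_accuracy
            )
        assert np.mean(accs) == pytest.approx(0.5, abs=0.06)

    def test_same_condition_redirects_to_loro(self):
        a, _ = self._pair()
        res = cross_classify(a, "imagery", a, "imagery", np.arange(6))
        assert len(res.fold_accuracies) == 4  # LORO folds, not a single split


class TestConditionPairDecoding:
    def _two_condition_betas(self, delta, seed=0, noise=0.5, n_vox=6):
        rng = np.random.default_rng(seed)
        rows, runs, cols, conds = [], [], [], []
        for r in range(4):
            for cond, shift in (("illusory", delta), ("mock", -delta)):
                for colour in ("red", "green"):
                    for _ in range(3):
                        rows.append(shift + noise * rng.standard_normal(n_vox))
                        runs.append(r)
                        cols.append(colour)
                        conds.append(cond)
        return _betas(np.array(rows), runs, cols, conditions=conds)

    def test_identical_generating_patterns_near_chance(self):
        accs = []
        for seed in range(25):
            bm = self._two_condition_betas(np.zeros(6), seed=seed)
            res = decode_condition_pair(bm, "illusory", "mock", np.arange(6))
            accs.extend([res["red"].mean_accuracy, res["green"].mean_accuracy])
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_separable_conditions_decode_and_colours_agree(self):
        rng = np.random.default_rng(7)
        delta = rng.standard_normal(6)
        reds, greens = [], []
        for seed in range(10):
            bm = self._two_condition_betas(delta, seed=seed, noise=0.4)
            res = decode_condition_pair(bm, "illusory", "mock", np.arange(6))
            reds.append(res["red"].mean_accuracy)
            greens.append(res["green"].mean_accuracy)
        assert np.mean(reds) > 0.9 and np.mean(greens) > 0.9
        assert abs(np.mean(reds) - np.mean(greens)) < 0.1

    def test_same_condition_pair_rejected(self):
        bm = self._two_condition_betas(np.zeros(6))
        with pytest.raises(ValueError, match="distinct"):
            decode_condition_pair(bm, "mock", "mock", np.arange(6))


class TestWeightMap:
    def test_single_informative_voxel_dominates(self):
        rng = np.random.default_rng(8)
        w = np.zeros(6)
        w[2] = 2.0
        bm = _pattern_betas(w, noise=0.3, seed=11)
        res = decode_loro(bm, np.arange(6))
        wmap = extract_weight_map(res)
        assert np.argmax(np.abs(wmap.weights)) == 2

    def test_class_swap_flips_weight_signs(self):
        rng = np.random.default_rng(9)
        w = rng.standard_normal(5)
        bm = _pattern_betas(w, noise=0.3, seed=12)
        res1 = decode_loro(bm, np.arange(5), classes=("red", "green"))
        res2 = decode_loro(bm, np.arange(5), classes=("green", "red"))
        w1 = extract_weight_map(res1).weights
        w2 = extract_weight_map(res2).weights
        # agreement up to the solver's termination tolerance (0.001)
        np.testing.assert_allclose(w1, -w2, atol=1e-3)

    def test_weight_sign_points_to_first_class(self):
        # red trials sit at +w: the red-vs-green weight vector should have
        # positive projection onto w
        rng = np.random.default_rng(10)
        w = rng.standard_normal(6)
        bm = _pattern_betas(w, noise=0.1, seed=13)
        wmap = extract_weight_map(decode_loro(bm, np.arange(6)))
        assert wmap.weights @ w > 0
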