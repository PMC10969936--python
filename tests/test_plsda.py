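"""NIPALS PLS-DA: algebraic identities, oracles and validation behaviour."""

import numpy as np
import pandas as pd
import pytest

from flavorgrade import (
    PlsdaError, one_hot, permutation_test, plsda_fit, q2_crossval,
    stratified_folds, vip_scores,
)


def make_separable(n_per_group=5, n_var=8, gap=8.0, seed=0):
    """Three well-separated classes whose centers form a simplex (one
    informative variable per class), so two components suffice."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(["A", "B", "C"], n_per_group)
    X = rng.normal(0, 1, (3 * n_per_group, n_var))
    for i, g in enumerate("ABC"):
        X[labels == g, i] += gap
    return X, labels


class TestFit:
    def test_separable_two_groups(self):
        X = np.array([[0.0], [0.1], [-0.1], [5.0], [5.1], [4.9]])
        labels = ["lo"] * 3 + ["hi"] * 3
        m = plsda_fit(X, labels, n_components=1)
        t = m.x_scores[:, 0]
        assert (t[:3] > 0).all() != (t[3:] > 0).all()  # sign separates groups
        assert m.r2y > 0.99

    def test_score_orthogonality_and_deflation(self, sim_triplicates):
        m = plsda_fit(sim_triplicates.values, sim_triplicates.group_labels, 2)
        T = m.x_scores
        assert abs(T[:, 0] @ T[:, 1]) < 1e-8 * np.linalg.norm(T[:, 0]) \
            * np.linalg.norm(T[:, 1])
        # X is reconstructed by T P' plus a residual that shrinks with A
        Xs = m.x_scaler.transform(
            sim_triplicates.values.to_numpy(dtype=float))
        r1 = np.linalg.norm(Xs - np.outer(T[:, 0], m.x_loadings[:, 0]))
        r2 = np.linalg.norm(Xs - T @ m.x_loadings.T)
        assert r2 <= r1 <= np.linalg.norm(Xs)

    def test_one_component_weights_follow_covariance(self):
        """With univariate y the first PLS weight vector is collinear with
        cov(X, y)."""
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 6))
        labels = np.array(["a", "b"] * 15)
        y = (labels == "a").astype(float)
        m = plsda_fit(X, labels, n_components=1, scaling="center")
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ (y - y.mean())
        cos = abs(cov @ m.x_weights[:, 0]) / np.linalg.norm(cov)
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_r2_bounds_and_q2_relation(self, sim_triplicates):
        m = plsda_fit(sim_triplicates.values, sim_triplicates.group_labels, 2)
        q2 = q2_crossval(sim_triplicates.values,
                         sim_triplicates.group_labels, 2)
        assert 0 <= m.r2x <= 1 and 0 <= m.r2y <= 1
        assert q2 <= m.r2y + 1e-9

    def test_zero_variance_variables_dropped(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 10.0],
                      [1.0, 11.0], [1.0, 12.0]])
        m = plsda_fit(X, ["a"] * 3 + ["b"] * 3, 1)
        assert m.variable_ids == ["x1"]

    def test_errors(self):
        X = np.zeros((4, 3))
        with pytest.raises(PlsdaError):
            plsda_fit(X, ["a"] * 4, 1)                   # one class
        with pytest.raises(PlsdaError):
            plsda_fit(np.random.default_rng(0).normal(size=(3, 3)),
                      ["a", "a", "b"], 1)                # singleton class

    def test_sklearn_oracle_agreement(self):
        """Scores match scikit-learn's NIPALS PLS up to column sign and
        R²Y to high precision on a small dense problem."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, labels = make_separable(seed=11)
        m = plsda_fit(X, labels, n_components=2)
        Y, _ = one_hot(labels)
        ref = sklearn.PLSRegression(n_components=2, scale=True,
                                    max_iter=5000, tol=1e-12)
        ref.fit(X, Y - Y.mean(axis=0))
        for a in range(2):
            ours, theirs = m.x_scores[:, a], ref.x_scores_[:, a]
            cos = abs(ours @ theirs) / (np.linalg.norm(ours)
                                        * np.linalg.norm(theirs))
            assert cos == pytest.approx(1.0, abs=1e-6)
        Yc = Y - Y.mean(axis=0)
        r2y_ref = 1 - ((Yc - ref.predict(X)) ** 2).sum() / (Yc ** 2).sum()
        assert m.r2y == pytest.approx(r2y_ref, abs=1e-6)


class TestQ2:
    def test_group_determined_x_loo(self):
        """When X is (almost) a pure function of the group, leave-one-out
        prediction of the class matrix approaches perfection."""
        rng = np.random.default_rng(0)
        labels = np.repeat(["A", "B", "C"], 5)
        centers = rng.normal(0, 1, (3, 8)) * 5
        X = centers[np.repeat(np.arange(3), 5)] \
            + rng.normal(0, 0.01, (15, 8))
        q2 = q2_crossval(X, labels, 2, n_folds=len(labels))
        assert q2 > 0.95

    def test_nfolds_equal_to_n_is_loo(self):
        X, labels = make_separable(seed=5)
        n = len(labels)
        loo_folds = [np.array([i]) for i in range(n)]
        assert q2_crossval(X, labels, 2, n_folds=n) == pytest.approx(
            q2_crossval(X, labels, 2, folds=loo_folds), rel=1e-12)

    def test_null_data_q2_nonpositive_in_median(self):
        """Random X independent of the labels predicts nothing: median Q²
        over 50 seeds is <= 0."""
        labels = np.repeat(["A", "B", "C"], 3)
        q2s = []
        for seed in range(50):
            X = np.random.default_rng(seed).normal(0, 1, (9, 50))
            q2s.append(q2_crossval(X, labels, 2, n_folds=3))
        assert np.median(q2s) <= 0

    def test_scrambled_labels_q2_nonpositive_in_median(self, sim_triplicates):
        X = sim_triplicates.values.to_numpy(dtype=float)
        labels = np.asarray(sim_triplicates.group_labels)
        q2s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(labels))
            q2s.append(q2_crossval(X, labels[perm], 2, n_folds=3))
        assert np.median(q2s) <= 0

    def test_unstratified_fold_losing_a_class_rejected(self):
        X, labels = make_separable(n_per_group=2)
        bad_folds = [np.arange(0, 2), np.arange(2, 6)]
        with pytest.raises(PlsdaError, match="stratified"):
            q2_crossval(X, labels, 1, folds=bad_folds)

    def test_stratified_folds_cover_and_stratify(self):
        labels = np.repeat(["A", "B", "C"], 3)
        folds = stratified_folds(labels, 3)
        assert sorted(np.concatenate(folds)) == list(range(9))
        for f in folds:
            assert len(set(labels[f])) == 3


class TestVip:
    def test_mean_square_identity(self, sim_triplicates):
        m = plsda_fit(sim_triplicates.values, sim_triplicates.group_labels, 2)
        v = vip_scores(m)
        assert float((v ** 2).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_copies_have_unit_vip(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, 12)
        X = np.tile(col[:, None], (1, 5))
        labels = np.array(["a", "b"] * 6)
        X[:, :] += (labels == "a")[:, None] * 2.0
        m = plsda_fit(X, labels, 1)
        v = vip_scores(m)
        assert np.allclose(v, 1.0)

    def test_planted_signal_has_max_vip(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (18, 10))
        labels = np.repeat(["a", "b", "c"], 6)
        X[:, 4] += 6.0 * (labels == "a") - 6.0 * (labels == "c")
        m = plsda_fit(X, labels, 2)
        v = vip_scores(m)
        assert v.idxmax() == "x4" and v["x4"] > 1.0


class TestPermutation:
    def test_separable_data_judged_valid(self, sim_triplicates):
        res = permutation_test(sim_triplicates.values,
                               sim_triplicates.group_labels,
                               n_components=2, n_perm=50, seed=3, n_folds=3)
        assert res.q2_intercept < 0
        assert res.valid
        assert res.n_perm == 50 and len(res.q2) == 50

    def test_noise_data_not_separated_from_permutations(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (12, 30))
        labels = np.repeat(["A", "B", "C"], 4)
        res = permutation_test(X, labels, 2, n_perm=50, seed=9, n_folds=3)
        # original Q2 not in the top 5% of the permutation distribution
        assert res.original_q2 <= np.quantile(res.q2, 0.95)

    def test_seed_determinism(self):
        X, labels = make_separable(n_per_group=3, seed=2)
        a = permutation_test(X, labels, 2, n_perm=25, seed=42, n_folds=3)
        b = permutation_test(X, labels, 2, n_perm=25, seed=42, n_folds=3)
        assert a.q2_intercept == b.q2_intercept
        assert np.array_equal(a.q2, b.q2)

    def test_too_few_permutations_rejected(self):
        X, labels = make_separable(n_per_group=3)
        with pytest.raises(PlsdaError):
            permutation_test(X, labels, 2, n_perm=5)
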