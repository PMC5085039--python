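"""Shrinkage LDA, AUC, cross-validation and transfer schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crosstask_erp as ce
from crosstask_erp.classify import (
    FittingError,
    TransferResult,
    stack_transfer,
)
from crosstask_erp.containers import FeatureMatrix


def _gaussian_problem(n0=60, n1=30, d=10, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(size=(n0, d))
    X1 = rng.normal(size=(n1, d))
    X1[:, 0] += sep
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    return X, y


# ---------------------------------------------------------------------------
# analytic shrinkage

class TestAnalyticShrinkage:
    def test_matches_literal_elementwise_formula(self):
        """gamma equals a literal double-loop implementation of the closed
        form: sum of Var(S_ij) estimates over the squared Frobenius
        distance between S and nu*I."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3)) @ np.diag([1.0, 2.0, 0.5])
        Xc = X - X.mean(axis=0)
        n, d = Xc.shape
        S = np.zeros((d, d))
        for i in range(d):
            for j in range(d):
                S[i, j] = np.mean(Xc[:, i] * Xc[:, j])
        nu = np.trace(S) / d
        var_sum = 0.0
        dist2 = 0.0
        for i in range(d):
            for j in range(d):
                w = Xc[:, i] * Xc[:, j]
                var_sum += np.mean((w - S[i, j]) ** 2) / n
                dist2 += (S[i, j] - (nu if i == j else 0.0)) ** 2
        gamma_oracle = min(1.0, var_sum / dist2)
        sigma_oracle = (1 - gamma_oracle) * S + gamma_oracle * nu * np.eye(d)

        sigma, gamma = ce.analytic_shrinkage_covariance(Xc)
        assert gamma == pytest.approx(gamma_oracle, rel=1e-12)
        np.testing.assert_allclose(sigma, sigma_oracle, rtol=1e-12)

    def test_agrees_with_ledoit_wolf_reference(self):
        """Independent cross-check against sklearn's Ledoit-Wolf estimator
        (identical shrinkage target after scaling conventions)."""
        from sklearn.covariance import ledoit_wolf

        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 6)) @ rng.normal(size=(6, 6))
        Xc = X - X.mean(axis=0)
        sigma, gamma = ce.analytic_shrinkage_covariance(Xc)
        lw_sigma, lw_gamma = ledoit_wolf(Xc, assume_centered=True)
        assert gamma == pytest.approx(lw_gamma, rel=1e-8)
        np.testing.assert_allclose(sigma, lw_sigma, rtol=1e-8)

    def test_extreme_undersampling_forces_strong_shrinkage(self):
        """gamma grows toward 1 as n shrinks relative to D = 930.

        The n = 2 case is a known degeneracy of the closed form: the two
        centered rows are +-v, so every per-sample second moment equals S
        and the estimated sampling variance (hence gamma) is exactly 0.
        """
        rng = np.random.default_rng(5)
        gammas = {}
        for n in (2, 3, 10):
            Xc = rng.normal(size=(n, 930))
            Xc = Xc - Xc.mean(axis=0)
            _, gammas[n] = ce.analytic_shrinkage_covariance(Xc)
        assert gammas[2] == 0.0
        assert 0.0 < gammas[3] < gammas[10]
        assert gammas[10] > 0.75

    def test_large_sample_consistency(self):
        """With many i.i.d. rows from a known diagonal covariance the
        estimate is entrywise within 2% (scaled by the largest variance)
        and gamma is small."""
        rng = np.random.default_rng(6)
        truth = np.diag([4.0, 2.0, 1.0, 0.5, 0.25])
        X = rng.normal(size=(100_000, 5)) * np.sqrt(np.diag(truth))
        Xc = X - X.mean(axis=0)
        sigma, gamma = ce.analytic_shrinkage_covariance(Xc)
        assert gamma < 0.05
        np.testing.assert_allclose(sigma, truth, atol=0.02 * truth.max())

    def test_constant_input_forces_gamma_one(self, caplog):
        Xc = np.zeros((5, 3))
        with caplog.at_level("WARNING"):
            _, gamma = ce.analytic_shrinkage_covariance(Xc)
        assert gamma == 1.0
        assert "forced to 1" in caplog.text

    def test_too_few_rows_raise(self):
        with pytest.raises(FittingError):
            ce.analytic_shrinkage_covariance(np.zeros((1, 4)))


# ---------------------------------------------------------------------------
# LDA fitting

class TestFitLda:
    def test_small_problem_matches_explicit_inverse(self):
        """w equals the explicit matrix-inverse solution of the shrunk
        system on a D=4 problem."""
        X, y = _gaussian_problem(n0=40, n1=20, d=4, seed=7)
        model = ce.fit_lda(X, y)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Xc = X - np.where(y[:, None] == 1, mu1, mu0)
        S = Xc.T @ Xc / len(y)
        nu = np.trace(S) / 4
        sigma = (1 - model.gamma) * S + model.gamma * nu * np.eye(4)
        w_oracle = np.linalg.inv(sigma) @ (mu1 - mu0)
        np.testing.assert_allclose(model.w, w_oracle, rtol=1e-10)

    def test_dual_solver_matches_direct_when_undersampled(self):
        """The n << D path (Woodbury in the n x n space) gives the same
        weights as the explicit D x D solve."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 300))
        y = np.r_[np.zeros(25, int), np.ones(15, int)]
        model = ce.fit_lda(X, y)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Xc = X - np.where(y[:, None] == 1, mu1, mu0)
        S = Xc.T @ Xc / len(y)
        nu = np.trace(S) / 300
        sigma = (1 - model.gamma) * S + model.gamma * nu * np.eye(300)
        w_oracle = np.linalg.solve(sigma, mu1 - mu0)
        np.testing.assert_allclose(model.w, w_oracle, rtol=1e-8, atol=1e-12)

    def test_full_shrinkage_reduces_to_mean_difference(self):
        X, y = _gaussian_problem(seed=9)
        model = ce.fit_lda(X, y, gamma=1.0)
        diff = X[y == 1].mean(0) - X[y == 0].mean(0)
        ratio = model.w / diff
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_separable_clouds_reach_high_training_auc(self):
        X, y = _gaussian_problem(sep=8.0, seed=10)
        model = ce.fit_lda(X, y)
        assert ce.auc(model.decision_scores(X), y) > 0.99

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(FittingError):
            ce.fit_lda(X, np.zeros(10, dtype=int))

    def test_bias_places_threshold_between_class_means(self):
        X, y = _gaussian_problem(seed=11)
        model = ce.fit_lda(X, y)
        s0 = model.decision_scores(X[y == 0].mean(0)[None, :])[0]
        s1 = model.decision_scores(X[y == 1].mean(0)[None, :])[0]
        assert s0 == pytest.approx(-s1, rel=1e-9)


# ---------------------------------------------------------------------------
# AUC

class TestAuc:
    def test_perfect_ranking(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        assert ce.auc(labels.astype(float), labels) == 1.0

    def test_permuted_labels_average_to_chance(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=200)
        labels = np.r_[np.zeros(100, int), np.ones(100, int)]
        vals = [ce.auc(scores, rng.permutation(labels)) for _ in range(300)]
        assert abs(np.mean(vals) - 0.5) < 0.01

    def test_ties_match_exhaustive_pairwise_count(self):
        """Midrank AUC equals the O(n^2) count of concordant pairs with
        ties worth 1/2, on a 20-sample set with many ties."""
        rng = np.random.default_rng(13)
        scores = rng.integers(0, 4, size=20).astype(float)
        labels = rng.integers(0, 2, size=20)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 2, size=20)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        total = 0.0
        for sp in pos:
            for sn in neg:
                total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        oracle = total / (len(pos) * len(neg))
        assert ce.auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ce.auc(np.arange(4.0), np.ones(4, dtype=int))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 5.0))
    def test_invariant_under_monotone_transform(self, seed, scale):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        a = ce.auc(scores, labels)
        assert ce.auc(np.exp(scale * scores), labels) == pytest.approx(a, abs=1e-12)
        assert ce.auc(scale * scores + 3.0, labels) == pytest.approx(a, abs=1e-12)


# ---------------------------------------------------------------------------
# cross-validation and transfer

class TestCrossvalidation:
    def test_pure_noise_is_at_chance(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(300, 20))
        y = np.r_[np.zeros(200, int), np.ones(100, int)]
        a = ce.crossvalidate_within(X, y, k=10, seed=0)
        assert 0.38 < a < 0.62

    def test_separable_problem_is_near_perfect(self):
        X, y = _gaussian_problem(n0=200, n1=100, sep=8.0, seed=15)
        assert ce.crossvalidate_within(X, y, k=10, seed=0) > 0.97

    def test_class_smaller_than_fold_count_raises(self):
        X, y = _gaussian_problem(n0=50, n1=5, seed=16)
        with pytest.raises(FittingError):
            ce.crossvalidate_within(X, y, k=10, seed=0)

    def test_fold_seed_stability(self):
        """Cross-validated AUC varies little across fold-assignment seeds
        on an adequately sized problem."""
        X, y = _gaussian_problem(n0=400, n1=200, d=20, sep=1.5, seed=17)
        vals = [ce.crossvalidate_within(X, y, k=10, seed=s) for s in range(5)]
        assert np.ptp(vals) < 0.02


def _features(X, y, participant="P01", condition="C"):
    idx = [("ch", float(i)) for i in range(X.shape[1])]
    return FeatureMatrix(X=X, y=y, feature_index=idx,
                         epoch_index=np.arange(len(y)),
                         participant=participant, condition=condition)


class TestTransfer:
    def test_identical_conditions_give_symmetric_matrix(self):
        """With one generative process for all three conditions, the nine
        cells are statistically indistinguishable."""
        rng = np.random.default_rng(18)
        features = {}
        for cond in ("A", "C", "M"):
            X, y = _gaussian_problem(n0=200, n1=100, d=15, sep=1.5,
                                     seed=int(rng.integers(2**31)))
            features[cond] = _features(X, y, condition=cond)
        res = ce.transfer_within_participant(features, k=10, seed=0)
        assert res.auc.shape == (3, 3)
        assert np.all(res.auc > 0.5)
        assert np.ptp(res.auc) < 0.15

    def test_two_participant_across_matches_manual_swap(self):
        """Leave-one-out with two participants equals the hand-computed
        train-on-one / test-on-other evaluation."""
        rng = np.random.default_rng(19)
        cohort = {}
        for p in ("P01", "P02"):
            cohort[p] = {}
            for cond in ("A", "C"):
                X, y = _gaussian_problem(n0=80, n1=40, d=8, sep=2.0,
                                         seed=int(rng.integers(2**31)))
                cohort[p][cond] = _features(X, y, participant=p, condition=cond)
        results = ce.transfer_across_participants(cohort)
        assert [r.participant for r in results] == ["P01", "P02"]
        for held_out, other in (("P01", "P02"), ("P02", "P01")):
            res = next(r for r in results if r.participant == held_out)
            for i, ctr in enumerate(res.conditions):
                model = ce.fit_lda(cohort[other][ctr].X, cohort[other][ctr].y)
                for j, cte in enumerate(res.conditions):
                    fte = cohort[held_out][cte]
                    expected = ce.auc(model.decision_scores(fte.X), fte.y)
                    assert res.auc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_learning_curve_full_n_matches_leave_one_out_oracle(self):
        """At n = all-but-one there is a single possible draw, so the curve
        value equals a direct leave-one-out computation with merged
        conditions."""
        rng = np.random.default_rng(20)
        cohort = {}
        for p in ("P01", "P02", "P03"):
            cohort[p] = {}
            for cond in ("A", "C"):
                X, y = _gaussian_problem(n0=60, n1=30, d=8, sep=2.0,
                                         seed=int(rng.integers(2**31)))
                cohort[p][cond] = _features(X, y, participant=p, condition=cond)
        curve = ce.learning_curve(cohort, n_range=[2], n_draws=5, seed=0, n_boot=50)
        for pi, held_out in enumerate(curve.participants):
            rest = [p for p in curve.participants if p != held_out]
            Xtr = np.vstack([cohort[p][c].X for p in rest for c in ("A", "C")])
            ytr = np.concatenate([cohort[p][c].y for p in rest for c in ("A", "C")])
            Xte = np.vstack([cohort[held_out][c].X for c in ("A", "C")])
            yte = np.concatenate([cohort[held_out][c].y for c in ("A", "C")])
            model = ce.fit_lda(Xtr, ytr)
            expected = ce.auc(model.decision_scores(Xte), yte)
            assert curve.auc[pi, 0] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# population statistics

class TestPopulationTest:
    def test_all_at_chance_is_nonsignificant(self):
        res = ce.population_test(np.full(13, 0.5))
        assert res["p_corrected"] == 1.0

    def test_thirteen_above_chance_is_significant_after_bonferroni(self):
        """All-positive signed ranks at n=13 give the exact one-sided
        p = 2^-13; times nine this stays below 0.05."""
        aucs = 0.5 + np.linspace(0.02, 0.2, 13)
        res = ce.population_test(aucs, n_comparisons=9)
        assert res["p_uncorrected"] == pytest.approx(2.0**-13, rel=1e-9)
        assert res["p_corrected"] <= 0.05

    def test_symmetric_mixture_is_nonsignificant(self):
        aucs = 0.5 + np.array([-0.1, 0.1, -0.05, 0.05, -0.02, 0.02])
        res = ce.population_test(aucs, n_comparisons=1)
        assert res["p_uncorrected"] > 0.3

    def test_matrix_input_tests_every_cell(self):
        rng = np.random.default_rng(21)
        stack = 0.6 + 0.02 * rng.normal(size=(13, 3, 3))
        res = ce.population_test(stack)
        assert np.asarray(res["p_corrected"]).shape == (3, 3)
        assert np.all(np.asarray(res["p_corrected"]) <= 0.05)

    def test_stack_transfer_shapes(self):
        mats = [TransferResult(auc=np.full((3, 3), 0.6), conditions=["A", "C", "M"],
                               participant=f"P{i}") for i in range(4)]
        assert stack_transfer(mats).shape == (4, 3, 3)


class TestShrinkagePath:
    def test_analytic_gamma_not_worse_than_endpoints_when_undersampled(self):
        """On an undersampled correlated problem the analytically shrunk
        discriminant is at least as good (up to a small epsilon) as both
        the unshrunk (gamma=0) and fully shrunk (gamma=1) variants."""
        rng = np.random.default_rng(22)
        d, n_tr, n_te = 200, 80, 4000
        A = rng.normal(size=(d, d)) / np.sqrt(d)
        cov_half = np.eye(d) + 0.5 * A
        diff = np.zeros(d)
        diff[:20] = 0.5
        def draw(n):
            X0 = rng.normal(size=(n, d)) @ cov_half.T
            X1 = rng.normal(size=(n, d)) @ cov_half.T + diff
            return np.vstack([X0, X1]), np.r_[np.zeros(n, int), np.ones(n, int)]
        Xtr, ytr = draw(n_tr // 2)
        Xte, yte = draw(n_te // 2)
        aucs = {}
        for g in (None, 0.0, 1.0):
            model = ce.fit_lda(Xtr, ytr, gamma=g)
            aucs[g] = ce.auc(model.decision_scores(Xte), yte)
        assert aucs[None] >= max(aucs[0.0], aucs[1.0]) - 0.02
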