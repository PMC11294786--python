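"""Rank tests, logistic regression, ROC/AUC and DeLong machinery."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from noctivitals.diagnostics import (
    PerfectSeparationError,
    chi_square,
    compare_auc,
    delong_auc_variance,
    fit_logistic,
    mann_whitney_z,
    roc_evaluate,
    screen_features,
)


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney_z([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_sign_reflects_ordering(self):
        res = mann_whitney_z([1, 2, 3], [4, 5, 6])  # U1 = 0
        assert res.statistic < 0
        flipped = mann_whitney_z([4, 5, 6], [1, 2, 3])
        assert flipped.statistic == pytest.approx(-res.statistic)

    def test_close_to_exact_permutation_p(self, rng):
        """Continuity-corrected normal p within 0.02 of the exact p, n <= 8."""
        for _ in range(100):
            n1, n2 = rng.integers(3, 9, 2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(-1, 1), 1, n2)
            approx = mann_whitney_z(a, b).p_value
            exact = st.mannwhitneyu(a, b, method="exact").pvalue
            assert abs(approx - exact) <= 0.02

    def test_handles_heavy_ties(self):
        res = mann_whitney_z([1, 1, 1, 2], [1, 1, 2, 2])
        assert 0.0 <= res.p_value <= 1.0
        all_tied = mann_whitney_z([5, 5], [5, 5, 5])
        assert all_tied.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_z([], [1.0])


class TestChiSquare:
    def test_independent_table(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 1

    def test_hand_computed_value(self):
        res = chi_square([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20.0 / 3.0, rel=1e-12)
        assert res.df == 1

    def test_matches_direct_formula(self, rng):
        for _ in range(50):
            table = rng.integers(1, 60, (2, 2)).astype(float)
            res = chi_square(table)
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row @ col / table.sum()
            direct = ((table - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(direct, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestScreening:
    def test_null_and_strong_features(self, rng):
        n = 200
        frame = pd.DataFrame(
            {
                "group": ["case"] * n + ["control"] * n,
                "flat": rng.normal(0, 1, 2 * n),
                "strong": np.r_[rng.normal(3, 1, n), rng.normal(0, 1, n)],
            }
        )
        result = screen_features(frame, ["flat", "strong"])
        assert result.retained == ("strong",)
        assert result.excluded == ("flat",)


class TestLogistic:
    def test_two_by_two_slope_is_log_odds_ratio(self):
        # exposure | case: 30 yes / 10 no; control: 10 yes / 30 no -> OR = 9
        x = np.r_[np.ones(30), np.zeros(10), np.ones(10), np.zeros(30)]
        y = np.r_[np.ones(40), np.zeros(40)].astype(int)
        model = fit_logistic(pd.DataFrame({"exposed": x}), y)
        assert model.coefficients[0] == pytest.approx(np.log(9.0), abs=1e-6)
        assert model.converged

    def test_uninformative_feature(self, rng):
        x = rng.normal(0, 1, 400)
        y = (rng.random(400) < 0.25).astype(int)
        model = fit_logistic(pd.DataFrame({"noise": x}), y)
        prevalence = y.mean()
        assert abs(model.coefficients[0]) < 0.5
        assert model.intercept == pytest.approx(
            np.log(prevalence / (1 - prevalence)), abs=0.5
        )

    def test_gradient_vanishes_at_optimum(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (300, 3)), columns=list("abc"))
        eta = 0.8 * X["a"] - 0.5 * X["b"]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
        model = fit_logistic(X, y)
        p = model.predict_proba(X.to_numpy())
        design = np.column_stack([np.ones(len(y)), X.to_numpy()])
        gradient = design.T @ (y - p)
        assert np.max(np.abs(gradient)) < 1e-6

    def test_probabilities_reproducible_from_coefficients(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (200, 2)), columns=["u", "v"])
        y = (X["u"] + rng.normal(0, 1, 200) > 0).astype(int)
        model = fit_logistic(X, y)
        np.testing.assert_allclose(
            model.predict_proba(X.to_numpy()),
            model.fitted_probabilities,
            atol=1e-8,
        )

    def test_perfect_separation_names_feature(self):
        X = pd.DataFrame({"benign": [0.1, -0.2, 0.3, 0.0], "culprit": [1, 2, 8, 9]})
        y = np.array([0, 0, 1, 1])
        with pytest.raises(PerfectSeparationError, match="culprit"):
            fit_logistic(X, y)

    def test_rank_deficient_design_rejected(self, rng):
        a = rng.normal(0, 1, 50)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        y = (rng.random(50) < 0.5).astype(int)
        y[:2] = [0, 1]
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            fit_logistic(X, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), np.array([1, 1]))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        res = roc_evaluate(scores, labels, "probability")
        assert res.auc == 1.0 and res.youden_index == 1.0
        assert res.accuracy == 1.0

    def test_auc_equals_pair_counting(self, rng):
        """Trapezoidal AUC equals U/(n1 n2) with ties counted one half."""
        scores = rng.integers(0, 10, 120).astype(float)  # many ties
        labels = (rng.random(120) < 0.4).astype(int)
        res = roc_evaluate(scores, labels, "probability")
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert res.auc == pytest.approx(expected, rel=1e-12)

    def test_youden_identity_is_exact(self, rng):
        scores = rng.normal(0, 1, 300)
        labels = (rng.random(300) < 0.5).astype(int)
        labels[:2] = [0, 1]
        res = roc_evaluate(scores, labels, "youden")
        assert res.sensitivity + res.specificity - 1.0 == pytest.approx(
            res.youden_index, abs=1e-12
        )

    def test_invariance_under_monotone_transform(self, rng):
        """The ROC depends only on the score ordering, not its scale."""
        scores = rng.normal(0, 1, 200)
        labels = (scores + rng.normal(0, 1, 200) > 0).astype(int)
        base = roc_evaluate(scores, labels, "youden")
        warped = roc_evaluate(np.exp(3 * scores), labels, "youden")
        assert warped.auc == pytest.approx(base.auc, rel=1e-12)
        assert warped.youden_index == pytest.approx(base.youden_index, rel=1e-12)
        assert warped.sensitivity == pytest.approx(base.sensitivity)
        assert warped.specificity == pytest.approx(base.specificity)

    def test_null_scores_give_chance_auc(self):
        """Independent scores and labels: AUC concentrates around 1/2."""
        rng = np.random.default_rng(5)
        inside = 0
        for _ in range(50):
            scores = rng.normal(0, 1, 500)
            labels = (rng.random(500) < 0.5).astype(int)
            auc = roc_evaluate(scores, labels, "probability").auc
            inside += 0.45 <= auc <= 0.55
        assert inside >= 45

    def test_ci_brackets_auc(self, rng):
        scores = rng.normal(0, 1, 150)
        labels = (scores + rng.normal(0, 2, 150) > 0).astype(int)
        res = roc_evaluate(scores, labels, "probability")
        assert res.ci_low <= res.auc <= res.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_evaluate([0.1, 0.9], [1, 1], "probability")


class TestDeLong:
    def test_identical_scores_no_difference(self, rng):
        scores = rng.normal(0, 1, 100)
        labels = (rng.random(100) < 0.5).astype(int)
        labels[:2] = [0, 1]
        res = compare_auc(scores, scores, labels)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_antisymmetric_scores_on_separable_data(self):
        rng = np.random.default_rng(2)
        labels = np.r_[np.ones(100), np.zeros(100)].astype(int)
        scores = np.r_[rng.normal(3, 1, 100), rng.normal(0, 1, 100)]
        res = compare_auc(scores, -scores, labels)
        assert res.p_value < 1e-3
        assert res.statistic > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1, 2], [1, 2, 3], [0, 1])

    def test_variance_close_to_bootstrap(self):
        """DeLong variance of dAUC within 20% of a 2000-rep bootstrap."""
        rng = np.random.default_rng(11)
        n = 200
        labels = (rng.random(n) < 0.5).astype(int)
        signal = labels + rng.normal(0, 1.2, n)
        scores_a = signal + rng.normal(0, 0.5, n)
        scores_b = signal + rng.normal(0, 0.8, n)
        auc_a, _ = delong_auc_variance(labels, scores_a)
        auc_b, _ = delong_auc_variance(labels, scores_b)

        def auc_of(y, s):
            pos, neg = s[y == 1], s[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            return (wins + 0.5 * ties) / (len(pos) * len(neg))

        deltas = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            y = labels[idx]
            if y.min() == y.max():
                continue
            deltas.append(auc_of(y, scores_a[idx]) - auc_of(y, scores_b[idx]))
        boot_var = np.var(deltas, ddof=1)

        # recompute the DeLong variance exactly as compare_auc does
        res = compare_auc(scores_a, scores_b, labels)
        delong_var = ((auc_a - auc_b) / res.statistic) ** 2
        assert 0.8 <= delong_var / boot_var <= 1.2
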