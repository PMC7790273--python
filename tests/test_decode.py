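"""LDA correctness, feature ranking, subset sizes and cohort evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import fnirsdecode as fd
from fnirsdecode.errors import FitError, ValidationError
from fnirsdecode.features import META_COLUMNS

from conftest import gaussian_feature_problem


class TestFitPredict:
    def test_separated_1d_classes_fully_classified(self, rng):
        X, y = gaussian_feature_problem(rng, n_per_class=30, n_features=1, sep=10.0)
        model = fd.fit_lda(X, y)
        assert fd.balanced_accuracy(y, fd.predict(model, X)) == 100.0

    def test_identical_class_means_project_to_zero(self, rng):
        X, y = gaussian_feature_problem(rng, n_per_class=200, n_features=4, sep=0.0)
        model = fd.fit_lda(X, y)
        # projected separation is pure sampling noise (order 2p/n), not signal
        assert abs(model.w @ (model.mu_pos - model.mu_neg)) <= 0.15
        fresh, yf = gaussian_feature_problem(np.random.default_rng(99),
                                             n_per_class=200, n_features=4, sep=0.0)
        acc = fd.balanced_accuracy(yf, fd.predict(model, fresh))
        assert 35.0 <= acc <= 65.0

    def test_weights_match_closed_form_oracle(self, rng):
        X, y = gaussian_feature_problem(rng, n_per_class=50, n_features=5, sep=1.0)
        model = fd.fit_lda(X, y)
        assert model.shrinkage == 0.0
        Xa, Xb = X[y == "a"], X[y == "b"]
        # independent oracle: explicit matrix inverse of the pooled covariance
        Sw = (np.cov(Xa.T, ddof=1) * (len(Xa) - 1)
              + np.cov(Xb.T, ddof=1) * (len(Xb) - 1)) / (len(X) - 2)
        expected = np.linalg.inv(Sw) @ (Xa.mean(0) - Xb.mean(0))
        assert np.abs(model.w - expected).max() <= 1e-9

    def test_midpoint_tie_goes_to_first_label(self, rng):
        X, y = gaussian_feature_problem(rng, n_per_class=20, n_features=3, sep=2.0)
        model = fd.fit_lda(X, y)
        mid = (model.mu_pos + model.mu_neg) / 2.0
        assert fd.predict(model, mid[None, :])[0] == model.class_labels[0]
        assert fd.predict(model, model.mu_pos[None, :])[0] == model.class_labels[0]

    def test_single_class_and_tiny_classes_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(FitError):
            fd.fit_lda(X, np.array(["a"] * 6))
        with pytest.raises(FitError):
            fd.fit_lda(X, np.array(["a", "b", "a", "a", "a", "a"]))

    def test_dimension_mismatch_rejected(self, rng):
        X, y = gaussian_feature_problem(rng)
        model = fd.fit_lda(X, y)
        with pytest.raises(ValidationError):
            fd.predict(model, np.zeros((2, X.shape[1] + 1)))

    def test_reference_implementation_agreement(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        agree = 0
        total = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X, y = gaussian_feature_problem(r, n_per_class=40, n_features=6,
                                            sep=1.5, informative=(0, 2))
            Xnew = r.normal(size=(100, 6)) + 0.75
            model = fd.fit_lda(X, y)
            ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
            agree += (fd.predict(model, Xnew) == ref.predict(Xnew)).sum()
            total += 100
        assert agree / total >= 0.99

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.01, 100.0, allow_nan=False))
    def test_scale_invariance_of_predictions_and_ranking(self, seed, scale):
        r = np.random.default_rng(seed)
        X, y = gaussian_feature_problem(r, n_per_class=25, n_features=4, sep=1.0)
        Xnew = r.normal(size=(30, 4))
        base = fd.fit_lda(X, y)
        scaled = fd.fit_lda(X * scale, y)
        assert base.shrinkage == 0.0 and scaled.shrinkage == 0.0
        assert np.array_equal(fd.predict(base, Xnew),
                              fd.predict(scaled, Xnew * scale))
        assert np.array_equal(fd.rank_features(X, y).order,
                              fd.rank_features(X * scale, y).order)


class TestRanking:
    def test_planted_feature_ranks_first(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            X, y = gaussian_feature_problem(r, n_per_class=40, n_features=10,
                                            sep=5.0, informative=(3,))
            hits += fd.rank_features(X, y).order[0] == 3
        assert hits >= 50 * 0.99

    def test_duplicated_feature_gets_equal_score(self, rng):
        X, y = gaussian_feature_problem(rng, n_per_class=30, n_features=4, sep=1.0)
        Xdup = np.hstack([X, X[:, [1]]])
        rk = fd.rank_features(Xdup, y)
        assert abs(rk.scores[1] - rk.scores[4]) <= 1e-9

    def test_all_noise_ranking_is_permutation(self, rng):
        X, y = gaussian_feature_problem(rng, n_per_class=80, n_features=64, sep=0.0)
        rk = fd.rank_features(X, y)
        assert sorted(rk.order.tolist()) == list(range(64))

    def test_planted_subset_beats_noise_subset(self):
        # monotone data-processing: decoding on informative columns is at
        # least as good as on pure-noise columns, paired across seeds
        wins, losses = 0, 0
        for seed in range(60):
            r = np.random.default_rng(seed)
            X, y = gaussian_feature_problem(r, n_per_class=30, n_features=8,
                                            sep=1.2, informative=(0, 1))
            Xt, yt = gaussian_feature_problem(np.random.default_rng(seed + 10_000),
                                              n_per_class=30, n_features=8,
                                              sep=1.2, informative=(0, 1))
            acc_planted = fd.balanced_accuracy(
                yt, fd.predict(fd.fit_lda(X[:, :2], y), Xt[:, :2]))
            acc_noise = fd.balanced_accuracy(
                yt, fd.predict(fd.fit_lda(X[:, 2:4], y), Xt[:, 2:4]))
            if acc_planted > acc_noise:
                wins += 1
            elif acc_planted < acc_noise:
                losses += 1
        assert sps.binomtest(wins, wins + losses, 0.5,
                             alternative="greater").pvalue < 0.01


class TestSubsetSize:
    @pytest.mark.parametrize("fraction,expected", [
        (0.05, 3), (0.20, 12), (0.30, 19), (1.00, 64), (0.10, 6), (0.01, 1),
    ])
    def test_documented_sizes(self, fraction, expected):
        assert fd.subset_size(fraction, 64) == expected

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            fd.subset_size(0.0, 64)
        with pytest.raises(ValidationError):
            fd.subset_size(1.5, 64)


class TestBalancedAccuracy:
    def test_arithmetic(self):
        y_true = np.array(["A"] * 5 + ["B"] * 10)
        y_pred = np.array(["A"] * 4 + ["B"] + ["B"] * 6 + ["A"] * 4)
        assert fd.balanced_accuracy(y_true, y_pred) == pytest.approx(70.0)
        assert fd.balanced_accuracy(y_true, y_true) == 100.0

    def test_constant_predictor_scores_fifty_under_imbalance(self):
        y_true = np.array(["A"] * 5 + ["B"] * 10)
        assert fd.balanced_accuracy(y_true, np.array(["B"] * 15)) == 50.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValidationError):
            fd.balanced_accuracy(np.array(["A", "A"]), np.array(["A", "B"]))


def _feature_table(rng, subjects, sep, n_features=6, trials_per_class=(5, 10)):
    rows = []
    cols = [f"{i + 1}-1_{c}" for c in ("HbO", "HbR") for i in range(n_features // 2)]
    for s in subjects:
        for cond, n in (("positive", trials_per_class[0]),
                        ("neutral", trials_per_class[1])):
            for t in range(n):
                vals = rng.normal(size=n_features)
                if cond == "positive":
                    vals[0] += sep
                rows.append({"subject_id": s, "task": "active", "condition": cond,
                             "trial_index": t, **dict(zip(cols, vals))})
    return pd.DataFrame(rows, columns=META_COLUMNS + cols)


class TestCohortEvaluation:
    def test_result_cardinality(self, rng):
        train = _feature_table(rng, [f"tr{i}" for i in range(4)], sep=2.0)
        test = _feature_table(rng, [f"te{i}" for i in range(3)], sep=2.0)
        res = fd.cross_dataset_evaluate(train, test, "pos_vs_neu", "active")
        assert len(res) == 20 * 3  # fractions x test subjects

    def test_separable_self_evaluation_is_perfect(self, rng):
        table = _feature_table(rng, ["s1", "s2"], sep=25.0)
        res = fd.cross_dataset_evaluate(table, table, "pos_vs_neu", "active",
                                        fractions=[0.5])
        assert all(r.balanced_accuracy_pct == 100.0 for r in res)

    def test_schema_mismatch_rejected(self, rng):
        train = _feature_table(rng, ["s1", "s2"], sep=1.0)
        test = _feature_table(rng, ["s3"], sep=1.0, n_features=4)
        with pytest.raises(ValidationError, match="schema"):
            fd.cross_dataset_evaluate(train, test, "pos_vs_neu", "active")

    def test_loso_has_no_subject_leakage_and_is_order_invariant(self, rng):
        table = _feature_table(rng, ["s1", "s2", "s3"], sep=3.0)
        res = fd.loso_cv(table, "pos_vs_neu", "active", fractions=[0.5, 1.0])
        assert {r.subject_id for r in res} == {"s1", "s2", "s3"}
        assert len(res) == 2 * 3
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res2 = fd.loso_cv(shuffled, "pos_vs_neu", "active", fractions=[0.5, 1.0])
        key = lambda r: (r.subject_id, r.subset_fraction)
        accs1 = {key(r): r.balanced_accuracy_pct for r in res}
        accs2 = {key(r): r.balanced_accuracy_pct for r in res2}
        assert accs1 == accs2

    def test_perfectly_separable_loso_hits_100(self, rng):
        table = _feature_table(rng, ["s1", "s2", "s3"], sep=25.0)
        res = fd.loso_cv(table, "pos_vs_neu", "active", fractions=[1.0])
        assert all(r.balanced_accuracy_pct == 100.0 for r in res)
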