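"""Weighted lasso logistic regression and the nested LOOCV protocol."""

import warnings

import numpy as np
import pytest
import statsmodels.api as sm

from oculomse.classification import (
    CvConfig,
    class_weights,
    feature_combination_sweep,
    fit_lasso_logistic,
    nested_loocv_evaluate,
    optimal_f1_threshold,
    roc_pr_metrics,
)
from .conftest import make_feature_table

FAST_CV = CvConfig(lambda_grid=tuple(float(x) for x in np.logspace(-3, 1, 8)), seed=3)


class TestClassWeights:
    def test_balanced_gives_unit_weights(self):
        w = class_weights(np.r_[np.zeros(10), np.ones(10)])
        assert np.allclose(w, 1.0)

    def test_study_imbalance(self):
        """20 vs 16: each class carries half the total weight."""
        y = np.r_[np.zeros(20), np.ones(16)]
        w = class_weights(y)
        assert np.allclose(w[:20], 0.9)
        assert np.allclose(w[20:], 1.125)
        assert w[:20].sum() == pytest.approx(18.0)
        assert w[20:].sum() == pytest.approx(18.0)

    @pytest.mark.parametrize("split", [(3, 17), (7, 13), (12, 8)])
    def test_weights_sum_to_n(self, split):
        y = np.r_[np.zeros(split[0]), np.ones(split[1])]
        assert class_weights(y).sum() == pytest.approx(y.size)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.zeros(5))


class TestFitLassoLogistic:
    @pytest.fixture
    def toy(self, rng):
        X = rng.standard_normal((50, 3))
        X = (X - X.mean(0)) / X.std(0)
        logits = X @ np.array([1.0, -0.7, 0.0]) + 0.3
        y = (rng.uniform(size=50) < 1 / (1 + np.exp(-logits))).astype(int)
        return X, y

    def test_huge_lambda_shrinks_all_slopes_to_zero(self, toy):
        X, y = toy
        coef, _ = fit_lasso_logistic(X, y, 1e6, class_weights(y))
        assert np.array_equal(coef, np.zeros(3))

    def test_unpenalized_matches_newton_mle(self, toy):
        """lambda = 0 equals the unpenalized ML fit of an independent solver."""
        X, y = toy
        coef, intercept = fit_lasso_logistic(X, y, 0.0)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(np.r_[intercept, coef], ref.params, atol=1e-6)

    def test_l1_norm_non_increasing_along_path(self, toy):
        X, y = toy
        w = class_weights(y)
        norms = [
            np.abs(fit_lasso_logistic(X, y, lam, w)[0]).sum()
            for lam in np.logspace(-3, 2, 25)
        ]
        assert all(b <= a + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_zero_variance_column_dropped(self, toy):
        X, y = toy
        X = X.copy()
        X[:, 1] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            coef, _ = fit_lasso_logistic(X, y, 0.1, class_weights(y))
        assert coef[1] == 0.0

    def test_negative_lambda_rejected(self, toy):
        X, y = toy
        with pytest.raises(ValueError):
            fit_lasso_logistic(X, y, -1.0)


class TestRocPrMetrics:
    def test_perfect_separation(self):
        m = roc_pr_metrics(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert m["auc_roc"] == 1.0
        assert m["auc_pr"] == 1.0

    def test_constant_probabilities_give_half(self):
        m = roc_pr_metrics(np.full(10, 0.5), np.r_[np.ones(5), np.zeros(5)])
        assert m["auc_roc"] == 0.5

    def test_toy_concordance(self):
        """3 of 4 positive-negative pairs concordant -> AUC 0.75."""
        m = roc_pr_metrics(np.array([0.9, 0.8, 0.7, 0.1]), np.array([1, 0, 1, 0]))
        assert m["auc_roc"] == pytest.approx(0.75)

    def test_auc_equals_pairwise_concordance(self, rng):
        """AUC-ROC equals the tie-corrected concordance probability."""
        for _ in range(10):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # ties likely
            pos, neg = p[y == 1], p[y == 0]
            conc = np.mean(
                [(a > b) + 0.5 * (a == b) for a in pos for b in neg]
            )
            assert roc_pr_metrics(p, y)["auc_roc"] == pytest.approx(conc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_metrics(np.array([0.5, 0.6]), np.array([1, 1]))


class TestOptimalF1Threshold:
    def test_perfect_separation(self):
        out = optimal_f1_threshold(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert out["f1"] == 1.0
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 25))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = rng.uniform(size=n)
            out = optimal_f1_threshold(p, y)
            best = 0.0
            for thr in np.unique(p):
                pred = (p >= thr).astype(int)
                tp = np.sum((pred == 1) & (y == 1))
                denom = 2 * tp + np.sum(pred != y)
                best = max(best, 2 * tp / denom if denom else 0.0)
            assert out["f1"] == pytest.approx(best)

    def test_confusion_consistent(self, rng):
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        p = rng.uniform(size=20)
        out = optimal_f1_threshold(p, y)
        c = out["confusion"]
        assert c["tp"] + c["fn"] == int(y.sum())
        assert c["tn"] + c["fp"] == int((1 - y).sum())
        assert out["sensitivity"] == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))


class TestNestedLoocv:
    def test_shape_contract(self):
        df = make_feature_table(n_td=8, n_adhd=6, seed=0, pupil_delta=0.3)
        rep = nested_loocv_evaluate(df, ("pupil_size",), FAST_CV)
        assert rep.probabilities.size == 14
        assert np.all((rep.probabilities >= 0) & (rep.probabilities <= 1))
        assert rep.lambdas.size == 14

    def test_determinism(self):
        df = make_feature_table(n_td=8, n_adhd=6, seed=1, pupil_delta=0.3)
        a = nested_loocv_evaluate(df, ("pupil_size", "hor_fuzzyen"), FAST_CV)
        b = nested_loocv_evaluate(df, ("pupil_size", "hor_fuzzyen"), FAST_CV)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert np.array_equal(a.lambdas, b.lambdas)

    def test_perfectly_separable_feature_gives_auc_one(self):
        df = make_feature_table(n_td=10, n_adhd=8, seed=2, noise=0.05)
        df.loc[df["group"] == "ADHD", "pupil_size"] += 5.0
        rep = nested_loocv_evaluate(df, ("pupil_size",), FAST_CV)
        assert rep.auc_roc == 1.0

    def test_leakage_audit(self):
        """Perturbing only the held-out row never changes that fold's
        standardization or penalty choice, hence its training-side model."""
        df = make_feature_table(n_td=7, n_adhd=6, seed=3, pupil_delta=0.5)
        rep = nested_loocv_evaluate(df, ("pupil_size", "vert_fuzzyen"), FAST_CV)
        df2 = df.copy()
        # move held-out participant 0 far away in feature space
        df2.loc[0, ["pupil_size", "vert_fuzzyen"]] += 100.0
        rep2 = nested_loocv_evaluate(df2, ("pupil_size", "vert_fuzzyen"), FAST_CV)
        assert rep2.lambdas[0] == rep.lambdas[0]
        # all other folds see a changed training set, but fold 0's model
        # is untouched: its probability moves only through its own features
        assert rep2.probabilities[0] != rep.probabilities[0]

    def test_missing_features_dropped_with_warning(self):
        df = make_feature_table(n_td=8, n_adhd=6, seed=4, pupil_delta=0.4)
        df.loc[0, "pupil_size"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            rep = nested_loocv_evaluate(df, ("pupil_size",), FAST_CV)
        assert rep.probabilities.size == 13


class TestFeatureCombinationSweep:
    def test_seven_subsets(self):
        df = make_feature_table(seed=5, pupil_delta=0.4, entropy_delta=0.3)
        reports = feature_combination_sweep(df, config=FAST_CV)
        assert len(reports) == 7
        sizes = sorted(len(k) for k in reports)
        assert sizes == [1, 1, 1, 2, 2, 2, 3]

    def test_complementary_features_beat_singles(self):
        """Two independent informative features: the pair's AUC is at least
        each single's in the large majority of seeded replicates."""
        wins = 0
        n_rep = 14
        tiny = CvConfig(lambda_grid=tuple(float(x) for x in np.logspace(-3, 1, 6)), seed=0)
        for seed in range(n_rep):
            df = make_feature_table(
                n_td=25, n_adhd=20, seed=seed, pupil_delta=0.45,
                entropy_delta=0.45, noise=0.3,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pair = nested_loocv_evaluate(df, ("pupil_size", "vert_fuzzyen"), tiny)
                single_p = nested_loocv_evaluate(df, ("pupil_size",), tiny)
                single_v = nested_loocv_evaluate(df, ("vert_fuzzyen",), tiny)
            if pair.auc_roc >= max(single_p.auc_roc, single_v.auc_roc):
                wins += 1
        assert wins >= int(0.8 * n_rep)

    def test_null_features_give_chance_auc(self):
        """Label-independent features at study-scale n: per-cohort AUC stays
        in a wide chance band and the across-cohort mean is ~0.5."""
        tiny = CvConfig(lambda_grid=(0.01, 0.1, 1.0, 10.0), seed=0)
        aucs = []
        for seed in range(20):
            df = make_feature_table(n_td=20, n_adhd=16, seed=1000 + seed)
            rep = nested_loocv_evaluate(df, ("pupil_size", "hor_fuzzyen"), tiny)
            aucs.append(rep.auc_roc)
        assert abs(np.mean(aucs) - 0.5) < 0.07
        # pooled LOOCV is slightly pessimistic under the null at this n, so
        # rare cohorts fall just below the nominal chance band
        aucs = np.asarray(aucs)
        assert np.mean((aucs > 0.3) & (aucs < 0.7)) >= 0.9
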