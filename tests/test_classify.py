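import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cogtype import classify as cl


def make_table(X, y, feature_names=None):
    feats = feature_names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=feats,
                      index=[f"subj{i}" for i in range(len(X))])
    df[cl.LABEL_COL] = y
    return df


def null_table(n, rng, feature_names):
    X = rng.normal(size=(n, len(feature_names)))
    y = np.array([0, 1] * (n // 2))
    return make_table(X, y, feature_names)


def preds_from(scores, labels):
    n = len(scores)
    return cl.CVPredictions(
        subject_ids=[f"s{i}" for i in range(n)],
        scores=np.asarray(scores, float),
        labels=np.asarray(labels),
        fold_ids=[f"s{i}" for i in range(n)],
    )


class TestSelectFeatures:
    def test_label_identical_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10)
        X = np.column_stack([rng.normal(size=20), y.astype(float),
                             rng.normal(size=20)])
        table = make_table(X, y, ["noise1", "oracle", "noise2"])
        ranked = cl.select_features(table, k=3)
        assert ranked[0][0] == "oracle"

    def test_constant_feature_ranked_last_with_zero_score(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 10)
        X = np.column_stack([np.ones(20), rng.normal(size=20), y + 0.0])
        table = make_table(X, y, ["const", "noise", "good"])
        ranked = cl.select_features(table, k=3)
        assert ranked[-1] == ("const", 0.0)

    def test_null_selection_frequency_roughly_uniform(self):
        """With pure-noise features the top-1 pick is ~uniform over features."""
        rng = np.random.default_rng(2)
        counts = {f"f{i}": 0 for i in range(4)}
        for _ in range(100):
            table = null_table(200, rng, list(counts))
            counts[cl.select_features(table, k=1)[0][0]] += 1
        freqs = np.array(list(counts.values())) / 100
        assert np.all(np.abs(freqs - 0.25) < 0.15)

    def test_exp1_preset_documented(self):
        assert cl.FEATURE_PRESETS["exp1"] == ["nonstop", "dvrst", "HS", "MDD"]


class TestLosoPredict:
    def test_separable_clusters_auc_one(self):
        rng = np.random.default_rng(3)
        X0 = rng.normal(0, 0.3, size=(10, 2))
        X1 = rng.normal(5, 0.3, size=(10, 2))
        table = make_table(np.vstack([X0, X1]), np.r_[np.zeros(10), np.ones(10)])
        preds = cl.loso_predict(table, "logistic_regression")
        assert roc_auc_score(preds.labels, preds.scores) == 1.0

    def test_permutation_null_auc_near_half(self):
        rng = np.random.default_rng(4)
        table = null_table(200, rng, ["a", "b", "c"])
        preds = cl.loso_predict(table, "logistic_regression")
        auc = roc_auc_score(preds.labels, preds.scores)
        assert 0.4 <= auc <= 0.6

    def test_one_prediction_per_subject(self):
        rng = np.random.default_rng(5)
        table = null_table(12, rng, ["a", "b"])
        preds = cl.loso_predict(table, "knn")
        assert preds.subject_ids == list(table.index)
        assert preds.fold_ids == preds.subject_ids

    def test_missing_feature_errors(self):
        rng = np.random.default_rng(6)
        table = null_table(12, rng, ["a"])
        with pytest.raises(KeyError, match="ghost"):
            cl.loso_predict(table, "logistic_regression", ["a", "ghost"])

    def test_fold_scaler_uses_training_fold_only(self):
        """With an extreme held-out outlier, per-fold scaler statistics must
        differ from whole-table statistics (leakage guard)."""
        from sklearn.preprocessing import StandardScaler
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 1))
        X[0] = 1000.0  # outlier to be held out
        full_mean = StandardScaler().fit(X).mean_[0]
        fold_mean = StandardScaler().fit(X[1:]).mean_[0]
        assert abs(full_mean - fold_mean) > 10


class TestCascade:
    def test_dominant_first_stages_give_auc_one(self):
        # both modalities separate perfectly, so the first-stage
        # probabilities separate and the second stage preserves the ordering
        rng = np.random.default_rng(8)
        y = np.array([0, 1] * 10)
        sep = lambda: y * 3.0 + rng.normal(0, 0.05, 20)
        table = make_table(
            np.column_stack([sep(), sep(), sep(), sep(), sep()]),
            y, ["dvrst", "nonstop", "MDD", "B", "R"])
        preds = cl.cascade_predict(table, "C", seed=0)
        assert roc_auc_score(preds.labels, preds.scores) == 1.0

    def test_missing_column_named_in_error(self):
        rng = np.random.default_rng(9)
        table = null_table(10, rng, ["dvrst", "nonstop", "MDD"])
        with pytest.raises(KeyError, match="B"):
            cl.cascade_predict(table, "A")

    def test_unknown_design_rejected(self):
        rng = np.random.default_rng(10)
        table = null_table(10, rng, ["dvrst"])
        with pytest.raises(ValueError):
            cl.cascade_predict(table, "Z")


class TestYouden:
    def test_separable(self):
        preds = preds_from([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        cutoff, sp, se = cl.youden_cutoff(preds)
        assert sp == 1.0 and se == 1.0
        assert 0.2 < cutoff <= 0.8

    def test_degenerate_all_equal(self):
        preds = preds_from([0.5] * 6, [0, 1] * 3)
        _, sp, se = cl.youden_cutoff(preds)
        assert (sp, se) == (1.0, 0.0)

    def test_interleaved_example_matches_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.6]
        labels = [0, 1, 0, 1, 0]
        preds = preds_from(scores, labels)
        cutoff, sp, se = cl.youden_cutoff(preds)
        # brute-force: best J over the five distinct thresholds
        best_j = max(
            np.mean([s >= t for s, l in zip(scores, labels) if l == 1])
            + np.mean([s < t for s, l in zip(scores, labels) if l == 0]) - 1
            for t in scores
        )
        assert se + sp - 1 == pytest.approx(best_j)

    def test_matches_exhaustive_oracle_on_random_sets(self):
        """Implementation equals threshold enumeration on 50 random sets."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            labels = np.r_[np.zeros(n // 2), np.ones(n - n // 2)].astype(int)
            scores = np.round(rng.uniform(0, 1, n), 2)  # force ties
            preds = preds_from(scores, labels)
            _, sp, se = cl.youden_cutoff(preds)
            pos, neg = labels == 1, labels == 0
            best = max(
                (scores[pos] >= t).mean() + (scores[neg] < t).mean() - 1
                for t in np.r_[np.unique(scores), np.inf]
            )
            assert se + sp - 1 == pytest.approx(best)


class TestBootstrapROC:
    def test_perfect_ordering_degenerate_ci(self):
        preds = preds_from([0.1, 0.2, 0.3, 0.7, 0.8, 0.9],
                           [0, 0, 0, 1, 1, 1])
        res = cl.bootstrap_roc(preds, n_boot=200, seed=0)
        assert res.mean_auc == 1.0
        assert res.auc_ci == (1.0, 1.0)
        assert res.accuracy == 1.0

    def test_anti_ordering_auc_zero(self):
        preds = preds_from([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
        res = cl.bootstrap_roc(preds, n_boot=100, seed=0)
        assert res.mean_auc == 0.0

    def test_null_scores_ci_contains_half(self):
        """Scores independent of labels: the 95% CI covers the true AUC of
        0.5 in nearly all of 10 null replicates (each covers w.p. ~0.95)."""
        rng = np.random.default_rng(12)
        labels = np.array([0, 1] * 100)
        covered = 0
        for rep in range(10):
            preds = preds_from(rng.uniform(size=200), labels)
            res = cl.bootstrap_roc(preds, n_boot=500, seed=rep)
            covered += res.auc_ci[0] <= 0.5 <= res.auc_ci[1]
        assert covered >= 8

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(13)

        def width(n):
            labels = np.array([0, 1] * (n // 2))
            scores = labels + rng.normal(0, 1.0, n)
            res = cl.bootstrap_roc(preds_from(scores, labels),
                                   n_boot=500, seed=2)
            return res.auc_ci[1] - res.auc_ci[0]

        assert width(200) < width(20)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        labels = np.array([0, 1] * 20)
        scores = labels + rng.normal(0, 1, 40)
        r1 = cl.bootstrap_roc(preds_from(scores, labels), n_boot=300, seed=3)
        r2 = cl.bootstrap_roc(preds_from(np.exp(3 * scores), labels),
                              n_boot=300, seed=3)
        assert r1.mean_auc == pytest.approx(r2.mean_auc)
        assert r1.auc_ci == pytest.approx(r2.auc_ci)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cl.bootstrap_roc(preds_from([0.1, 0.9], [0, 1]))


class TestClinicalCorrelation:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        r, p = cl.clinical_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_negative_linearity(self):
        x = np.arange(10.0)
        r, _ = cl.clinical_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(15)
        r, _ = cl.clinical_correlation(rng.normal(size=1000),
                                       rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_zero_variance_flagged(self):
        r, p = cl.clinical_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)
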