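"""Pipeline mechanics: label binarization, participant-grouped splitting,
the ordered preprocessing stages, SMOTE oversampling, LASSO-threshold
selection, classifier training, and the randomized search."""

import numpy as np
import pandas as pd
import pytest

from pdmotion import (
    FeatureTable,
    HyperparameterSet,
    binarize_label,
    split_by_participant,
    fit_preprocessor,
    oversample_minority,
    lasso_select,
    fit_classifier,
    fit_pipeline,
    cross_val_f1,
    random_search,
)
from pdmotion.modeling import HYPERPARAMETER_RANGES


def make_table(n_rows=60, n_informative=4, n_noise=6, n_participants=12,
               seed=0, effect=3.0, prevalence=0.5, task="FTN"):
    """Synthetic feature table: informative columns shift with the label."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n_rows) < prevalence).astype(int)
    X = rng.normal(size=(n_rows, n_informative + n_noise))
    X[:, :n_informative] += effect * y[:, None]
    cols = [f"f{i:02d}" for i in range(X.shape[1])]
    idx = [f"v{i:03d}" for i in range(n_rows)]
    participants = [f"P{i % n_participants:03d}" for i in range(n_rows)]
    return FeatureTable(
        features=pd.DataFrame(X, index=idx, columns=cols),
        labels=pd.Series(y, index=idx),
        participants=pd.Series(participants, index=idx),
        task=task,
    )


class TestBinarizeLabel:
    @pytest.mark.parametrize("score,expected", [(0, 0), (1, 1), (2, 1), (3, 1), (4, 1)])
    def test_positive_iff_any_symptom(self, score, expected):
        assert binarize_label(score) == expected

    def test_idempotent_on_binary(self):
        assert binarize_label(binarize_label(3)) == 1
        assert binarize_label(binarize_label(0)) == 0

    def test_out_of_range_rejected(self):
        for bad in (-1, 5, 2.5):
            with pytest.raises(ValueError):
                binarize_label(bad)


class TestSplitByParticipant:
    def test_eighty_twenty_partition(self):
        t = make_table(n_rows=50, n_participants=10)
        train, val = split_by_participant(t, 0.8, seed=0)
        assert train.participants.nunique() == 8
        assert val.participants.nunique() == 2
        assert len(train) + len(val) == 50

    def test_participant_sets_disjoint(self):
        t = make_table(n_rows=66, n_participants=11)
        for seed in range(5):
            train, val = split_by_participant(t, 0.8, seed=seed)
            assert not set(train.participants) & set(val.participants)

    def test_deterministic(self):
        t = make_table()
        a = split_by_participant(t, 0.8, seed=3)[0]
        b = split_by_participant(t, 0.8, seed=3)[0]
        assert list(a.features.index) == list(b.features.index)

    def test_too_few_participants_rejected(self):
        t = make_table(n_rows=6, n_participants=1)
        with pytest.raises(ValueError):
            split_by_participant(t)


class TestPreprocessing:
    def test_missing_feature_dropped_first(self):
        t = make_table(n_rows=30)
        t.features["all_missing"] = np.nan
        pre = fit_preprocessor(t, HyperparameterSet(max_missing_frac=0.5))
        assert "all_missing" not in pre.kept_after_missing

    def test_constant_feature_dropped_by_variance(self):
        t = make_table(n_rows=30)
        t.features["constant"] = 1.0
        pre = fit_preprocessor(t, HyperparameterSet(min_variance=0.1))
        assert "constant" in pre.kept_after_missing  # survives stage 1
        assert "constant" not in pre.kept_after_variance

    def test_duplicate_feature_pruned_by_correlation(self):
        t = make_table(n_rows=30)
        t.features["f00_copy"] = t.features["f00"]
        pre = fit_preprocessor(t, HyperparameterSet(max_corr=0.85))
        kept = pre.kept_features
        assert ("f00" in kept) != ("f00_copy" in kept)  # exactly one survives
        assert "f00" in kept  # earlier in canonical order wins

    def test_standardization_uses_training_statistics(self):
        t = make_table(n_rows=40, seed=1)
        pre = fit_preprocessor(t, HyperparameterSet(min_variance=0.0, max_corr=0.89))
        out = pre.transform(t.features)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0, ddof=0), 1.0, atol=1e-9)
        other = make_table(n_rows=10, seed=2)
        out2 = pre.transform(other.features)
        assert list(out2.columns) == list(out.columns)

    def test_imputation_fills_gaps(self):
        t = make_table(n_rows=30)
        t.features.iloc[0, 0] = np.nan
        pre = fit_preprocessor(t, HyperparameterSet(max_missing_frac=0.5, impute_k=2))
        out = pre.transform(t.features)
        assert not out.isna().any().any()

    def test_all_features_removed_is_error(self):
        t = make_table(n_rows=20)
        t.features[:] = np.nan
        with pytest.raises(ValueError, match="empty feature set"):
            fit_preprocessor(t, HyperparameterSet(max_missing_frac=0.1))


class TestOversampling:
    def _imbalanced(self, n_min=5, n_maj=10, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * n_min + [0] * n_maj)
        X = rng.normal(size=(len(y), 3))
        idx = [f"v{i}" for i in range(len(y))]
        return FeatureTable(
            features=pd.DataFrame(X, index=idx, columns=["a", "b", "c"]),
            labels=pd.Series(y, index=idx),
            participants=pd.Series([f"P{i}" for i in range(len(y))], index=idx),
        )

    def test_equalizes_class_counts(self):
        out = oversample_minority(self._imbalanced(5, 10), k=2, seed=0)
        counts = out.labels.value_counts()
        assert counts[0] == counts[1] == 10

    def test_synthetic_rows_on_segments_between_minority_rows(self):
        t = self._imbalanced(6, 14)
        out = oversample_minority(t, k=3, seed=1)
        minority = t.features[t.labels == 1].to_numpy()
        synth = out.features.loc[[i for i in out.features.index if i.startswith("syn")]]
        for row in synth.to_numpy():
            # x + u(x'−x) lies on a segment between two real minority rows:
            # check representability as a convex combination of some pair
            ok = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = np.dot(d, d)
                    if denom == 0:
                        continue
                    u = np.dot(row - minority[i], d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        minority[i] + u * d, row, atol=1e-9
                    ):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_balanced_input_unchanged(self):
        t = self._imbalanced(8, 8)
        out = oversample_minority(t, k=2, seed=0)
        pd.testing.assert_frame_equal(out.features, t.features)

    def test_too_few_minority_rejected(self):
        with pytest.raises(ValueError, match="too few minority"):
            oversample_minority(self._imbalanced(2, 10), k=2)

    def test_deterministic(self):
        t = self._imbalanced(5, 12)
        a = oversample_minority(t, k=2, seed=5)
        b = oversample_minority(t, k=2, seed=5)
        pd.testing.assert_frame_equal(a.features, b.features)


class TestLassoSelect:
    def test_zero_threshold_keeps_nonzero_coefficients(self):
        t = make_table(n_rows=80, n_informative=3, n_noise=3, effect=2.0)
        kept = lasso_select(t, coef_threshold=0.0)
        assert set(kept) >= {"f00", "f01", "f02"} or len(kept) >= 3

    def test_noise_features_mostly_dropped(self):
        """20 informative + 80 pure-noise features at effect size 2 sd:
        the L1 penalty plus threshold must discard most of the noise."""
        rng = np.random.default_rng(42)
        n = 200
        y = rng.integers(0, 2, size=n)
        informative = rng.normal(size=(n, 20)) + 2.0 * y[:, None]
        noise = rng.normal(size=(n, 80))
        X = np.hstack([informative, noise])
        X = (X - X.mean(0)) / X.std(0)
        cols = [f"inf{i:02d}" for i in range(20)] + [f"noise{i:02d}" for i in range(80)]
        t = FeatureTable(
            features=pd.DataFrame(X, columns=cols),
            labels=pd.Series(y),
            participants=pd.Series([f"P{i}" for i in range(n)]),
        )
        kept = lasso_select(t, coef_threshold=0.01)
        kept_noise = [c for c in kept if c.startswith("noise")]
        assert len(kept_noise) < 40  # majority of the 80 noise features gone
        assert any(c.startswith("inf") for c in kept)

    def test_duplicated_informative_feature_sparsified(self):
        """L1 splits/concentrates weight over exact duplicates; at most one
        copy keeps a large coefficient."""
        rng = np.random.default_rng(0)
        n = 100
        y = rng.integers(0, 2, size=n).astype(float)
        f = y + 0.1 * rng.normal(size=n)
        f = (f - f.mean()) / f.std()
        X = pd.DataFrame({"dup_a": f, "dup_b": f, "other": rng.normal(size=n)})
        t = FeatureTable(
            features=X, labels=pd.Series(y.astype(int)),
            participants=pd.Series([f"P{i}" for i in range(n)]),
        )
        from sklearn.linear_model import Lasso

        coefs = Lasso(alpha=0.01).fit(X.to_numpy(), y).coef_
        large = np.sum(np.abs(coefs[:2]) > 0.25)
        assert large <= 1

    def test_nothing_survives_is_error(self):
        t = make_table(n_rows=40, n_informative=0, n_noise=5, effect=0.0)
        with pytest.raises(ValueError):
            lasso_select(t, coef_threshold=0.9)


class TestClassifiers:
    def _toy(self, n=40):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(scale=0.2, size=(n, 2)) + 3.0 * y[:, None]
        return FeatureTable(
            features=pd.DataFrame(X, columns=["a", "b"]),
            labels=pd.Series(y),
            participants=pd.Series([f"P{i}" for i in range(n)]),
        )

    @pytest.mark.parametrize("kind", ["svm", "rf"])
    def test_separable_data_perfect_training_f1(self, kind):
        from sklearn.metrics import f1_score

        t = self._toy()
        clf = fit_classifier(t, kind, HyperparameterSet(svm_C=1.5, svm_gamma=0.1), seed=0)
        pred = clf.predict(t.features.to_numpy())
        assert f1_score(t.labels, pred) == 1.0

    @pytest.mark.parametrize("kind", ["svm", "rf"])
    def test_predictions_deterministic(self, kind):
        t = self._toy()
        a = fit_classifier(t, kind, HyperparameterSet(), seed=1)
        b = fit_classifier(t, kind, HyperparameterSet(), seed=1)
        X = t.features.to_numpy()
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_single_class_rejected(self):
        t = self._toy()
        t.labels[:] = 1
        with pytest.raises(ValueError, match="single-class"):
            fit_classifier(t, "svm", HyperparameterSet())

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            fit_classifier(self._toy(), "mlp", HyperparameterSet())


class TestFittedPipeline:
    def test_end_to_end_predicts_probabilities(self):
        t = make_table(n_rows=80, n_participants=16, effect=3.0)
        train, val = split_by_participant(t, 0.8, seed=0)
        pipe = fit_pipeline(train, "svm", HyperparameterSet(), seed=0)
        prob = pipe.predict_proba(val.features)
        assert prob.shape == (len(val),)
        assert np.all((prob >= 0) & (prob <= 1))

    def test_selection_summary_structure(self):
        t = make_table(n_rows=60, effect=3.0)
        pipe = fit_pipeline(t, "svm", HyperparameterSet(), seed=0)
        summary = pipe.selection_summary()
        assert set(summary.columns) >= {"type", "joint", "signal", "filter_width", "detail"}
        assert len(summary) == len(pipe.selected_features)


class TestCrossValidation:
    def test_permuted_labels_near_chance(self):
        """With labels shuffled independently of the features, the
        cross-validated F1 must show no real skill (chance level for 50%
        prevalence; a degenerate always-positive classifier caps at 2/3)."""
        rng = np.random.default_rng(7)
        t = make_table(n_rows=100, n_participants=20, effect=3.0, seed=7)
        permuted = FeatureTable(
            features=t.features,
            labels=pd.Series(rng.permutation(t.labels.to_numpy()), index=t.features.index),
            participants=t.participants,
        )
        f1 = cross_val_f1(permuted, "svm", HyperparameterSet(), cv_folds=5, seed=0)
        assert f1 < 0.75

    def test_informative_data_scores_high(self):
        t = make_table(n_rows=100, n_participants=20, effect=4.0, seed=3)
        f1 = cross_val_f1(t, "svm", HyperparameterSet(), cv_folds=5, seed=0)
        assert f1 > 0.9


class TestRandomSearch:
    def test_sampled_parameters_within_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            h = HyperparameterSet.sample(rng)
            for name, (lo, hi, kind) in HYPERPARAMETER_RANGES.items():
                v = getattr(h, name)
                if kind == "int":
                    assert lo <= v < hi and isinstance(v, int)
                elif name == "svm_gamma":
                    assert lo <= v <= hi
                else:
                    assert lo <= v < hi

    def test_deterministic_given_seed(self):
        t = make_table(n_rows=60, n_participants=12, effect=3.0)
        a = random_search(t, "svm", n_iter=4, cv_folds=3, seed=5)
        b = random_search(t, "svm", n_iter=4, cv_folds=3, seed=5)
        assert a == b

    def test_best_at_least_as_good_as_fixed_midrange(self):
        t = make_table(n_rows=60, n_participants=12, effect=4.0)
        _, best_f1 = random_search(t, "svm", n_iter=6, cv_folds=3, seed=1)
        fixed = cross_val_f1(t, "svm", HyperparameterSet(), cv_folds=3, seed=1)
        assert best_f1 >= fixed - 1e-9
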