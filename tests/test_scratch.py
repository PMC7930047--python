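"""Class balancing, RFE-CV feature selection and the scratch classifier."""

import numpy as np
import pytest

import sleepscratch as ss
from sleepscratch.scratch import (
    NON_SCRATCH,
    SCRATCH,
    load_model,
    model_metadata,
    save_model,
)


def _planted_data(seed, n=300, n_features=36, informative=5, shift=2.0):
    """Features 0..informative-1 carry class signal; the rest are noise."""
    rng = np.random.default_rng(seed)
    y = np.array([SCRATCH, "restless"])[rng.integers(0, 2, n)]
    X = rng.normal(size=(n, n_features))
    for j in range(informative):
        X[y == SCRATCH, j] += shift
    return X, y


class TestBalance:
    def test_majority_downsampled_to_minority(self):
        y = np.array([SCRATCH] * 100 + ["restless"] * 40)
        idx = ss.balance_classes(y, 0)
        yb = y[idx]
        assert (yb == SCRATCH).sum() == 40
        assert (yb == "restless").sum() == 40
        assert len(np.unique(idx)) == len(idx)  # without replacement

    def test_already_balanced_unchanged_sizes(self):
        y = np.array([SCRATCH] * 25 + ["restless"] * 25)
        assert len(ss.balance_classes(y, 3)) == 50

    def test_deterministic_under_seed(self):
        y = np.array([SCRATCH] * 90 + ["restless"] * 30)
        np.testing.assert_array_equal(ss.balance_classes(y, 42), ss.balance_classes(y, 42))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ss.balance_classes(np.array([SCRATCH] * 10))


def _complementary_data(seed, n=600, n_features=36, informative=5):
    """The class is the sign of the sum of the informative features, so
    every one of them carries part of the signal."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = np.where(X[:, :informative].sum(axis=1) > 0, SCRATCH, "restless")
    return X, y


class TestFeatureSelection:
    def test_informative_features_retained_across_seeds(self):
        hits = 0
        for seed in range(10):
            X, y = _complementary_data(seed)
            support = ss.select_features_rfecv(X, y, seed=seed)
            if support[:5].all():
                hits += 1
        assert hits >= 9

    def test_duplicated_feature_mostly_deduplicated(self):
        kept_both = 0
        for seed in range(6):
            X, y = _planted_data(seed, informative=1, shift=4.0)
            X[:, 1] = X[:, 0]  # perfect duplicate of the only informative feature
            support = ss.select_features_rfecv(X, y, seed=seed)
            if support[0] and support[1]:
                kept_both += 1
        assert kept_both <= 2

    def test_single_informative_feature_gives_small_subset(self):
        X, y = _planted_data(0, informative=1, shift=4.0)
        support = ss.select_features_rfecv(X, y, seed=0)
        assert support.sum() < 18

    def test_too_few_samples_for_folds_rejected(self):
        X, y = _planted_data(0, n=6)
        with pytest.raises(ValueError, match="cv"):
            ss.select_features_rfecv(X, y, seed=0, cv=5)


class TestScratchClassifier:
    def test_separable_data_fits_perfectly(self):
        X, y = _planted_data(1, shift=6.0)
        clf = ss.ScratchClassifier(random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == pytest.approx(1.0)
        assert clf.forest_.n_estimators == 50
        assert len(clf.selected_feature_names_) == clf.support_.sum() >= 1

    def test_same_seed_same_predictions(self):
        X, y = _planted_data(2)
        p1 = ss.ScratchClassifier(random_state=7).fit(X, y).scratch_probability(X)
        p2 = ss.ScratchClassifier(random_state=7).fit(X, y).scratch_probability(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        X = np.zeros((20, 36))
        with pytest.raises(ValueError, match="class"):
            ss.ScratchClassifier(random_state=0).fit(X, np.array([SCRATCH] * 20))

    def test_sklearn_params_roundtrip(self):
        clf = ss.ScratchClassifier(n_estimators=25, threshold=0.7)
        params = clf.get_params()
        assert params["n_estimators"] == 25
        clf.set_params(threshold=0.4)
        assert clf.threshold == 0.4

    def test_training_meta_records_counts(self):
        X, y = _planted_data(3)
        clf = ss.ScratchClassifier(random_state=0).fit(X, y)
        meta = clf.training_meta_
        counts = meta["balanced_counts"]
        assert counts[SCRATCH] == counts["restless"]
        assert meta["n_selected"] == clf.support_.sum()


@pytest.fixture(scope="module")
def model():
    X, y = _planted_data(4, shift=6.0)
    return ss.ScratchClassifier(random_state=0).fit(X, y)


class TestPredictWindows:
    def test_gated_windows_never_classified(self, model):
        X, y = _planted_data(4, n=40, shift=6.0)
        moving = np.zeros(40, dtype=bool)
        out = ss.predict_windows(model, X, moving)
        assert (out["pred"] == NON_SCRATCH).all()
        assert out["probability"].isna().all()

    def test_threshold_extremes(self, model):
        X, _ = _planted_data(4, n=40, shift=6.0)
        moving = np.ones(40, dtype=bool)
        none = ss.predict_windows(model, X, moving, threshold=1.0)
        allp = ss.predict_windows(model, X, moving, threshold=-0.01)
        assert (none["pred"] == NON_SCRATCH).all()
        assert (allp["pred"] == SCRATCH).all()

    def test_raising_threshold_shrinks_scratch_set(self, model):
        X, _ = _planted_data(5, n=100)
        moving = np.ones(100, dtype=bool)
        sets = []
        for thr in (0.2, 0.5, 0.8):
            out = ss.predict_windows(model, X, moving, threshold=thr)
            sets.append(set(np.flatnonzero((out["pred"] == SCRATCH).to_numpy())))
        assert sets[2] <= sets[1] <= sets[0]


class TestLoso:
    def test_fold_count_equals_subject_count(self, labeled_windows):
        _, X, y, subj = labeled_windows
        per = ss.loso_validate(X, y, subj, seed=0)
        assert len(per) == len(np.unique(subj))

    def test_identical_separable_subjects_near_perfect(self):
        X, y = _planted_data(6, n=120, shift=6.0)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        subj = np.array(["a"] * 120 + ["b"] * 120)
        per = ss.loso_validate(X2, y2, subj, seed=0)
        assert (per["accuracy"] > 0.95).all()

    def test_single_subject_rejected(self):
        X, y = _planted_data(7, n=50)
        with pytest.raises(ValueError, match="2 subjects"):
            ss.loso_validate(X, y, np.zeros(50), seed=0)

    def test_summary_shape(self, labeled_windows):
        _, X, y, subj = labeled_windows
        per = ss.loso_validate(X, y, subj, seed=0)
        summ = ss.loso_summary(per)
        assert set(summ.columns) == {"mean", "sd"}
        assert "sensitivity" in summ.index


class TestModelArchive:
    def test_roundtrip_reproduces_predictions(self, tmp_path, scratch_model):
        path = tmp_path / "model.joblib"
        save_model(scratch_model, path)
        back = load_model(path)
        X = np.random.default_rng(0).normal(size=(10, 36))
        np.testing.assert_array_equal(
            back.scratch_probability(X), scratch_model.scratch_probability(X)
        )
        meta = model_metadata(path)
        assert meta["format_version"] == "1"
        assert meta["selected_feature_names"] == scratch_model.selected_feature_names_

    def test_unfitted_model_cannot_be_saved(self, tmp_path):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            save_model(ss.ScratchClassifier(), tmp_path / "m.joblib")
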