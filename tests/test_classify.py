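from itertools import product

import numpy as np
import pytest

from pepforge import (
    EnsembleModel,
    SVMConfig,
    ensemble_predict,
    fit_ensemble,
    train_knn,
    train_nb,
    train_rf,
    train_svm,
)

SMALL_SVM = SVMConfig(c_grid=(1.0, 10.0), gamma_grid=(0.1, 1.0), cv_folds=3)


def blobs(rng, n=60, d=4, sep=4.0):
    """Two well-separated Gaussian blobs labeled ACP/NACP."""
    X = np.vstack(
        [rng.normal(-sep / 2, 1.0, size=(n // 2, d)), rng.normal(sep / 2, 1.0, size=(n // 2, d))]
    )
    y = np.array(["ACP"] * (n // 2) + ["NACP"] * (n // 2))
    return X, y


class TestSVM:
    def test_separable_blobs_fit_perfectly(self, rng):
        X, y = blobs(rng)
        model = train_svm(X, y, SMALL_SVM, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_grid_of_size_one_is_selected(self, rng):
        X, y = blobs(rng)
        cfg = SVMConfig(c_grid=(3.0,), gamma_grid=(0.25,), cv_folds=3)
        model = train_svm(X, y, cfg)
        assert (model.C, model.gamma) == (3.0, 0.25)

    def test_label_permutation_null_accuracy(self, rng):
        # labels independent of features => CV accuracy near chance
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.svm import SVC

        accs = []
        for _ in range(20):
            X, y = blobs(rng, n=80)
            y = rng.permutation(y)
            cv = StratifiedKFold(3, shuffle=True, random_state=0)
            accs.append(cross_val_score(SVC(C=1.0, gamma=0.5), X, y, cv=cv).mean())
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            train_svm(X, ["ACP"] * 10, SMALL_SVM)


class TestRF:
    def test_separable_blobs_high_oob(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        X, y = blobs(rng, n=200)
        clf = RandomForestClassifier(n_estimators=100, oob_score=True, random_state=0)
        clf.fit(X, y)
        assert clf.oob_score_ > 0.95

    def test_same_seed_identical_predictions(self, rng):
        X, y = blobs(rng, n=100, sep=1.0)
        Q = rng.normal(size=(30, 4))
        a = train_rf(X, y, seed=42).predict(Q)
        b = train_rf(X, y, seed=42).predict(Q)
        np.testing.assert_array_equal(a, b)

    def test_single_tree_equals_its_bootstrap_tree(self, rng):
        X, y = blobs(rng, n=60, sep=1.5)
        forest = train_rf(X, y, n_trees=1, seed=3)
        Q = rng.normal(size=(20, 4))
        single = forest.estimators_[0]
        classes = forest.classes_
        np.testing.assert_array_equal(
            forest.predict(Q), classes[single.predict(Q).astype(int)]
        )


class TestNB:
    def test_symmetric_means_boundary_near_zero(self, rng):
        # 1-D classes at -3 and +3, unit variance: posterior crossover at 0
        X = np.concatenate([rng.normal(-3, 1, 500), rng.normal(3, 1, 500)])[:, None]
        y = np.array(["ACP"] * 500 + ["NACP"] * 500)
        model = train_nb(X, y)
        probe = np.linspace(-1, 1, 2001)[:, None]
        pred = model.predict(probe)
        flip = probe[np.argmax(pred != pred[0])][0]
        assert abs(flip) < 0.3

    def test_uninformative_features_give_prior(self, rng):
        X = rng.normal(size=(300, 2))
        y = np.array(["ACP"] * 100 + ["NACP"] * 200)
        model = train_nb(X, y)
        post = model.predict_proba(rng.normal(size=(50, 2))).mean(axis=0)
        prior = [1 / 3, 2 / 3] if list(model.classes_) == ["ACP", "NACP"] else [2 / 3, 1 / 3]
        np.testing.assert_allclose(post, prior, atol=0.15)

    def test_constant_feature_changes_nothing(self, rng):
        X, y = blobs(rng, n=80, sep=1.0)
        Xc = np.hstack([X, np.full((80, 1), 5.0)])
        Q = rng.normal(size=(25, 4))
        Qc = np.hstack([Q, np.full((25, 1), 5.0)])
        np.testing.assert_array_equal(train_nb(X, y).predict(Q), train_nb(Xc, y).predict(Qc))


class TestKNN:
    def test_query_equal_to_training_row(self, rng):
        X, y = blobs(rng, n=20, sep=1.0)
        model = train_knn(X, y, k=1)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_k_equals_n_gives_majority(self, rng):
        X = rng.normal(size=(9, 3))
        y = np.array(["ACP"] * 5 + ["NACP"] * 4)
        model = train_knn(X, y, k=9)
        assert set(model.predict(rng.normal(size=(10, 3)))) == {"ACP"}

    def test_five_point_hand_dataset_vs_enumeration(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        y = np.array(["ACP", "ACP", "NACP", "NACP", "NACP"])
        model = train_knn(X, y, k=3)
        for q in (-1.0, 0.5, 1.6, 5.9, 6.1, 12.0):
            d = np.abs(X[:, 0] - q)
            nearest = np.argsort(d, kind="stable")[:3]
            votes, counts = np.unique(y[nearest], return_counts=True)
            assert model.predict(np.array([[q]]))[0] == votes[np.argmax(counts)]

    def test_distance_tie_prefers_lower_row_index(self):
        X = np.array([[0.0], [2.0]])
        y = np.array(["NACP", "ACP"])
        assert train_knn(X, y, k=1).predict(np.array([[1.0]]))[0] == "NACP"

    def test_even_k_rejected(self, rng):
        X, y = blobs(rng, n=10)
        with pytest.raises(ValueError):
            train_knn(X, y, k=4)


class FixedVote:
    """Stub base classifier that always votes one label."""

    def __init__(self, label, dim=2):
        self.label = label
        self.shape_fit_ = (1, dim)

    def predict(self, X):
        return np.array([self.label] * len(X))


def stub_ensemble(votes, weights, tie_break="svm", majority="NACP"):
    svm, rf, nb = (FixedVote(v) for v in votes)
    return EnsembleModel(
        svm=svm, rf=rf, nb=nb, weights=weights, tie_break=tie_break, majority_class=majority
    )


def brute_vote(votes, weights, tie_break="svm", majority="NACP"):
    scores = {}
    for v, w in zip(votes, weights):
        scores[v] = scores.get(v, 0.0) + w
    top = max(scores.values())
    winners = sorted(c for c, s in scores.items() if s == top)
    if len(winners) == 1:
        return winners[0]
    return votes[0] if tie_break == "svm" else majority


class TestEnsembleVoting:
    def test_unanimity_any_weights(self, rng):
        for _ in range(5):
            w = tuple(rng.uniform(0.01, 1, 3))
            model = stub_ensemble(("ACP", "ACP", "ACP"), w)
            assert ensemble_predict(model, np.zeros((3, 2)))[0] == "ACP"

    def test_two_of_three_majority_equal_weights(self):
        model = stub_ensemble(("ACP", "ACP", "NACP"), (1.0, 1.0, 1.0))
        assert ensemble_predict(model, np.zeros((1, 2)))[0] == "ACP"

    def test_exact_tie_falls_to_svm_vote(self):
        model = stub_ensemble(("ACP", "NACP", "NACP"), (0.5, 0.25, 0.25))
        assert ensemble_predict(model, np.zeros((1, 2)))[0] == "ACP"

    def test_exact_tie_majority_class_mode(self):
        model = stub_ensemble(
            ("ACP", "NACP", "NACP"), (0.5, 0.25, 0.25), tie_break="majority_class"
        )
        assert ensemble_predict(model, np.zeros((1, 2)))[0] == "NACP"

    def test_all_patterns_times_seeded_weights_match_brute_force(self, rng):
        patterns = list(product(["ACP", "NACP"], repeat=3))
        for _ in range(50):
            w = tuple(rng.choice([0.0, 0.25, 0.5, 1.0], size=3))
            if not any(w):
                w = (1.0, 0.0, 0.0)
            for votes in patterns:
                model = stub_ensemble(votes, w)
                got = ensemble_predict(model, np.zeros((1, 2)))[0]
                assert got == brute_vote(votes, w)

    def test_weights_100_reduce_to_svm(self, rng):
        X, y = blobs(rng, n=80, sep=1.0)
        svm = train_svm(X, y, SMALL_SVM, seed=0)
        rf = train_rf(X, y, seed=0)
        nb = train_nb(X, y)
        model = EnsembleModel(svm=svm, rf=rf, nb=nb, weights=(1.0, 0.0, 0.0))
        Q = rng.normal(size=(40, 4))
        np.testing.assert_array_equal(ensemble_predict(model, Q), svm.predict(Q))

    def test_dimension_mismatch_rejected(self, rng):
        X, y = blobs(rng)
        model = fit_ensemble(X, y, svm_config=SMALL_SVM, seed=0)
        with pytest.raises(ValueError):
            ensemble_predict(model, np.zeros((2, 9)))


class TestFitEnsemble:
    def test_equal_mode_unit_weights(self, rng):
        X, y = blobs(rng)
        model = fit_ensemble(X, y, svm_config=SMALL_SVM, weight_mode="equal", seed=0)
        assert model.weights == (1.0, 1.0, 1.0)

    def test_cv_accuracy_weights_are_cv_scores(self, rng):
        X, y = blobs(rng, n=90, sep=1.5)
        model = fit_ensemble(X, y, svm_config=SMALL_SVM, weight_mode="cv_accuracy", seed=0)
        assert model.weights == model.base_cv_accuracy
        assert all(0 <= w <= 1 for w in model.weights)

    def test_equal_weight_prediction_is_majority_of_base_votes(self, rng):
        X, y = blobs(rng, n=100, sep=1.0)
        model = fit_ensemble(X, y, svm_config=SMALL_SVM, seed=1)
        Q = rng.normal(size=(50, 4))
        votes = model.base_votes(Q)
        majority = [
            v[np.argmax(c)] for v, c in (np.unique(row, return_counts=True) for row in votes)
        ]
        np.testing.assert_array_equal(model.predict(Q), majority)

    def test_row_order_invariance(self, rng):
        X, y = blobs(rng, n=80, sep=1.0)
        model = fit_ensemble(X, y, svm_config=SMALL_SVM, seed=0)
        Q = rng.normal(size=(30, 4))
        perm = rng.permutation(30)
        np.testing.assert_array_equal(model.predict(Q)[perm], model.predict(Q[perm]))

    def test_ensemble_competitive_with_bases(self, rng):
        # ensemble test accuracy >= best base - 0.05, averaged over repeats
        gaps = []
        for i in range(10):
            r = np.random.default_rng(100 + i)
            X, y = blobs(r, n=120, sep=2.0)
            Q, yq = blobs(r, n=60, sep=2.0)
            model = fit_ensemble(X, y, svm_config=SMALL_SVM, seed=i)
            base_acc = max(np.mean(m.predict(Q) == yq) for m in model.base_models)
            gaps.append(np.mean(model.predict(Q) == yq) - base_acc)
        assert np.mean(gaps) >= -0.05
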