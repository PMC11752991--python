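"""Chromosome decoding, CV fitness and the AFFWDI classifier."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from affwdi import learners as bl
from affwdi.estimator import (AFFWDIClassifier, Chromosome, cv_fitness,
                              decode)


def _chrom(mask, weights=None, hyper=(0.5,), n_hyper=1):
    mask = np.asarray(mask, float)
    weights = np.ones_like(mask) if weights is None else np.asarray(weights)
    return Chromosome(np.concatenate([mask, weights, hyper]),
                      n_features=mask.size, n_hyperparameters=n_hyper)


LR = bl.get_spec("lr", seed=0)


class TestDecode:
    def test_full_mask_selects_everything(self):
        sol = decode(_chrom([1, 1, 1]), ["a", "b", "c"], LR)
        assert sol.selected_features == ("a", "b", "c")

    def test_empty_mask_repaired_by_argmax(self):
        sol = decode(_chrom([0.1, 0.4, 0.2]), ["a", "b", "c"], LR)
        assert sol.selected_features == ("b",)

    def test_threshold_is_inclusive_at_half(self):
        sol = decode(_chrom([0.6, 0.4, 0.5]), ["a", "b", "c"], LR)
        assert sol.selected_features == ("a", "c")

    def test_weights_map_affinely_onto_unit_floor_interval(self):
        sol = decode(_chrom([1, 1], weights=[0.0, 1.0], hyper=(0.5,)),
                     ["a", "b"], LR)
        assert sol.feature_weights["a"] == pytest.approx(0.01)
        assert sol.feature_weights["b"] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            Chromosome(np.zeros(4), n_features=3, n_hyperparameters=1)
        with pytest.raises(ValueError, match="names"):
            decode(_chrom([1, 1]), ["a", "b", "c"], LR)

    def test_gene_range_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            Chromosome(np.array([1.5, 0.0, 0.0]), 1, 1)


class TestCvFitness:
    def test_perfectly_separable_feature_reaches_unit_accuracy(self,
                                                               separable_xy):
        X, y = separable_xy
        f = cv_fitness(_chrom([1, 1]), X, y, LR, ["a", "b"], cv_folds=5)
        assert f == 1.0

    def test_permuted_labels_give_chance_level(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((300, 4))
        y = np.repeat([0, 1], 150)
        f = cv_fitness(_chrom([1, 1, 1, 1]), X, rng.permutation(y), LR,
                       list("abcd"), cv_folds=5, seed=8)
        assert 0.35 <= f <= 0.65

    def test_deterministic_given_chromosome_and_seed(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((80, 3))
        y = (X[:, 0] + 0.5 * rng.standard_normal(80) > 0).astype(int)
        c = _chrom([1, 0.2, 1])
        f1 = cv_fitness(c, X, y, LR, list("abc"), seed=4)
        f2 = cv_fitness(c, X, y, LR, list("abc"), seed=4)
        assert f1 == f2

    def test_rare_class_smaller_than_fold_count_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        y = np.r_[np.ones(3, int), np.zeros(17, int)]
        with pytest.raises(ValueError, match="folds"):
            cv_fitness(_chrom([1, 1]), X, y, LR, ["a", "b"], cv_folds=5)

    def test_full_mask_unit_weights_match_independent_cv_exactly(self):
        """With every feature selected at weight 1, AFFWDI fitness must equal
        a plain, independently coded CV of the base learner on Z-scored
        features, fold for fold."""
        rng = np.random.default_rng(12)
        n = 200
        X = rng.standard_normal((n, 5))
        y = (X[:, 0] + X[:, 1] + 1.2 * rng.standard_normal(n) > 0).astype(int)
        names = list("abcde")
        seed = 12
        spec = bl.get_spec("lr", seed=seed)
        f = cv_fitness(_chrom([1] * 5, weights=[1] * 5, hyper=(0.5,)),
                       X, y, spec, names, cv_folds=5, seed=seed)
        hp = bl.decode_hyperparameters(spec, [0.5])
        accs = []
        for tr, te in StratifiedKFold(5, shuffle=True,
                                      random_state=seed).split(X, y):
            mu, sd = X[tr].mean(0), X[tr].std(0)
            est = LogisticRegression(C=hp["C"], max_iter=2000,
                                     solver="lbfgs")
            est.fit((X[tr] - mu) / sd, y[tr])
            accs.append(np.mean(est.predict((X[te] - mu) / sd) == y[te]))
        assert abs(f - np.mean(accs)) < 1e-12
        assert 0.5 < f < 1.0  # the check is only meaningful off saturation


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(21)
    n = 160
    X = pd.DataFrame({
        "signal_a": rng.standard_normal(n),
        "signal_b": rng.standard_normal(n),
        "noise": rng.standard_normal(n),
    })
    y = ((X["signal_a"] + X["signal_b"]
          + 1.0 * rng.standard_normal(n)) > 0).astype(int)
    return X, y


class TestAFFWDIClassifier:
    def _fast_clf(self, **kw):
        defaults = dict(base_learner="lr", population_size=6,
                        max_iterations=8, cv_folds=3, patience=None,
                        random_state=0)
        defaults.update(kw)
        return AFFWDIClassifier(**defaults)

    def test_fit_exposes_decoded_solution_and_fitness(self, small_problem):
        X, y = small_problem
        clf = self._fast_clf().fit(X, y)
        assert 0.0 <= clf.best_fitness_ <= 1.0
        assert len(clf.selected_features_) >= 1
        assert set(clf.selected_features_) <= set(X.columns)
        assert all(0.01 <= w <= 1.0 for w in clf.feature_weights_.values())
        proba = clf.predict_proba(X)
        assert proba.shape == (len(X), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_fit_is_deterministic_for_a_fixed_seed(self, small_problem):
        X, y = small_problem
        c1 = self._fast_clf(random_state=3).fit(X, y)
        c2 = self._fast_clf(random_state=3).fit(X, y)
        assert c1.selected_features_ == c2.selected_features_
        assert c1.best_fitness_ == c2.best_fitness_
        np.testing.assert_array_equal(c1.predict(X), c2.predict(X))

    def test_best_fitness_is_the_maximum_over_evaluations(self, small_problem):
        X, y = small_problem
        clf = self._fast_clf().fit(X, y)
        assert clf.best_fitness_ == pytest.approx(
            float(np.max(clf.convergence_trace_)), abs=1e-12)

    def test_standardization_comes_from_the_fitted_data_only(self,
                                                             small_problem):
        X, y = small_problem
        clf = self._fast_clf().fit(X, y)
        for j, name in enumerate(clf.selected_features_):
            assert clf.mean_[j] == pytest.approx(X[name].mean(), abs=1e-9)
        # a record at the training means standardizes to the origin
        record = {name: float(X[name].mean()) for name in
                  clf.selected_features_}
        row = pd.DataFrame([record])
        np.testing.assert_allclose(clf._transform(row), 0.0, atol=1e-9)

    def test_probability_boundary_is_labelled_poor(self, small_problem):
        X, y = small_problem
        clf = self._fast_clf().fit(X, y)

        class _Half:
            def predict_proba(self, Z):
                return np.tile([0.5, 0.5], (len(Z), 1))

        clf.learner_state_.estimator = _Half()
        record = {f: 0.0 for f in clf.selected_features_}
        prob, label = clf.predict_record(record)
        assert prob == 0.5 and label == 1

    def test_missing_selected_feature_named_in_error(self, small_problem):
        X, y = small_problem
        clf = self._fast_clf().fit(X, y)
        incomplete = {f: 0.0 for f in clf.selected_features_[1:]}
        with pytest.raises(ValueError, match=clf.selected_features_[0]):
            clf.predict_record(incomplete)

    def test_sklearn_param_protocol_and_clone(self):
        clf = self._fast_clf(random_state=7)
        params = clf.get_params()
        assert params["base_learner"] == "lr" and params["random_state"] == 7
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_single_class_target_rejected(self, small_problem):
        X, _ = small_problem
        with pytest.raises(ValueError, match="single class"):
            self._fast_clf().fit(X, np.zeros(len(X), int))
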