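"""Majority voting, base-learner training, grid search, and persistence."""

import itertools

import numpy as np
import pytest

from methylvote.ensemble import (
    ALGORITHMS,
    BaseClassifierSpec,
    default_specs,
    grid_search,
    load_model,
    majority_vote,
    save_model,
    train_base,
    train_ensemble,
)
from methylvote.sequence_io import SplitSpec, split_dataset
from methylvote.synthetic import SyntheticSpec, default_profile, generate


@pytest.fixture(scope="module")
def strong_synthetic():
    """n=150/150 windows at full enrichment: easily separable."""
    spec = SyntheticSpec(150, 150, default_profile(1.0), seed=5)
    data = generate(spec)
    return split_dataset(data, SplitSpec(train_fraction=0.8, seed=5))


class TestMajorityVote:
    def test_three_or_more_rule(self):
        assert majority_vote([1, 1, 1, 0, 0], 3) == 1
        assert majority_vote([1, 1, 0, 0, 0], 3) == 0
        assert majority_vote([0, 0, 0, 0, 0], 3) == 0

    def test_exhaustive_oracle_all_32_patterns(self):
        # independent oracle: direct count comparison
        for votes in itertools.product([0, 1], repeat=5):
            assert majority_vote(votes, 3) == (1 if sum(votes) >= 3 else 0)

    def test_symmetry_and_monotonicity(self):
        for votes in itertools.product([0, 1], repeat=5):
            label = majority_vote(votes, 3)
            # permutation symmetry
            assert majority_vote(votes[::-1], 3) == label
            # flipping a 0 to 1 never flips the label 1 -> 0
            for i, v in enumerate(votes):
                if v == 0:
                    flipped = list(votes)
                    flipped[i] = 1
                    assert majority_vote(flipped, 3) >= label

    def test_unanimity(self):
        assert majority_vote([1] * 5, 3) == 1
        assert majority_vote([0] * 5, 3) == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            majority_vote([], 1)
        with pytest.raises(ValueError):
            majority_vote([1, 0], 3)


def separable_toy(n=20, d=8):
    # all-ones vs all-zeros rows plus tiny jitter (LDA needs nonzero
    # within-class scatter); still trivially linearly separable
    jitter = np.random.default_rng(0).normal(scale=0.01, size=(2 * n, d))
    X = np.vstack([np.ones((n, d)), np.zeros((n, d))]) + jitter
    y = np.array([1] * n + [0] * n)
    return X, y


class TestTrainBase:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_data_perfect_fit(self, algorithm):
        X, y = separable_toy()
        clf = train_base(BaseClassifierSpec(algorithm, seed=0), X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_determinism_same_seed(self, rng):
        X = rng.normal(size=(60, 10))
        y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
        probe = rng.normal(size=(20, 10))
        spec = BaseClassifierSpec("RF", seed=42)
        p1 = train_base(spec, X, y).predict(probe)
        p2 = train_base(spec, X, y).predict(probe)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_base(BaseClassifierSpec("RF"), X, np.ones(10, dtype=int))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_base(BaseClassifierSpec("RF"), np.ones((10, 3)),
                       np.array([0, 1]))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            BaseClassifierSpec("SVM")


class TestGridSearch:
    def test_single_combination_returned(self):
        X, y = separable_toy()
        res = grid_search(BaseClassifierSpec("RF", seed=0),
                          {"n_estimators": [10]}, X, y, folds=2)
        assert res.best_params == {"n_estimators": 10}
        assert len(res.results) == 1

    def test_degenerate_value_loses(self, rng):
        # an over-regularized SGD predicts one class; the good alpha wins
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] > 0).astype(int)
        res = grid_search(BaseClassifierSpec("SGD", seed=0),
                          {"alpha": [1e-4, 1e6]}, X, y, folds=3)
        assert res.best_params == {"alpha": 1e-4}
        scores = dict((tuple(p.items()), s) for p, s in res.results)
        assert scores[(("alpha", 1e6),)] < 0.7

    def test_exhaustiveness(self):
        X, y = separable_toy()
        grid = {"n_estimators": [5, 10], "max_depth": [2, 3, None]}
        res = grid_search(BaseClassifierSpec("RF", seed=0), grid, X, y, folds=2)
        assert len(res.results) == 6
        assert res.best_score >= max(s for _, s in res.results
                                     if np.isfinite(s)) - 1e-12


class TestEnsemble:
    def test_recovery_on_strong_synthetic(self, strong_synthetic):
        train_set, test_set = strong_synthetic
        model = train_ensemble(train_set, "ONEHOT2", seed=0)
        acc = np.mean(model.predict(test_set) == test_set.label_array())
        assert acc > 0.9

    def test_determinism_identical_votes(self, strong_synthetic):
        train_set, test_set = strong_synthetic
        m1 = train_ensemble(train_set, "ONEHOT2", seed=3)
        m2 = train_ensemble(train_set, "ONEHOT2", seed=3)
        v1, l1 = m1.predict_votes(test_set)
        v2, l2 = m2.predict_votes(test_set)
        assert np.array_equal(v1, v2) and np.array_equal(l1, l2)

    def test_metadata_provenance(self, strong_synthetic):
        train_set, _ = strong_synthetic
        model = train_ensemble(train_set, "ONEHOT2", seed=0)
        assert model.metadata["encoder"] == "ONEHOT2"
        assert model.metadata["algorithms"] == list(ALGORITHMS)
        assert model.metadata["seed"] == 0

    def test_label_equals_vote_recount(self, strong_synthetic):
        train_set, test_set = strong_synthetic
        model = train_ensemble(train_set, "ONEHOT2", seed=0)
        votes, labels = model.predict_votes(test_set)
        recount = [majority_vote(row, model.vote_threshold) for row in votes]
        assert np.array_equal(labels, recount)

    def test_invalid_windows_listed(self, strong_synthetic):
        from methylvote.sequence_io import DnaWindow

        train_set, _ = strong_synthetic
        model = train_ensemble(train_set, "ONEHOT2", seed=0)
        with pytest.raises(ValueError, match="bad_center"):
            model.predict([DnaWindow("G" * 41, "bad_center")])
        with pytest.raises(ValueError, match="too_short"):
            model.predict([DnaWindow("C" * 10 + "A" + "C" * 10, "too_short")])

    def test_grid_search_inside_training(self, strong_synthetic):
        train_set, test_set = strong_synthetic
        model = train_ensemble(
            train_set, "ONEHOT1",
            specs=[BaseClassifierSpec("RF", seed=0),
                   BaseClassifierSpec("LDA", seed=1),
                   BaseClassifierSpec("SGD", seed=2)],
            grids={"RF": {"n_estimators": [20, 50]}},
            folds=2, seed=0, vote_threshold=2,
        )
        assert "RF" in model.metadata["grid_search"]
        assert model.metadata["grid_search"]["RF"]["best_params"][
            "n_estimators"] in (20, 50)
        assert np.mean(model.predict(test_set) == test_set.label_array()) > 0.9

    def test_save_load_round_trip(self, strong_synthetic, tmp_path):
        train_set, test_set = strong_synthetic
        model = train_ensemble(train_set, "ONEHOT2", seed=0)
        before_votes, before_labels = model.predict_votes(test_set)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        after_votes, after_labels = loaded.predict_votes(test_set)
        assert np.array_equal(before_votes, after_votes)
        assert np.array_equal(before_labels, after_labels)

    def test_default_specs_cover_all_algorithms(self):
        assert [s.algorithm for s in default_specs()] == list(ALGORITHMS)
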