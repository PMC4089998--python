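"""FLD classifier, cross-validation accuracy, and permutation null."""

import numpy as np
import pytest

from chromodor import (
    GeneratorConfig,
    ValidationError,
    cv_accuracy,
    fld_fit,
    fld_predict,
    generate_dataset,
    null_dataset,
    permutation_test,
)
from chromodor.data import Dataset
import pandas as pd


def _identical_participants_dataset(n=9, odors=("burnt", "candy", "fish")):
    """Every participant answers identically; odors have distinct choices."""
    rows = []
    for p in range(n):
        for oi, odor in enumerate(odors):
            cong = [1 + 2 * oi, 2 + 2 * oi, 30 + oi]
            incong = [10 + 2 * oi, 11 + 2 * oi, 25 + oi]
            for c in cong:
                rows.append(("g", f"p{p}", odor, "congruent", c))
            for c in incong:
                rows.append(("g", f"p{p}", odor, "incongruent", c))
    return Dataset(pd.DataFrame(rows, columns=["group", "participant", "odor",
                                               "choice_type", "color_id"]))


class TestFldFit:
    def test_one_dimensional_class_means(self):
        X = np.array([[-1.1], [-0.9], [0.9], [1.1]])
        y = ["a", "a", "b", "b"]
        model = fld_fit(X, y, shrinkage=0.5)
        np.testing.assert_allclose(model.class_means.ravel(), [-1.0, 1.0])

    def test_duplicating_patterns_leaves_model_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        y = np.repeat([0, 1, 2], 4)
        m1 = fld_fit(X, y, shrinkage=0.3)
        m2 = fld_fit(np.vstack([X, X]), np.concatenate([y, y]), shrinkage=0.3)
        np.testing.assert_allclose(m1.class_means, m2.class_means)
        np.testing.assert_allclose(m1.covariance, m2.covariance)

    def test_auto_shrinkage_yields_positive_definite_covariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 72))  # far fewer samples than features
        y = np.repeat(np.arange(5), 2)
        model = fld_fit(X, y, shrinkage="auto")
        assert 0.0 < model.shrinkage <= 1.0
        assert np.linalg.eigvalsh(model.covariance).min() > 0

    def test_errors(self):
        with pytest.raises(ValidationError):
            fld_fit(np.zeros((3, 2)), ["a", "a", "a"])  # one class
        with pytest.raises(ValidationError):
            fld_fit(np.zeros((3, 2)), ["a", "b"])  # label length mismatch
        with pytest.raises(ValidationError):
            fld_fit(np.random.default_rng(0).normal(size=(4, 6)),
                    ["a", "a", "b", "b"], shrinkage=1.5)


class TestFldPredict:
    def test_nearer_mean_wins_in_one_dimension(self):
        model = fld_fit(np.array([[-1.1], [-0.9], [0.9], [1.1]]),
                        ["a", "a", "b", "b"], shrinkage=1.0)
        assert fld_predict(model, [[-1.05]])[0] == "a"

    def test_tie_broken_by_first_label(self):
        model = fld_fit(np.array([[-1.0], [-1.0], [1.0], [1.0]]),
                        ["x", "x", "y", "y"], shrinkage=1.0)
        # the origin is exactly equidistant; covariance target is identity
        assert fld_predict(model, [[0.0]])[0] == "x"

    def test_dimension_mismatch(self):
        model = fld_fit(np.array([[-1.0], [1.0]]), ["a", "b"], shrinkage=1.0)
        with pytest.raises(ValidationError, match="dimension"):
            fld_predict(model, [[0.0, 1.0]])

    def test_full_shrinkage_equals_nearest_class_mean_oracle(self):
        """At shrinkage 1 the metric is spherical, so FLD must reproduce a
        brute-force nearest-class-mean classifier on random instances."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            d = int(rng.integers(1, 8))
            n_per = int(rng.integers(1, 5))
            X = rng.normal(size=(k * n_per, d))
            y = np.repeat(np.arange(k), n_per)
            model = fld_fit(X, y, shrinkage=1.0)
            T = rng.normal(size=(10, d))
            pred = fld_predict(model, T)
            means = np.stack([X[y == c].mean(0) for c in range(k)])
            d2 = ((T[:, None, :] - means[None]) ** 2).sum(-1)
            oracle = np.argmin(d2, axis=1)  # argmin takes the first on ties
            np.testing.assert_array_equal(pred, oracle)

    def test_matches_reference_lda_with_fixed_shrinkage(self):
        """Independent cross-check against a reference shrunken-covariance
        LDA on a random multi-class problem."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 12))
        y = np.repeat(np.arange(3), 10)
        X[y == 1] += 0.8
        X[y == 2] -= 0.5
        s = 0.4
        ours = fld_predict(fld_fit(X, y, shrinkage=s), X)
        ref = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=s, priors=np.full(3, 1 / 3)
        ).fit(X, y)
        np.testing.assert_array_equal(ours, ref.predict(X))


class TestCvAccuracy:
    def test_identical_participants_classify_perfectly(self):
        ds = _identical_participants_dataset()
        acc = cv_accuracy(ds, "g", n_folds=3, n_shuffles=8, seed=0)
        np.testing.assert_allclose(acc, 1.0)

    def test_null_data_accuracy_near_chance(self):
        cfg = GeneratorConfig(groups={f"g{i}": 20 for i in range(6)}, seed=0)
        ds = null_dataset(cfg)
        means = [cv_accuracy(ds, g, n_shuffles=40, seed=i).mean()
                 for i, g in enumerate(ds.groups)]
        assert abs(np.mean(means) - 1 / 14) < 0.025

    def test_strong_associations_classify_above_half(self):
        cfg = GeneratorConfig(groups={"g": 12}, odors=GeneratorConfig().odors[:8],
                              kappa=0.05, rho=0.0, seed=21)
        ds = generate_dataset(cfg)
        assert cv_accuracy(ds, "g", n_shuffles=15, seed=2).mean() > 0.5

    def test_accuracy_granularity(self, group20_dataset):
        acc = cv_accuracy(group20_dataset, "solo", n_shuffles=10, seed=3)
        grid = acc * (3 * len(group20_dataset.odors))
        np.testing.assert_allclose(grid, np.round(grid), atol=1e-9)

    def test_seed_determinism(self, group20_dataset):
        a = cv_accuracy(group20_dataset, "solo", n_shuffles=6, seed=9)
        b = cv_accuracy(group20_dataset, "solo", n_shuffles=6, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_global_color_relabeling_invariance(self, group20_dataset):
        perm = np.random.default_rng(5).permutation(36) + 1
        relabeled = group20_dataset.relabel_colors(perm)
        a = cv_accuracy(group20_dataset, "solo", n_shuffles=8, seed=4)
        b = cv_accuracy(relabeled, "solo", n_shuffles=8, seed=4)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_fold_count_errors(self, group20_dataset):
        with pytest.raises(ValidationError):
            cv_accuracy(group20_dataset, "solo", n_folds=21, n_shuffles=1)


class TestPermutationTest:
    def test_null_distribution_mean_at_chance(self, group20_dataset):
        res = permutation_test(group20_dataset, "solo", n_shuffles=20,
                               n_permutations=300, seed=1)
        chance = 1 / 14
        se = res.null_distribution.std(ddof=1) / np.sqrt(300)
        assert abs(res.null_distribution.mean() - chance) < 3 * se + 0.005

    def test_perfectly_consistent_data_attains_minimal_p(self):
        ds = _identical_participants_dataset()
        res = permutation_test(ds, "g", n_shuffles=5, n_permutations=99,
                               seed=2)
        assert res.mean_accuracy == 1.0
        assert res.p == pytest.approx(1 / 100)

    def test_structured_data_beats_null(self, group20_dataset):
        res = permutation_test(group20_dataset, "solo", n_shuffles=20,
                               n_permutations=200, seed=3)
        assert res.mean_accuracy > res.null_distribution.mean()
        assert res.p < 0.05

    def test_type_one_error_control_on_null_data(self):
        """Null data should rarely reach significance (seeded replicates)."""
        high_p = 0
        n_reps = 15
        for seed in range(n_reps):
            cfg = GeneratorConfig(groups={"g": 15},
                                  odors=GeneratorConfig().odors[:8],
                                  seed=7000 + seed)
            ds = null_dataset(cfg)
            res = permutation_test(ds, "g", n_shuffles=10,
                                   n_permutations=120, seed=seed)
            high_p += res.p > 0.05
        assert high_p >= int(0.8 * n_reps)

    def test_global_permutation_scheme_preserves_structure(self, group20_dataset):
        """A single shared permutation per repetition keeps within-group
        agreement, so its null tracks the observed accuracy, unlike the
        per-trial null."""
        per_trial = permutation_test(group20_dataset, "solo", n_shuffles=10,
                                     n_permutations=60, seed=8, per_trial=True)
        shared = permutation_test(group20_dataset, "solo", n_shuffles=10,
                                  n_permutations=60, seed=8, per_trial=False)
        assert shared.null_distribution.mean() > per_trial.null_distribution.mean()
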