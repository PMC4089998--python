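"""First- and second-order representational dissimilarity analysis."""

import numpy as np
import pytest

from chromodor import (
    GeneratorConfig,
    Rdm,
    UndefinedCorrelationError,
    ValidationError,
    bootstrap_rdm_null,
    compute_rdm,
    draw_profiles,
    generate_dataset,
    pattern_dissimilarity,
    second_order_rdm,
)

ODORS_3 = ("burnt", "candy", "fish")


class TestPatternDissimilarity:
    def test_identical_patterns_are_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pattern_dissimilarity(a, a) == pytest.approx(0.0)

    def test_affine_transform_is_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pattern_dissimilarity(a, 5 * a + 2) == pytest.approx(0.0)

    def test_reversal_is_two(self):
        assert pattern_dissimilarity([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(2.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pattern_dissimilarity([1, 1, 1], [1, 2, 3])

    def test_shape_errors(self):
        with pytest.raises(ValidationError):
            pattern_dissimilarity([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            pattern_dissimilarity([1, 2, 3], [1, 2, 3, 4])


class TestRdmType:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError, match="symmetric"):
            Rdm(("a", "b"), np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValidationError, match="diagonal"):
            Rdm(("a", "b"), np.array([[0.1, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError, match=r"\[0, 2\]"):
            Rdm(("a", "b"), np.array([[0.0, 2.5], [2.5, 0.0]]))

    def test_reorder_permutes_consistently(self):
        m = np.array([[0.0, 0.3, 0.8], [0.3, 0.0, 1.1], [0.8, 1.1, 0.0]])
        rdm = Rdm(("a", "b", "c"), m)
        back = rdm.reordered(("c", "a", "b")).reordered(("a", "b", "c"))
        np.testing.assert_allclose(back.matrix, m)


class TestComputeRdm:
    def test_diagonal_zero_and_symmetric(self, group20_dataset):
        rdm = compute_rdm(group20_dataset, "solo")
        assert rdm.matrix.shape == (14, 14)
        assert (np.diag(rdm.matrix) == 0.0).all()
        np.testing.assert_allclose(rdm.matrix, rdm.matrix.T)
        assert rdm.matrix.min() >= 0 and rdm.matrix.max() <= 2

    def test_identical_odor_data_gives_zero_cell(self):
        cfg = GeneratorConfig(groups={"g": 8}, odors=ODORS_3, seed=2)
        profiles = draw_profiles(cfg)
        lookup = {(p.group, p.odor): p for p in profiles}
        # give two odors the same profile AND the same realized choices by
        # cloning candy's records onto burnt
        ds = generate_dataset(cfg, profiles=profiles)
        df = ds.records.copy()
        candy = df[df["odor"] == "candy"].copy()
        candy["odor"] = "burnt"
        df = df[df["odor"] != "burnt"]
        import pandas as pd

        from chromodor.data import Dataset

        ds2 = Dataset(pd.concat([df, candy]), odors=ODORS_3, groups=("g",))
        rdm = compute_rdm(ds2, "g")
        i, j = rdm.labels.index("burnt"), rdm.labels.index("candy")
        assert rdm.matrix[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_congruent_only_mask(self, group20_dataset):
        mask = np.zeros(72, dtype=bool)
        mask[:36] = True
        rdm = compute_rdm(group20_dataset, "solo", feature_mask=mask)
        assert rdm.matrix.shape == (14, 14)

    def test_global_color_relabeling_invariance(self, group20_dataset):
        perm = np.random.default_rng(11).permutation(36) + 1
        a = compute_rdm(group20_dataset, "solo").matrix
        b = compute_rdm(group20_dataset.relabel_colors(perm), "solo").matrix
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_planted_shared_odor_pair_is_most_similar(self):
        hits = 0
        n_reps = 20
        for seed in range(n_reps):
            cfg = GeneratorConfig(groups={"g": 20}, odors=ODORS_3, kappa=0.1,
                                  rho=0.0, seed=3000 + seed)
            profiles = draw_profiles(cfg)
            lookup = {(p.group, p.odor): p for p in profiles}
            shared = lookup[("g", "burnt")]
            lookup[("g", "candy")] = type(shared)(
                "g", "candy", shared.p_cong, shared.p_incong)
            ds = generate_dataset(cfg, profiles=list(lookup.values()))
            rdm = compute_rdm(ds, "g")
            i, j, k = (rdm.labels.index(o) for o in ODORS_3)
            d_pair = rdm.matrix[i, j]
            hits += d_pair < min(rdm.matrix[i, k], rdm.matrix[j, k])
        assert hits >= int(0.9 * n_reps)


class TestBootstrapNull:
    def test_values_in_range_and_shape(self, group20_dataset):
        null = bootstrap_rdm_null(group20_dataset, "solo", n_reps=30, seed=1)
        assert null.shape == (30, 14 * 13 // 2)
        assert null.min() >= 0 and null.max() <= 2

    def test_null_mean_near_one_for_independent_patterns(self, group20_null):
        null = bootstrap_rdm_null(group20_null, "solo", n_reps=400, seed=2)
        assert abs(null.mean() - 1.0) < 0.05

    def test_shared_pair_observed_below_null_fifth_percentile(self):
        cfg = GeneratorConfig(groups={"g": 20}, odors=ODORS_3, kappa=0.1,
                              rho=0.0, seed=17)
        profiles = draw_profiles(cfg)
        lookup = {(p.group, p.odor): p for p in profiles}
        shared = lookup[("g", "burnt")]
        lookup[("g", "candy")] = type(shared)("g", "candy", shared.p_cong,
                                              shared.p_incong)
        ds = generate_dataset(cfg, profiles=list(lookup.values()))
        rdm = compute_rdm(ds, "g")
        null = bootstrap_rdm_null(ds, "g", n_reps=300, seed=18)
        i, j = rdm.labels.index("burnt"), rdm.labels.index("candy")
        assert rdm.matrix[i, j] < np.quantile(null.ravel(), 0.05)

    def test_participant_bootstrap_scheme(self, group20_dataset):
        boot = bootstrap_rdm_null(group20_dataset, "solo", n_reps=20, seed=3,
                                  scheme="participant-bootstrap")
        assert boot.shape == (20, 91)
        assert boot.min() >= 0 and boot.max() <= 2

    def test_unknown_scheme_rejected(self, group20_dataset):
        with pytest.raises(ValidationError, match="scheme"):
            bootstrap_rdm_null(group20_dataset, "solo", scheme="nope")

    def test_seed_determinism(self, group20_dataset):
        a = bootstrap_rdm_null(group20_dataset, "solo", n_reps=5, seed=4)
        b = bootstrap_rdm_null(group20_dataset, "solo", n_reps=5, seed=4)
        np.testing.assert_array_equal(a, b)


class TestSecondOrder:
    def test_identical_rdms_give_zero(self, group20_dataset):
        rdm = compute_rdm(group20_dataset, "solo")
        second = second_order_rdm({"a": rdm, "b": rdm})
        assert second.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_identical_group_data_give_zero(self, small_dataset):
        rdm_a = compute_rdm(small_dataset, "alpha")
        second = second_order_rdm({"x": rdm_a, "y": rdm_a, "z": rdm_a})
        np.testing.assert_allclose(second.matrix, 0.0, atol=1e-12)

    def test_mismatched_odor_order_rejected(self, small_dataset):
        rdm = compute_rdm(small_dataset, "alpha")
        scrambled = rdm.reordered(tuple(reversed(rdm.labels)))
        with pytest.raises(ValidationError, match="labels"):
            second_order_rdm({"a": rdm, "b": scrambled})

    def test_odor_order_leaves_second_order_unchanged(self, small_dataset):
        rdm_a = compute_rdm(small_dataset, "alpha")
        rdm_b = compute_rdm(small_dataset, "beta")
        base = second_order_rdm({"a": rdm_a, "b": rdm_b}).matrix
        new_order = tuple(reversed(rdm_a.labels))
        permuted = second_order_rdm(
            {"a": rdm_a.reordered(new_order), "b": rdm_b.reordered(new_order)}
        ).matrix
        np.testing.assert_allclose(base, permuted, atol=1e-12)

    def test_spearman_variant(self, small_dataset):
        rdms = {g: compute_rdm(small_dataset, g) for g in small_dataset.groups}
        s = second_order_rdm(rdms, method="spearman")
        assert s.matrix.min() >= 0 and s.matrix.max() <= 2

    def test_needs_two_groups(self, small_dataset):
        with pytest.raises(ValidationError):
            second_order_rdm({"a": compute_rdm(small_dataset, "alpha")})
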