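import numpy as np
import pandas as pd
import pytest

import lettersim as ls
from lettersim.models import (
    ActivationSet,
    FeatureMask,
    apply_mask,
    categ_convention_rdm,
    categorical_rdm,
    image_level_rdm,
    intuitive_rdm,
    pool_feature_maps,
    random_matched_masks,
    search_convention_rdm,
    select_letter_preferring,
)
from lettersim.rdm import lower_triangle, spearman_rdm


def grid_acts(X, letters, fonts, stage="s"):
    return ActivationSet(stage, X, letters, fonts)


class TestPooling:
    def test_all_ones_13x13_map_pools_to_169(self):
        raw = np.ones((1, 1, 13, 13))
        acts = pool_feature_maps(raw)
        assert acts.activations[0, 0] == pytest.approx(169.0)

    def test_256_feature_maps_yield_256_dim_vectors(self, rng):
        raw = rng.random((3, 256, 13, 13))
        acts = pool_feature_maps(raw)
        assert acts.activations.shape == (3, 256)
        np.testing.assert_allclose(acts.activations, raw.sum(axis=(2, 3)))

    def test_1x1_maps_pool_to_identity(self, rng):
        raw = rng.random((4, 7, 1, 1))
        acts = pool_feature_maps(raw)
        np.testing.assert_allclose(acts.activations, raw[:, :, 0, 0])

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            pool_feature_maps(np.zeros((2, 3, 4)))


class TestSearchConvention:
    def test_two_letter_two_font_oracle(self):
        # letters a,b in fonts f1,f2 with 2-dim activations
        X = np.array([[0.0, 0.0], [1.0, 1.0],   # a in f1, f2
                      [3.0, 4.0], [1.0, 4.0]])  # b in f1, f2
        acts = grid_acts(X, ["a", "a", "b", "b"], ["f1", "f2", "f1", "f2"])
        rdm = search_convention_rdm(acts)
        d1 = np.sqrt(3.0**2 + 4.0**2)  # within f1
        d2 = np.sqrt(0.0**2 + 3.0**2)  # within f2
        assert rdm.values[0, 1] == pytest.approx((d1 + d2) / 2)

    def test_identical_letters_at_zero_distance(self, rng):
        row = rng.random(5)
        X = np.vstack([row, row, row, row])
        acts = grid_acts(X, ["a", "a", "b", "b"], ["f1", "f2", "f1", "f2"])
        assert search_convention_rdm(acts).values[0, 1] == pytest.approx(0.0)

    def test_feature_permutation_invariance(self, rng):
        X = rng.random((6, 8))
        acts = grid_acts(X, list("aabbcc"), ["f1", "f2"] * 3)
        perm = rng.permutation(8)
        acts_p = grid_acts(X[:, perm], list("aabbcc"), ["f1", "f2"] * 3)
        np.testing.assert_allclose(
            search_convention_rdm(acts).values, search_convention_rdm(acts_p).values
        )

    def test_zero_feature_padding_invariance_euclidean(self, rng):
        X = rng.random((4, 3))
        labels = (["a", "a", "b", "b"], ["f1", "f2", "f1", "f2"])
        padded = np.hstack([X, np.zeros((4, 2))])
        np.testing.assert_allclose(
            search_convention_rdm(grid_acts(X, *labels)).values,
            search_convention_rdm(grid_acts(padded, *labels)).values,
        )

    def test_single_font_equals_plain_pairwise_distances(self, rng):
        from scipy.spatial.distance import pdist, squareform

        X = rng.random((4, 6))
        acts = grid_acts(X, list("abcd"), ["f"] * 4)
        np.testing.assert_allclose(
            search_convention_rdm(acts).values, squareform(pdist(X))
        )

    def test_incomplete_grid_rejected(self, rng):
        acts = grid_acts(rng.random((3, 2)), ["a", "a", "b"], ["f1", "f2", "f1"])
        with pytest.raises(ValueError, match="grid"):
            search_convention_rdm(acts)


class TestCategConvention:
    def test_two_letter_two_font_one_dim_oracle(self):
        # a: 0 and 2 (template 1); b: 10 and 14 (template 12)
        X = np.array([[0.0], [2.0], [10.0], [14.0]])
        acts = grid_acts(X, ["a", "a", "b", "b"], ["f1", "f2", "f1", "f2"])
        rdm = categ_convention_rdm(acts)
        d_ab = (abs(0 - 12) + abs(2 - 12)) / 2  # exemplars of a vs template b
        d_ba = (abs(10 - 1) + abs(14 - 1)) / 2  # exemplars of b vs template a
        assert rdm.values[0, 1] == pytest.approx((d_ab + d_ba) / 2)

    def test_font_invariant_letters_sit_on_their_templates(self, rng):
        rows = rng.random((2, 4))
        X = np.vstack([rows[0], rows[0], rows[1], rows[1]])
        acts = grid_acts(X, ["a", "a", "b", "b"], ["f1", "f2", "f1", "f2"])
        rdm = categ_convention_rdm(acts)
        d = np.linalg.norm(rows[0] - rows[1])
        assert rdm.values[0, 1] == pytest.approx(d)

    def test_differs_from_search_convention_under_font_variation(self):
        X = np.array([[0.0], [4.0], [1.0], [3.0]])
        acts = grid_acts(X, ["a", "a", "b", "b"], ["f1", "f2", "f1", "f2"])
        s = search_convention_rdm(acts).values[0, 1]
        c = categ_convention_rdm(acts).values[0, 1]
        assert s != pytest.approx(c)


class TestImageAndCategoricalRDMs:
    def test_three_image_oracle(self, rng):
        from scipy.spatial.distance import pdist, squareform

        X = rng.random((3, 4))
        acts = grid_acts(X, list("abc"), list("fgh"))
        np.testing.assert_allclose(
            image_level_rdm(acts).values, squareform(pdist(X))
        )

    def test_duplicate_images_at_zero_distance(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        acts = grid_acts(X, ["a", "b"], ["f", "f"])
        assert image_level_rdm(acts).values[0, 1] == pytest.approx(0.0)

    def test_full_grid_yields_520x520(self):
        letters = np.repeat([chr(97 + i) for i in range(26)], 20)
        fonts = np.tile([f"f{k}" for k in range(20)], 26)
        acts = grid_acts(np.random.default_rng(0).random((520, 3)), letters, fonts)
        assert image_level_rdm(acts).n_items == 520

    def test_categorical_geometry(self):
        rdm = categorical_rdm(["a", "a", "b", "c"])
        assert rdm.values[0, 1] == pytest.approx(0.0)
        assert rdm.values[0, 2] == pytest.approx(np.sqrt(2))
        assert rdm.values[2, 3] == pytest.approx(np.sqrt(2))

    def test_categorical_rank_structure(self):
        labels = ["a", "a", "b", "b", "c"]
        vec = lower_triangle(categorical_rdm(labels)).values
        assert spearman_rdm(vec, vec) == pytest.approx(1.0)
        assert spearman_rdm(vec, -vec) == pytest.approx(-1.0)


class TestLetterPreferringSelection:
    def test_separating_feature_selected(self, rng):
        n = 30
        L = rng.normal(5.0, 1.0, (n, 3))
        O = rng.normal(0.0, 1.0, (n, 3))
        L[:, 1] = O[: n, 1] = 0.0  # all-zero feature
        L[:, 2] = rng.normal(0.0, 1.0, n)  # undifferentiated feature
        with pytest.warns(UserWarning, match="undefined variance"):
            mask = select_letter_preferring(
                grid_acts(L, ["a"] * n, ["f"] * n),
                grid_acts(O, ["obj"] * n, ["f"] * n),
            )
        assert mask.keep[0]
        assert not mask.keep[1]  # degenerate, flagged, never selected

    def test_mask_metadata_shapes(self, rng):
        L = rng.normal(size=(10, 6))
        O = rng.normal(size=(12, 6))
        mask = select_letter_preferring(
            grid_acts(L, ["a"] * 10, ["f"] * 10), grid_acts(O, ["o"] * 12, ["f"] * 12)
        )
        assert mask.keep.shape == mask.pvalue.shape == (6,)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            select_letter_preferring(
                grid_acts(rng.random((5, 3)), ["a"] * 5, ["f"] * 5),
                grid_acts(rng.random((5, 4)), ["o"] * 5, ["f"] * 5),
            )


class TestRandomMatchedMasks:
    def test_pool_equal_to_mask_size_returns_the_pool(self):
        mask = FeatureMask("s", [True, True, False, False])
        pool = np.array([False, False, True, True])
        out = random_matched_masks(mask, pool, 5, seed=0)
        for m in out:
            np.testing.assert_array_equal(m.keep, pool)

    def test_hundred_samples_of_matching_cardinality(self):
        rng = np.random.default_rng(3)
        keep = np.zeros(50, dtype=bool)
        keep[:7] = True
        pool = ~keep
        out = random_matched_masks(FeatureMask("s", keep), pool, 100, seed=1)
        assert len(out) == 100
        assert all(m.n_selected == 7 for m in out)
        assert all(not np.any(m.keep & keep) for m in out)

    def test_seed_reproduces_mask_list(self):
        keep = np.array([True] * 3 + [False] * 20)
        pool = ~keep
        a = random_matched_masks(FeatureMask("s", keep), pool, 10, seed=4)
        b = random_matched_masks(FeatureMask("s", keep), pool, 10, seed=4)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.keep, mb.keep)

    def test_insufficient_pool_rejected(self):
        mask = FeatureMask("s", [True, True, True, False])
        with pytest.raises(ValueError):
            random_matched_masks(mask, [False, False, False, True], 1, seed=0)

    def test_full_mask_subspace_equals_full_space(self, rng):
        X = rng.random((4, 5))
        acts = grid_acts(X, ["a", "a", "b", "b"], ["f1", "f2", "f1", "f2"])
        mask = FeatureMask("s", np.ones(5, dtype=bool))
        np.testing.assert_allclose(
            search_convention_rdm(apply_mask(acts, mask)).values,
            search_convention_rdm(acts).values,
        )


class TestIntuitiveRDM:
    def test_identical_rows_at_zero(self):
        t = pd.DataFrame({"letter": ["a", "b"], "f1": [2, 2], "f2": [1, 1]})
        assert intuitive_rdm(t).values[0, 1] == pytest.approx(0.0)

    def test_unit_vectors_at_sqrt2(self):
        t = pd.DataFrame({"letter": ["a", "b"], "f1": [1, 0], "f2": [0, 1]})
        assert intuitive_rdm(t).values[0, 1] == pytest.approx(np.sqrt(2))

    def test_three_letter_oracle(self):
        t = pd.DataFrame(
            {"letter": ["a", "b", "c"], "f1": [1, 0, 2], "f2": [0, 3, 1]}
        )
        rdm = intuitive_rdm(t)
        X = t[["f1", "f2"]].to_numpy(float)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert rdm.values[i, j] == pytest.approx(np.linalg.norm(X[i] - X[j]))

    def test_negative_counts_rejected(self):
        t = pd.DataFrame({"letter": ["a"], "f1": [-1]})
        with pytest.raises(ValueError):
            intuitive_rdm(t)

    def test_synthetic_table_runs_both_conventions(self):
        t = ls.synthetic_intuitive_table("abcdef")
        assert len(t) == 6
        s = intuitive_rdm(t, convention="search")
        c = intuitive_rdm(t, convention="categ")
        assert s.n_items == c.n_items == 6


class TestIO:
    def test_npz_round_trip(self, tmp_path, rng):
        acts = grid_acts(rng.random((4, 3)), ["a", "a", "b", "b"],
                         ["f1", "f2", "f1", "f2"], stage="layer3")
        acts.save_npz(tmp_path / "a.npz")
        back = ActivationSet.load_npz(tmp_path / "a.npz")
        assert back.stage == "layer3"
        np.testing.assert_allclose(back.activations, acts.activations)
        assert back.letters.tolist() == acts.letters.tolist()
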