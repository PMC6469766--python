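import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mitoprox import (
    ConfigurationError,
    InputError,
    ProximityConfig,
    average_masks,
    percent_overlap,
    proximity_index,
    window_proximity,
    window_ratio_factor,
    window_size_sweep,
)
from oracles import brute_overlap, naive_proximity_index

masks_8x8 = hnp.arrays(np.bool_, (8, 8))


class TestPercentOverlap:
    def test_identical_nonempty_masks_give_complete_overlap(self, random_mask_pair):
        a, _ = random_mask_pair
        r = percent_overlap(a, a)
        assert r.overlap == 1.0 and r.overlap_percent == 100.0
        assert r.common == r.union == a.sum()

    def test_disjoint_masks_give_zero_overlap(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[:5], b[5:] = True, True
        r = percent_overlap(a, b)
        assert r.overlap == 0.0 and r.common == 0 and r.union == 100

    def test_partial_overlap_counts(self):
        # A and B have 4 px each, sharing 2: common 2, union 6
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0:4] = True
        b[0, 2:4] = True
        b[1, 0:2] = True
        r = percent_overlap(a, b)
        assert (r.common, r.union) == (2, 6)
        assert r.overlap_percent == pytest.approx(100 * 2 / 6)

    def test_matches_brute_force_counting(self, rng):
        for _ in range(20):
            a = rng.random((16, 16)) < 0.4
            b = rng.random((16, 16)) < 0.4
            common, union, frac = brute_overlap(a, b)
            r = percent_overlap(a, b)
            assert (r.common, r.union, r.overlap) == (common, union, frac)

    def test_empty_masks_warn_and_define_zero(self):
        with pytest.warns(RuntimeWarning):
            r = percent_overlap(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))
        assert r.overlap == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            percent_overlap(np.ones((4, 4), dtype=bool), np.ones((4, 5), dtype=bool))

    @given(a=masks_8x8, b=masks_8x8)
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        if not (a.any() or b.any()):
            return
        r1, r2 = percent_overlap(a, b), percent_overlap(b, a)
        assert r1.overlap == r2.overlap
        assert 0.0 <= r1.overlap <= 1.0

    @given(a=masks_8x8, sub=masks_8x8)
    @settings(max_examples=100, deadline=None)
    def test_subset_overlap_is_area_ratio(self, a, sub):
        b = a & sub  # b is a subset of a
        if not a.any():
            return
        r = percent_overlap(a, b)
        assert r.overlap == b.sum() / a.sum()


class TestAverageAndWindowPrimitives:
    def test_average_values(self):
        a = np.array([[1, 1, 0, 0]], dtype=bool)
        b = np.array([[1, 0, 1, 0]], dtype=bool)
        np.testing.assert_array_equal(average_masks(a, b), [[1.0, 0.5, 0.5, 0.0]])

    def test_average_equals_elementwise_mean(self, random_mask_pair):
        a, b = random_mask_pair
        np.testing.assert_array_equal(average_masks(a, b), (a.astype(float) + b.astype(float)) / 2)

    @pytest.mark.parametrize(
        "ca,cb,expected", [(4, 2, 0.5), (2, 4, 0.5), (7, 7, 1.0), (5, 0, 0.0), (0, 0, 0.0)]
    )
    def test_ratio_factor(self, ca, cb, expected):
        assert window_ratio_factor(ca, cb) == expected

    @given(ca=st.integers(0, 10_000), cb=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_ratio_factor_symmetric_in_unit_interval(self, ca, cb):
        r = window_ratio_factor(ca, cb)
        assert r == window_ratio_factor(cb, ca)
        assert 0.0 <= r <= 1.0

    def test_window_proximity_worked_example(self):
        # 4x4 window: 2 px where both channels are present (averaged 1),
        # 2 px with one channel (averaged 0.5), 12 empty; ratio factor 0.5
        # -> (0.5 + 0.5 + 0.25 + 0.25) / 4 = 0.375
        window = np.zeros((4, 4))
        window[0, :2] = 1.0
        window[1, :2] = 0.5
        assert window_proximity(window, 0.5) == pytest.approx(0.375)

    def test_window_proximity_limits(self):
        assert window_proximity(np.ones((4, 4)), 1.0) == 1.0
        assert window_proximity(np.zeros((4, 4)), 0.7) == 0.0


class TestProximityIndex:
    def test_identical_masks_score_one_at_any_window_size(self, random_mask_pair):
        a, _ = random_mask_pair
        for k in (2, 3, 4, 5, 6):
            r = proximity_index(a, a, ProximityConfig(k=k))
            assert r.proximity_index == pytest.approx(1.0)

    def test_absent_channel_scores_zero(self, random_mask_pair):
        a, _ = random_mask_pair
        r = proximity_index(a, np.zeros_like(a), ProximityConfig(k=4))
        assert r.proximity_index == 0.0 and r.n_nonzero_windows == 0

    def test_single_nonzero_window_sets_the_image_index(self):
        # embed the worked 4x4 window in an otherwise empty 64x64 image
        a = np.zeros((64, 64), dtype=bool)
        b = np.zeros((64, 64), dtype=bool)
        a[0, 0:2] = True  # both channels in 2 px
        b[0, 0:2] = True
        a[1, 0:2] = True  # A alone in 2 px -> counts 4 vs 2, ratio 0.5
        r = proximity_index(a, b, ProximityConfig(k=2))
        assert r.n_nonzero_windows == 1
        assert r.proximity_index == pytest.approx(0.375)

    def test_matches_naive_reference_on_random_masks(self, rng):
        for i in range(200):
            density = 0.05 + 0.4 * (i % 5) / 4
            a = rng.random((64, 64)) < density
            b = rng.random((64, 64)) < density
            k = 2 + i % 5
            got = proximity_index(a, b, ProximityConfig(k=k)).proximity_index
            want = naive_proximity_index(a, b, window=2**k)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("edge", ["partial", "drop", "pad"])
    def test_edge_policies_match_reference_on_non_multiple_sizes(self, rng, edge):
        a = rng.random((70, 53)) < 0.3
        b = rng.random((70, 53)) < 0.3
        got = proximity_index(a, b, ProximityConfig(k=4, edge_policy=edge)).proximity_index
        ref_edge = "partial" if edge == "pad" else edge  # padded zeros never count
        want = naive_proximity_index(a, b, window=16, edge=ref_edge)
        assert got == pytest.approx(want, abs=1e-12)

    def test_overlapping_stride_matches_reference(self, rng):
        a = rng.random((40, 40)) < 0.3
        b = rng.random((40, 40)) < 0.3
        got = proximity_index(a, b, ProximityConfig(k=3, stride=4)).proximity_index
        want = naive_proximity_index(a, b, window=8, stride=4)
        assert got == pytest.approx(want, abs=1e-12)

    @given(a=masks_8x8, b=masks_8x8)
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        cfg = ProximityConfig(k=2)
        r1 = proximity_index(a, b, cfg)
        r2 = proximity_index(b, a, cfg)
        assert r1.proximity_index == pytest.approx(r2.proximity_index)
        assert 0.0 <= r1.proximity_index <= 1.0
        assert (r1.per_window_index >= 0).all() and (r1.per_window_index <= 1).all()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ConfigurationError):
            proximity_index(np.ones((16, 16), dtype=bool), np.ones((16, 16), dtype=bool), ProximityConfig(k=6))

    def test_invalid_k_rejected(self):
        for k in (1, 11, 2.5):
            with pytest.raises(ConfigurationError):
                ProximityConfig(k=k)


class TestWindowSizeSweep:
    def test_limit_groups_separate_fully_and_tie_breaks_to_small_k(self, rng):
        a = rng.random((128, 128)) < 0.3
        identical = [(a, a.copy()) for _ in range(3)]
        absent = [(a, np.zeros_like(a)) for _ in range(3)]
        res = window_size_sweep({"same": identical, "absent": absent}, k_range=range(2, 8))
        assert (res.separation == 1.0).all()
        assert res.selected_k == 2  # ties broken toward the finer window

    def test_single_group_rejected(self, random_mask_pair):
        with pytest.raises(ConfigurationError):
            window_size_sweep({"only": [random_mask_pair]})

    def test_empty_group_rejected(self, random_mask_pair):
        with pytest.raises(ConfigurationError):
            window_size_sweep({"a": [random_mask_pair], "b": []})

    def test_deterministic_for_seeded_batches(self):
        from mitoprox import SceneConfig, scene_batch

        cfg_c = SceneConfig(height=128, width=128, protein_mode="mito_colocalized", coloc_fraction=1.0)
        cfg_m = SceneConfig(height=128, width=128, protein_mode="membrane")
        results = []
        for _ in range(2):
            batch = scene_batch([cfg_c] * 5 + [cfg_m] * 5, ["coloc"] * 5 + ["memb"] * 5, base_seed=3)
            grouped = {}
            for ls in batch:
                grouped.setdefault(ls.label, []).append(
                    (ls.scene.truth_mito_mask, ls.scene.truth_protein_mask)
                )
            res = window_size_sweep(grouped, k_range=range(2, 8))
            results.append((res.selected_k, res.separation.to_dict()))
        assert results[0] == results[1]
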