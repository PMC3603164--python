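import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entroseg import (
    DegenerateImageError,
    EntropyConfig,
    cclsc_histogram,
    find_threshold,
    region_entropy,
    region_probabilities,
    similarity_map,
    weight,
)

from ._oracles import phi_scan_bf, similarity_map_bf, weight_bf
from .conftest import bimodal_channel, random_channel, two_valued_channel

CFG_N3 = EntropyConfig(n=3, epsilon=2)
CFG_N5 = EntropyConfig(n=5, epsilon=5)


class TestSimilarityMap:
    def test_uniform_neighbourhood_gives_full_count(self):
        g = similarity_map(np.full((5, 5), 40, dtype=np.uint8), CFG_N5)
        assert (g == 25).all()

    def test_isolated_center_gives_minimum_count(self):
        ch = np.full((5, 5), 255, dtype=np.uint8)
        ch[2, 2] = 0
        g = similarity_map(ch, CFG_N5)
        assert g[2, 2] == 1  # the center always matches itself

    def test_partial_match_counts_center_plus_tolerant_neighbours(self):
        # center 100, ten neighbours at 103 (within eps=5), fourteen at 200
        ch = np.full((5, 5), 200, dtype=np.uint8)
        flat = ch.ravel()
        flat[:10] = 103
        ch = flat.reshape(5, 5)
        ch[2, 2] = 100
        g = similarity_map(ch, CFG_N5)
        assert g[2, 2] == 11

    def test_image_smaller_than_neighbourhood_rejected(self):
        with pytest.raises(DegenerateImageError):
            similarity_map(np.zeros((3, 3), dtype=np.uint8), CFG_N5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_nested_loop_oracle(self, seed):
        ch = random_channel(seed, shape=(7, 9))
        got = similarity_map(ch, CFG_N3)
        assert np.array_equal(got, np.array(similarity_map_bf(ch.tolist(), 3, 2)))

    @given(seed=st.integers(0, 50), eps=st.integers(0, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity_in_epsilon(self, seed, eps):
        ch = random_channel(seed, shape=(6, 6))
        g1 = similarity_map(ch, EntropyConfig(n=3, epsilon=eps))
        g2 = similarity_map(ch, EntropyConfig(n=3, epsilon=eps + 3))
        assert g1.min() >= 1 and g1.max() <= 9
        assert (g2 >= g1).all()


class TestHistogram:
    def test_constant_image_concentrates_in_one_cell(self):
        ch = np.full((6, 6), 77, dtype=np.uint8)
        sim = similarity_map(ch, CFG_N5)
        hist = cclsc_histogram(ch, sim, CFG_N5)
        assert hist.table[77, 24] == pytest.approx(1.0)
        assert hist.table.sum() == pytest.approx(1.0)
        mask = np.ones_like(hist.table, dtype=bool)
        mask[77, 24] = False
        assert (hist.table[mask] == 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_normalization(self, seed):
        ch = random_channel(seed, shape=(16, 16))
        hist = cclsc_histogram(ch, similarity_map(ch, CFG_N5), CFG_N5)
        assert hist.table.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_product_of_marginals_oracle(self):
        ch = random_channel(42, shape=(8, 8))
        sim = similarity_map(ch, CFG_N3)
        hist = cclsc_histogram(ch, sim, CFG_N3)
        from ._oracles import cclsc_table_bf

        expected = np.array(cclsc_table_bf(ch.tolist(), sim.tolist(), 3))
        assert np.allclose(hist.table, expected, atol=1e-12)

    def test_joint_histogram_sums_to_one_and_has_same_marginals(self):
        cfg = EntropyConfig(n=3, epsilon=2, joint_histogram=True)
        ch = random_channel(3, shape=(10, 10))
        sim = similarity_map(ch, cfg)
        hist = cclsc_histogram(ch, sim, cfg)
        assert hist.table.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(hist.table.sum(axis=1) * 100, hist.pixel_hist)


class TestRegionProbabilities:
    def test_complementarity_for_all_t(self):
        ch = random_channel(8, shape=(12, 12))
        hist = cclsc_histogram(ch, similarity_map(ch, CFG_N5), CFG_N5)
        for t in range(0, 256, 17):
            p_o, p_b = region_probabilities(hist, t)
            assert p_o + p_b == pytest.approx(1.0, abs=1e-9)

    def test_all_mass_below_t(self):
        ch = np.full((6, 6), 100, dtype=np.uint8)
        hist = cclsc_histogram(ch, similarity_map(ch, CFG_N5), CFG_N5)
        assert region_probabilities(hist, 150) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_out_of_range_t_rejected(self):
        ch = random_channel(0, shape=(6, 6))
        hist = cclsc_histogram(ch, similarity_map(ch, CFG_N5), CFG_N5)
        with pytest.raises(ValueError):
            region_probabilities(hist, 256)


class TestWeight:
    def test_maximum_is_five_at_continuous_center(self):
        assert weight(12.5, 5) == pytest.approx(5.0)
        assert weight(4.5, 3) == pytest.approx(5.0)

    def test_frozen_values(self):
        assert weight(12, 5) == pytest.approx(5 * math.exp(-0.25 / 32), abs=1e-4)
        assert weight(12, 5) == pytest.approx(4.9610, abs=1e-4)
        assert weight(1, 5) == pytest.approx(5 * math.exp(-(11.5**2) / 32))
        assert weight(1, 5) == pytest.approx(0.0801, abs=1e-4)

    def test_symmetry_and_positivity(self):
        m = np.arange(1, 26)
        w = weight(m, 5)
        assert (w > 0).all() and w.max() <= 5.0
        for d in range(1, 12):
            assert weight(12.5 - d, 5) == pytest.approx(weight(12.5 + d, 5))


class TestRegionEntropy:
    def _hist_from(self, ch, cfg):
        return cclsc_histogram(ch, similarity_map(ch, cfg), cfg)

    def test_degenerate_single_cell_has_zero_entropy(self):
        hist = self._hist_from(np.full((6, 6), 30, dtype=np.uint8), CFG_N5)
        assert region_entropy(hist, 100, "object") == pytest.approx(0.0)

    def test_two_equal_cells_same_m_gives_ln2_times_weight(self):
        # hand-built table: object mass split equally over two k at one m
        hist = self._hist_from(np.full((6, 6), 30, dtype=np.uint8), CFG_N5)
        hist.table[:] = 0.0
        hist.table[10, 19] = 0.5
        hist.table[20, 19] = 0.5
        got = region_entropy(hist, 100, "object")
        assert got == pytest.approx(math.log(2) * weight(20, 5))

    def test_empty_region_raises(self):
        hist = self._hist_from(np.full((6, 6), 30, dtype=np.uint8), CFG_N5)
        with pytest.raises(DegenerateImageError):
            region_entropy(hist, 100, "background")

    def test_matches_nested_loop_oracle(self):
        from ._oracles import entropy_bf

        ch = random_channel(21, shape=(9, 9))
        hist = self._hist_from(ch, CFG_N3)
        for t in (50, 100, 128, 200):
            for region in ("object", "background"):
                expected = entropy_bf(hist.table.tolist(), t, region, 3)
                if expected is None:
                    continue
                assert region_entropy(hist, t, region) == pytest.approx(
                    expected, abs=1e-9
                )


class TestFindThreshold:
    def test_two_valued_image_threshold_separates_modes(self):
        ch = two_valued_channel(1, lo=50, hi=200)
        res = find_threshold(ch, CFG_N5)
        assert 50 <= res.threshold < 200
        # Phi is constant across the separating interval, tie broken to smallest t
        interval = res.phi_curve[50:200]
        assert np.nanmax(interval) - np.nanmin(interval) < 1e-9
        assert res.threshold == 50

    @pytest.mark.parametrize("seed", range(5))
    def test_gaussian_mixture_threshold_lands_between_modes(self, seed):
        ch = bimodal_channel(seed, modes=(60, 180), sd=10.0)
        res = find_threshold(ch, CFG_N5)
        assert 80 <= res.threshold <= 160

    def test_deterministic(self):
        ch = bimodal_channel(3)
        a = find_threshold(ch, CFG_N5)
        b = find_threshold(ch, CFG_N5)
        assert a.threshold == b.threshold
        assert np.array_equal(a.phi_curve, b.phi_curve, equal_nan=True)

    def test_single_valued_channel_raises(self):
        with pytest.raises(DegenerateImageError):
            find_threshold(np.full((8, 8), 9, dtype=np.uint8), CFG_N5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_scan_oracle(self, seed):
        ch = random_channel(seed, shape=(10, 10), levels=24)
        res = find_threshold(ch, CFG_N3)
        t_bf, phi_bf, g_bf, table_bf = phi_scan_bf(ch.tolist(), 3, 2)
        assert res.threshold == t_bf
        for t, val in phi_bf.items():
            assert res.phi_curve[t] == pytest.approx(val, abs=1e-9)
        inadmissible = sorted(set(range(255)) - set(phi_bf))
        assert np.isnan(res.phi_curve[inadmissible]).all()

    def test_exclude_masked_ignores_zeroed_pixels(self):
        ch = two_valued_channel(2, lo=50, hi=200)
        masked = ch.copy()
        masked[:4] = 0
        cfg = EntropyConfig(n=5, epsilon=5, exclude_masked=True)
        res = find_threshold(masked, cfg)
        assert 50 <= res.threshold < 200
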