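import numpy as np
import pytest

from greenhia import (
    adult_population,
    align_population,
    apply_qa_mask,
    apply_water_mask,
    compute_exposures,
    filter_outliers,
    median_composite,
    population_weighted_ndvi,
    rasterize_city_mask,
    summer_mean_composite,
    temporal_consistency_filter,
    unweighted_ndvi,
)
from greenhia.exposure import UndefinedExposureError
from greenhia.io_formats import GridValidationError, RasterGrid

ND = -9999.0


def ndvi_grid(values, **kw):
    return RasterGrid(np.asarray(values, dtype=float), kind="ndvi_scene", **kw)


def flag_grid(values, kind="qa_flag", **kw):
    return RasterGrid(np.asarray(values, dtype=float), kind=kind, **kw)


class TestQaMask:
    def test_all_valid_leaves_scene_unchanged(self, rng):
        scene = ndvi_grid(rng.uniform(0, 1, (4, 4)))
        out = apply_qa_mask(scene, flag_grid(np.ones((4, 4))))
        np.testing.assert_array_equal(out.values, scene.values)

    def test_all_flagged_masks_everything(self, rng):
        scene = ndvi_grid(rng.uniform(0, 1, (4, 4)))
        out = apply_qa_mask(scene, flag_grid(np.zeros((4, 4))))
        assert out.n_valid == 0

    def test_valid_count_matches_counting_oracle(self, rng):
        values = rng.uniform(0, 1, (6, 6))
        values[0, :3] = ND  # already-missing pixels stay missing
        qa = (rng.random((6, 6)) < 0.6).astype(float)
        out = apply_qa_mask(ndvi_grid(values), flag_grid(qa))
        expected = int(((qa == 1) & (values != ND)).sum())
        assert out.n_valid == expected

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GridValidationError, match="mismatch"):
            apply_qa_mask(ndvi_grid(np.zeros((2, 2))), flag_grid(np.ones((3, 3))))


class TestOutlierFilter:
    @pytest.mark.parametrize(
        "value, kept",
        [(-0.3, False), (-0.2, True), (0.5, True), (1.0, True), (1.01, False)],
    )
    def test_range_boundaries(self, value, kept):
        out = filter_outliers(ndvi_grid([[value]]))
        assert (out.values[0, 0] != ND) == kept

    def test_commutes_with_qa_mask(self, rng):
        for _ in range(10):
            values = rng.uniform(-0.6, 1.4, (5, 5))
            qa = (rng.random((5, 5)) < 0.7).astype(float)
            scene = ndvi_grid(values)
            a = filter_outliers(apply_qa_mask(scene, flag_grid(qa)))
            b = apply_qa_mask(filter_outliers(scene), flag_grid(qa))
            np.testing.assert_array_equal(a.values, b.values)


class TestTemporalConsistency:
    def test_constant_series_unflagged(self):
        assert not temporal_consistency_filter([0.4] * 5).any()

    def test_single_spike_flagged(self):
        flags = temporal_consistency_filter([0.4, 0.4, 0.95, 0.4, 0.4], 0.3)
        np.testing.assert_array_equal(
            flags, [False, False, True, False, False])

    def test_mild_variation_unflagged(self):
        assert not temporal_consistency_filter([0.4, 0.5, 0.45]).any()

    def test_short_series_passes_through(self):
        assert not temporal_consistency_filter([0.1, 0.9]).any()


class TestMedianComposite:
    def test_single_scene_identity(self, rng):
        scene = ndvi_grid(rng.uniform(0, 1, (3, 3)))
        np.testing.assert_array_equal(
            median_composite([scene]).values, scene.values)

    def test_odd_count_median(self):
        scenes = [ndvi_grid([[v]]) for v in (0.1, 0.2, 0.9)]
        assert median_composite(scenes).values[0, 0] == pytest.approx(0.2)

    def test_even_count_uses_midpoint(self):
        scenes = [ndvi_grid([[v]]) for v in (0.1, 0.2, 0.6, 0.9)]
        assert median_composite(scenes).values[0, 0] == pytest.approx(0.4)

    def test_matches_sort_based_oracle(self, rng):
        stacks = [ndvi_grid(rng.uniform(0, 1, (6, 6))) for _ in range(7)]
        for grid in stacks:  # knock out random pixels
            grid.values[rng.random((6, 6)) < 0.3] = ND
        comp = median_composite(stacks)
        for i in range(6):
            for j in range(6):
                vals = sorted(
                    g.values[i, j] for g in stacks if g.values[i, j] != ND
                )
                if not vals:
                    assert comp.values[i, j] == ND
                else:
                    k = len(vals)
                    expected = (vals[(k - 1) // 2] + vals[k // 2]) / 2
                    assert comp.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_empty_scene_list_rejected(self):
        with pytest.raises(ValueError):
            median_composite([])


class TestWaterMask:
    def test_no_water_unchanged(self, rng):
        comp = ndvi_grid(rng.uniform(0, 1, (4, 4)))
        out = apply_water_mask(comp, flag_grid(np.zeros((4, 4)), "water_mask"))
        np.testing.assert_array_equal(out.values, comp.values)

    def test_checkerboard_halves_valid_count(self, rng):
        comp = ndvi_grid(rng.uniform(0, 1, (4, 4)))
        water = np.indices((4, 4)).sum(axis=0) % 2
        out = apply_water_mask(comp, flag_grid(water.astype(float), "water_mask"))
        assert out.n_valid == 8


class TestAlignPopulation:
    def _pop(self, values, k):
        return RasterGrid(np.asarray(values, float), pixel_size=float(k),
                          kind="population")

    def test_k1_is_identity(self, rng):
        ndvi = ndvi_grid(rng.uniform(0, 1, (4, 4)))
        pop = self._pop(rng.uniform(0, 100, (4, 4)), 1)
        np.testing.assert_array_equal(
            align_population(pop, ndvi).values, ndvi.values)

    def test_uniform_ndvi_gives_uniform_blocks(self):
        ndvi = ndvi_grid(np.full((4, 4), 0.37))
        pop = self._pop(np.zeros((2, 2)), 2)
        np.testing.assert_allclose(align_population(pop, ndvi).values, 0.37)

    def test_block_means_match_loop_oracle(self, rng):
        k = 4
        ndvi_vals = rng.uniform(0, 1, (8, 8))
        ndvi_vals[rng.random((8, 8)) < 0.25] = ND
        ndvi = ndvi_grid(ndvi_vals)
        pop = self._pop(rng.uniform(0, 100, (2, 2)), k)
        out = align_population(pop, ndvi)
        for bi in range(2):
            for bj in range(2):
                block = ndvi_vals[bi * k:(bi + 1) * k, bj * k:(bj + 1) * k]
                vals = block[block != ND]
                if vals.size:
                    assert out.values[bi, bj] == pytest.approx(
                        vals.mean(), abs=1e-12)
                else:
                    assert out.values[bi, bj] == ND

    def test_origin_mismatch_rejected(self, rng):
        ndvi = ndvi_grid(rng.uniform(0, 1, (4, 4)), origin_x=1.0)
        pop = self._pop(np.zeros((2, 2)), 2)
        with pytest.raises(GridValidationError, match="origin"):
            align_population(pop, ndvi)

    def test_non_integer_ratio_rejected(self, rng):
        ndvi = ndvi_grid(rng.uniform(0, 1, (4, 4)))
        pop = RasterGrid(np.zeros((2, 2)), pixel_size=1.5, kind="population")
        with pytest.raises(GridValidationError, match="integer"):
            align_population(pop, ndvi)


def member_mask(shape):
    return flag_grid(np.ones(shape))


class TestZonalNdvi:
    def test_uniform_field_returns_value(self, rng):
        ndvi = ndvi_grid(np.full((3, 3), 0.4))
        pop = RasterGrid(rng.uniform(1, 50, (3, 3)), kind="population")
        assert population_weighted_ndvi(ndvi, pop, member_mask((3, 3))) == (
            pytest.approx(0.4))

    def test_two_cell_hand_example(self):
        ndvi = ndvi_grid([[0.2, 0.6]])
        pop = RasterGrid(np.array([[300.0, 100.0]]), kind="population")
        assert population_weighted_ndvi(ndvi, pop, member_mask((1, 2))) == (
            pytest.approx(0.3))

    def test_matches_per_pixel_loop_oracle(self, rng):
        vals = rng.uniform(-0.2, 1.0, (5, 5))
        vals[rng.random((5, 5)) < 0.2] = ND
        ndvi = ndvi_grid(vals)
        pop = RasterGrid(rng.uniform(0, 100, (5, 5)), kind="population")
        mask = flag_grid((rng.random((5, 5)) < 0.8).astype(float))
        num = den = 0.0
        for i in range(5):
            for j in range(5):
                if mask.values[i, j] == 1 and vals[i, j] != ND:
                    num += vals[i, j] * pop.values[i, j]
                    den += pop.values[i, j]
        assert population_weighted_ndvi(ndvi, pop, mask) == pytest.approx(
            num / den, abs=1e-12)
        flat = [vals[i, j] for i in range(5) for j in range(5)
                if mask.values[i, j] == 1 and vals[i, j] != ND]
        assert unweighted_ndvi(ndvi, mask) == pytest.approx(
            np.mean(flat), abs=1e-12)

    def test_weight_rescaling_invariance(self, rng):
        vals = rng.uniform(0, 1, (4, 4))
        ndvi = ndvi_grid(vals)
        pop = RasterGrid(rng.uniform(1, 100, (4, 4)), kind="population")
        scaled = RasterGrid(pop.values * 7.5, kind="population")
        mask = member_mask((4, 4))
        assert population_weighted_ndvi(ndvi, pop, mask) == pytest.approx(
            population_weighted_ndvi(ndvi, scaled, mask), rel=1e-14)

    def test_zero_population_is_undefined(self):
        ndvi = ndvi_grid([[0.4]])
        pop = RasterGrid(np.array([[0.0]]), kind="population")
        with pytest.raises(UndefinedExposureError):
            population_weighted_ndvi(ndvi, pop, member_mask((1, 1)))

    def test_unweighted_simple_mean(self):
        assert unweighted_ndvi(ndvi_grid([[0.2, 0.6]]), member_mask((1, 2))) == (
            pytest.approx(0.4))


class TestSummerComposite:
    def test_single_summer_scene_identity(self, rng):
        scene = ndvi_grid(rng.uniform(0, 1, (3, 3)), month=7)
        np.testing.assert_array_equal(
            summer_mean_composite([scene]).values, scene.values)

    def test_mean_of_two(self):
        scenes = [ndvi_grid([[0.4]], month=6), ndvi_grid([[0.6]], month=8)]
        assert summer_mean_composite(scenes).values[0, 0] == pytest.approx(0.5)

    def test_winter_scenes_ignored_and_absence_rejected(self):
        winter = ndvi_grid([[0.9]], month=1)
        summer = ndvi_grid([[0.5]], month=7)
        assert summer_mean_composite([winter, summer]).values[0, 0] == (
            pytest.approx(0.5))
        with pytest.raises(ValueError, match="June-August"):
            summer_mean_composite([winter])


class TestAdultPopulation:
    @pytest.mark.parametrize(
        "total, fraction, expected",
        [(1000, 0.8, 800), (123.0, 0.0, 0.0), (456.0, 1.0, 456.0)],
    )
    def test_product(self, total, fraction, expected):
        assert adult_population(total, fraction) == pytest.approx(expected)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adult_population(100.0, 1.2)


class TestPipeline:
    def test_noiseless_bundle_reproduces_truth(self, noiseless_bundle):
        expo = compute_exposures(noiseless_bundle)
        merged = expo.merge(
            noiseless_bundle.ground_truth.ndvi, on=["city_id", "year"])
        assert len(merged) == len(noiseless_bundle.ground_truth.ndvi)
        np.testing.assert_allclose(
            merged["weighted_ndvi"], merged["true_ndvi"], rtol=1e-10)
        np.testing.assert_allclose(
            merged["unweighted_ndvi"], merged["true_ndvi"], rtol=1e-10)
        pops = expo.merge(
            noiseless_bundle.ground_truth.population, on=["city_id", "year"],
            suffixes=("", "_true"))
        np.testing.assert_allclose(
            pops["total_population"], pops["total_population_true"], rtol=1e-10)

    def test_exposures_stay_in_filtered_range(self, small_bundle):
        expo = compute_exposures(small_bundle)
        assert expo["weighted_ndvi"].between(-0.2, 1.0).all()
        assert expo["unweighted_ndvi"].between(-0.2, 1.0).all()
        assert (expo["adult_population"] <= expo["total_population"]).all()

    def test_noisy_exposure_close_to_truth(self, small_bundle):
        expo = compute_exposures(small_bundle)
        merged = expo.merge(small_bundle.ground_truth.ndvi, on=["city_id", "year"])
        # scene noise 0.02 shrinks by median-compositing and spatial averaging
        assert np.abs(merged.weighted_ndvi - merged.true_ndvi).max() < 0.02
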